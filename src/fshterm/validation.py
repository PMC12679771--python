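"""Structural validation of assembled terminology resources.

This is the layer that catches syntactic and referential problems before
anything is written to disk: missing required elements, malformed
canonical URIs, duplicate concept codes, properties used without a
declaration, hierarchy links that point nowhere or form cycles, compose
entries violating their invariants, and ConceptMap correspondence codes
from the wrong FHIR version's vocabulary.  Findings are returned as
:class:`Issue` values, never raised; ``fatal``/``error`` issues prevent
output writing, ``warning`` and ``info`` never do.

Deep validation against the full FHIR specification (the external HL7
validation engine) is deliberately not re-implemented here; the
application exposes an opt-in post-compile hook that runs an external
command on the written JSON and relays failures as warnings.

Issue codes emitted here:

``missing-status``, ``missing-content``, ``invalid-url``,
``duplicate-code``, ``undeclared-property``, ``dangling-parent``,
``parent-cycle``, ``concurrent-hierarchy``, ``name-convention``,
``invalid-compose-entry``, ``mode-vocabulary``, ``empty-display``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Any, Iterable, Mapping

from .fhir_model import (EQUIVALENCE_CODES_R4B, RELATIONSHIP_CODES_R5,
                         STATUS_CODES, FhirMode)

_URL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:\S+$")
_NAME_RE = re.compile(r"^[A-Z][A-Za-z0-9_]{0,254}$")

SEVERITIES = ("fatal", "error", "warning", "info")


@dataclass
class Issue:
    """One validation finding."""

    severity: str  # fatal | error | warning | info
    code: str
    message: str
    json_path: str | None = None
    source_file: str | None = None
    line: int | None = None

    @property
    def blocks_output(self) -> bool:
        return self.severity in ("fatal", "error")

    def to_json(self) -> str:
        payload = {"severity": self.severity, "code": self.code,
                   "message": self.message}
        if self.json_path:
            payload["jsonPath"] = self.json_path
        if self.source_file:
            payload["sourceFile"] = self.source_file
        if self.line is not None:
            payload["line"] = self.line
        return json.dumps(payload, ensure_ascii=False)


def detect_parent_cycles(parent_map: Mapping[str, Iterable[str]]
                         ) -> list[list[str]]:
    """Find every directed cycle in a code→parents graph.

    Returns each distinct cycle once as a code list, rotated to start at
    its lexicographically smallest member; an empty list for forests and
    DAGs.  Poly-hierarchies (multiple parents) are legal and produce no
    cycle by themselves.
    """
    graph = {code: list(parents) for code, parents in parent_map.items()}
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {c: WHITE for c in graph}
    cycles: list[list[str]] = []
    seen_cycles: set[frozenset[str]] = set()

    def canonical(cycle: list[str]) -> list[str]:
        pivot = cycle.index(min(cycle))
        return cycle[pivot:] + cycle[:pivot]

    # Iterative gray/black DFS so that very deep hierarchies cannot
    # exhaust the interpreter recursion limit.
    for root in graph:
        if color[root] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(root, 0)]
        path: list[str] = []
        while stack:
            node, edge = stack[-1]
            if edge == 0:
                color[node] = GRAY
                path.append(node)
            parents = [p for p in graph.get(node, ()) if p in color]
            if edge < len(parents):
                stack[-1] = (node, edge + 1)
                parent = parents[edge]
                state = color[parent]
                if state == GRAY:
                    cycle = path[path.index(parent):]
                    key = frozenset(cycle)
                    if key not in seen_cycles:
                        seen_cycles.add(key)
                        cycles.append(canonical(cycle))
                elif state == WHITE:
                    stack.append((parent, 0))
            else:
                color[node] = BLACK
                path.pop()
                stack.pop()
    return cycles


def _walk_concepts(concepts: list[dict], path: str
                   ) -> Iterable[tuple[str, dict, bool]]:
    """Yield (json_path, concept, has_children) depth-first."""
    for i, concept in enumerate(concepts):
        here = f"{path}[{i}]"
        children = concept.get("concept", [])
        yield here, concept, bool(children)
        if children:
            yield from _walk_concepts(children, f"{here}.concept")


def validate_structural(resource: dict[str, Any], mode: FhirMode, *,
                        line_index: Mapping[str, int] | None = None,
                        allow_dangling_parents: bool = False,
                        source_file: str | None = None) -> list[Issue]:
    """Run every structural check on an assembled resource tree.

    Side-effect free and deterministic: issue order follows document
    order, then check order.  ``line_index`` optionally maps concept codes
    to source-table lines so hierarchy findings can point at the
    originating row.
    """
    issues: list[Issue] = []
    lines = line_index or {}

    def add(severity: str, code: str, message: str,
            json_path: str | None = None, line: int | None = None) -> None:
        issues.append(Issue(severity=severity, code=code, message=message,
                            json_path=json_path, source_file=source_file,
                            line=line))

    rtype = resource.get("resourceType", "")
    status = resource.get("status")
    if status is None:
        add("error", "missing-status",
            "required element 'status' is not set (use '* ^status = #draft' "
            "or similar)", json_path="status")
    elif status not in STATUS_CODES:
        add("error", "missing-status",
            f"status '{status}' is not one of "
            f"{', '.join(sorted(STATUS_CODES))}", json_path="status")
    url = resource.get("url")
    if url is not None and not _URL_RE.match(url):
        add("error", "invalid-url",
            f"canonical URL '{url}' is not a syntactically valid URI",
            json_path="url")
    name = resource.get("name")
    if name is not None and not _NAME_RE.match(name):
        add("warning", "name-convention",
            f"name '{name}' does not follow the FHIR computable-name "
            f"convention (UpperCamelCase, [A-Z][A-Za-z0-9_]*)",
            json_path="name")

    if rtype == "CodeSystem":
        _validate_codesystem(resource, add, lines, allow_dangling_parents)
    elif rtype == "ValueSet":
        _validate_valueset(resource, add)
    elif rtype == "ConceptMap":
        _validate_conceptmap(resource, add, mode)
    return issues


def _validate_codesystem(resource: dict, add, lines: Mapping[str, int],
                         allow_dangling: bool) -> None:
    if "content" not in resource:
        add("error", "missing-content",
            "required element 'content' is not set", json_path="content")

    declared = {p["code"] for p in resource.get("property", [])}
    concepts = resource.get("concept", [])
    seen_codes: set[str] = set()
    parent_map: dict[str, list[str]] = {}
    any_nested = False
    any_hierarchy_props = False

    all_codes = {c.get("code") for _p, c, _n in _walk_concepts(concepts, "concept")}

    for path, concept, has_children in _walk_concepts(concepts, "concept"):
        code = concept.get("code")
        any_nested = any_nested or has_children
        if code in seen_codes:
            add("error", "duplicate-code",
                f"concept code '{code}' is defined more than once",
                json_path=path, line=lines.get(code))
        seen_codes.add(code)
        if "display" in concept and concept["display"] == "":
            add("warning", "empty-display",
                f"concept '{code}' has an empty display",
                json_path=f"{path}.display", line=lines.get(code))
        parent_map.setdefault(code, [])
        for j, prop in enumerate(concept.get("property", [])):
            pcode = prop.get("code")
            ppath = f"{path}.property[{j}]"
            if pcode not in declared:
                add("error", "undeclared-property",
                    f"concept '{code}' uses property '{pcode}' which is "
                    f"not declared", json_path=ppath, line=lines.get(code))
            if pcode in ("parent", "child"):
                any_hierarchy_props = True
                value = prop.get("valueCode")
                other = value if pcode == "parent" else code
                holder = code if pcode == "parent" else value
                if value not in all_codes:
                    severity = "warning" if allow_dangling else "error"
                    add(severity, "dangling-parent",
                        f"{pcode} '{value}' of concept "
                        f"'{code}' resolves to no code in this system",
                        json_path=ppath, line=lines.get(code))
                elif holder is not None:
                    parent_map.setdefault(holder, []).append(other)

    for cycle in detect_parent_cycles(parent_map):
        add("error", "parent-cycle",
            f"hierarchy cycle: {' -> '.join(cycle + [cycle[0]])}",
            json_path="concept", line=lines.get(cycle[0]))

    if any_nested and any_hierarchy_props:
        add("warning", "concurrent-hierarchy",
            "nested concepts and parent/child properties are used "
            "concurrently; the FHIR specification says they should not be",
            json_path="concept")


def _validate_valueset(resource: dict, add) -> None:
    compose = resource.get("compose", {})
    for direction in ("include", "exclude"):
        for i, entry in enumerate(compose.get(direction, [])):
            path = f"compose.{direction}[{i}]"
            if not entry.get("system") and not entry.get("valueSet"):
                add("error", "invalid-compose-entry",
                    f"{direction} entry has neither a system nor a valueSet",
                    json_path=path)
            if entry.get("concept") and entry.get("filter"):
                add("error", "invalid-compose-entry",
                    f"{direction} entry combines an explicit concept list "
                    f"with filters", json_path=path)


def _validate_conceptmap(resource: dict, add, mode: FhirMode) -> None:
    element_name = "equivalence" if mode is FhirMode.R4B else "relationship"
    vocab = (EQUIVALENCE_CODES_R4B if mode is FhirMode.R4B
             else RELATIONSHIP_CODES_R5)
    for g, group in enumerate(resource.get("group", [])):
        for e, element in enumerate(group.get("element", [])):
            for t, target in enumerate(element.get("target", [])):
                path = f"group[{g}].element[{e}].target[{t}]"
                corr = target.get(element_name)
                if corr is None or corr not in vocab:
                    add("error", "mode-vocabulary",
                        f"correspondence '{corr}' is not a valid "
                        f"{mode.value.upper()} {element_name} code",
                        json_path=f"{path}.{element_name}")
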