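"""Version-agnostic terminology-resource proxies and FHIR JSON assembly.

Content plugins and the FSH front end never touch FHIR-version-specific
element names: they produce :class:`ConceptEntry` / :class:`VsComposeEntry`
/ :class:`CmGroup` proxies plus a :class:`TermResourceMeta`.  Only
:func:`assemble` and :func:`serialize` consult the :class:`FhirMode`, which
selects between the R4B and R5 wire dialects.  A single compilation run
uses exactly one mode.

The two dialects differ in two ways that matter here:

* R5 adds resource-level metadata elements (``editor``, ``reviewer``,
  ``topic``, ``copyrightLabel``, ...) that the R4B schema rejects.
* The ConceptMap correspondence element was redesigned: R4B uses
  ``equivalence`` with one code vocabulary, R5 uses ``relationship`` with a
  different, incompatible vocabulary.  No automatic translation between the
  two vocabularies is attempted — a code from the wrong mode's vocabulary
  is a hard error.

Serialization is canonical and byte-deterministic: ``resourceType`` first,
elements in FHIR definition order for the selected mode, 2-space indent,
LF line endings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

from ._json import canonical_json_bytes
from .errors import ModeVocabularyError, UndeclaredPropertyUse


class FhirMode(Enum):
    """The FHIR core-specification version targeted by one compiler run."""

    R4B = "r4b"
    R5 = "r5"


# Properties the FHIR specification pre-defines for CodeSystem concepts;
# they may be used without an explicit declaration and are auto-declared
# on first use with their standard URIs.
IMPLICIT_PROPERTY_TYPES: dict[str, str] = {
    "parent": "code",
    "child": "code",
    "inactive": "boolean",
    "deprecated": "boolean",
    "notSelectable": "boolean",
}
IMPLICIT_PROPERTY_URI = "http://hl7.org/fhir/concept-properties#{code}"

PROPERTY_TYPES = ("code", "Coding", "string", "integer", "boolean",
                  "dateTime", "decimal")

# ConceptMap correspondence vocabularies.  R4B: 'equivalence' element;
# R5: 'relationship' element.  Only 'equivalent' is shared verbatim.
EQUIVALENCE_CODES_R4B = frozenset({
    "relatedto", "equivalent", "equal", "wider", "subsumes", "narrower",
    "specializes", "inexact", "unmatched", "disjoint",
})
RELATIONSHIP_CODES_R5 = frozenset({
    "related-to", "equivalent", "source-is-narrower-than-target",
    "source-is-broader-than-target", "not-related-to",
})

STATUS_CODES = frozenset({"draft", "active", "retired", "unknown"})


@dataclass
class PropertyDeclaration:
    """A CodeSystem property declaration: code, optional URI, value type."""

    code: str
    type: str = "code"
    uri: str | None = None


@dataclass
class ConceptEntry:
    """One CodeSystem concept produced by a content plugin.

    ``properties`` holds ``(property_code, (type_tag, value))`` pairs where
    the tag is one of :data:`PROPERTY_TYPES`.  ``children`` is populated
    only in nested-hierarchy mode.  ``source_line`` is internal provenance
    (the originating table row) and is never serialized.
    """

    code: str
    display: str | None = None
    definition: str | None = None
    designations: list[tuple[str | None, dict | None, str]] = field(default_factory=list)
    properties: list[tuple[str, tuple[str, Any]]] = field(default_factory=list)
    children: list["ConceptEntry"] = field(default_factory=list)
    source_line: int | None = None


@dataclass
class VsComposeEntry:
    """One ValueSet compose entry (an ``include`` or ``exclude``)."""

    direction: str  # "include" | "exclude"
    system: str | None = None
    version: str | None = None
    concepts: list[tuple[str, str | None]] = field(default_factory=list)
    filters: list[tuple[str, str, str]] = field(default_factory=list)
    value_sets: list[str] = field(default_factory=list)


@dataclass
class CmTarget:
    code: str
    correspondence: str
    display: str | None = None
    comment: str | None = None


@dataclass
class CmElement:
    code: str
    display: str | None = None
    targets: list[CmTarget] = field(default_factory=list)


@dataclass
class CmGroup:
    """One ConceptMap group: mappings between a source and a target system."""

    source_system: str | None = None
    source_version: str | None = None
    target_system: str | None = None
    target_version: str | None = None
    elements: list[CmElement] = field(default_factory=list)


@dataclass
class TermResourceMeta:
    """Resource-level metadata interpreted from the FSH rules of one item.

    ``r5_extras`` holds dotted-path → value entries for R5-only elements
    (non-empty only in R5 mode); ``generic_extras`` holds recognized FHIR
    paths outside the first-class field set, retained for serialization.
    """

    resource_kind: str  # codesystem | valueset | conceptmap
    name: str
    id: str | None = None
    url: str | None = None
    version: str | None = None
    title: str | None = None
    status: str | None = None
    experimental: bool | None = None
    date: str | None = None
    publisher: str | None = None
    description: str | None = None
    copyright: str | None = None
    case_sensitive: bool | None = None
    content_mode: str | None = None
    hierarchy_meaning: str | None = None
    identifiers: list[dict[str, Any]] = field(default_factory=list)
    property_declarations: list[PropertyDeclaration] = field(default_factory=list)
    r5_extras: dict[str, Any] = field(default_factory=dict)
    generic_extras: dict[str, Any] = field(default_factory=dict)
    source_path: str | None = None
    decl_line: int | None = None

    @property
    def resource_type(self) -> str:
        return {"codesystem": "CodeSystem", "valueset": "ValueSet",
                "conceptmap": "ConceptMap"}[self.resource_kind]


# --------------------------------------------------------------------------
# Element definition order per resource type and mode.  Metadata elements
# are emitted in this order; names absent from the active mode's list are
# never emitted under that mode.

_R5_METADATA_TAIL = [
    "copyrightLabel", "approvalDate", "lastReviewDate", "effectivePeriod",
    "topic", "author", "editor", "reviewer", "endorser", "relatedArtifact",
]

_CS_ORDER = {
    FhirMode.R4B: [
        "url", "identifier", "version", "name", "title", "status",
        "experimental", "date", "publisher", "contact", "description",
        "useContext", "jurisdiction", "purpose", "copyright",
        "caseSensitive", "valueSet", "hierarchyMeaning", "compositional",
        "versionNeeded", "content", "supplements", "count", "filter",
        "property", "concept",
    ],
    FhirMode.R5: [
        "url", "identifier", "version", "versionAlgorithmString",
        "versionAlgorithmCoding", "name", "title", "status", "experimental",
        "date", "publisher", "contact", "description", "useContext",
        "jurisdiction", "purpose", "copyright", *_R5_METADATA_TAIL,
        "caseSensitive", "valueSet", "hierarchyMeaning", "compositional",
        "versionNeeded", "content", "supplements", "count", "filter",
        "property", "concept",
    ],
}

_VS_ORDER = {
    FhirMode.R4B: [
        "url", "identifier", "version", "name", "title", "status",
        "experimental", "date", "publisher", "contact", "description",
        "useContext", "jurisdiction", "immutable", "purpose", "copyright",
        "compose",
    ],
    FhirMode.R5: [
        "url", "identifier", "version", "versionAlgorithmString",
        "versionAlgorithmCoding", "name", "title", "status", "experimental",
        "date", "publisher", "contact", "description", "useContext",
        "jurisdiction", "immutable", "purpose", "copyright",
        *_R5_METADATA_TAIL, "compose",
    ],
}

_CM_ORDER = {
    FhirMode.R4B: [
        "url", "identifier", "version", "name", "title", "status",
        "experimental", "date", "publisher", "contact", "description",
        "useContext", "jurisdiction", "purpose", "copyright",
        "sourceUri", "sourceCanonical", "targetUri", "targetCanonical",
        "group",
    ],
    FhirMode.R5: [
        "url", "identifier", "version", "versionAlgorithmString",
        "versionAlgorithmCoding", "name", "title", "status", "experimental",
        "date", "publisher", "contact", "description", "useContext",
        "jurisdiction", "purpose", "copyright", *_R5_METADATA_TAIL,
        "property", "additionalAttribute", "sourceScopeUri",
        "sourceScopeCanonical", "targetScopeUri", "targetScopeCanonical",
        "group",
    ],
}

_ORDER_BY_TYPE = {"CodeSystem": _CS_ORDER, "ValueSet": _VS_ORDER,
                  "ConceptMap": _CM_ORDER}

# Nested element names legal inside each resource type, used for the
# mode-gating allowlist (the *_only entries belong to exactly one mode).
_NESTED_COMMON = {
    "identifier": {"use", "type", "system", "value", "period", "assigner",
                   "coding", "text", "code", "display"},
    "contactdetail": {"name", "telecom", "system", "value", "use", "rank"},
}
_CS_NESTED = {
    "property": {"code", "uri", "description", "type"},
    "concept": {"code", "display", "definition", "designation", "property",
                "concept", "language", "use", "value", "system",
                "valueCode", "valueCoding", "valueString", "valueInteger",
                "valueBoolean", "valueDateTime", "valueDecimal"},
    "filter": {"code", "description", "operator", "value"},
}
_VS_NESTED = {
    "compose": {"lockedDate", "inactive", "include", "exclude", "system",
                "version", "concept", "code", "display", "designation",
                "filter", "property", "op", "value", "valueSet"},
}
_CM_NESTED_R4B = {
    "group": {"source", "sourceVersion", "target", "targetVersion",
              "element", "code", "display", "noMap", "target", "equivalence",
              "comment", "dependsOn", "product", "unmapped", "mode", "url"},
}
_CM_NESTED_R5 = {
    "group": {"source", "target", "element", "code", "display", "noMap",
              "valueSet", "target", "relationship", "comment", "property",
              "dependsOn", "product", "unmapped", "mode", "url"},
}


def allowed_element_names(mode: FhirMode, resource_type: str) -> frozenset[str]:
    """All element names legal at any depth for a resource type under a mode.

    Backs the mode-gating check: serialized output must contain no key
    outside this set.
    """
    names: set[str] = {"resourceType", "id"}
    names.update(_ORDER_BY_TYPE[resource_type][mode])
    for group in _NESTED_COMMON.values():
        names.update(group)
    if resource_type == "CodeSystem":
        for group in _CS_NESTED.values():
            names.update(group)
    elif resource_type == "ValueSet":
        for group in _VS_NESTED.values():
            names.update(group)
    else:
        nested = _CM_NESTED_R4B if mode is FhirMode.R4B else _CM_NESTED_R5
        for group in nested.values():
            names.update(group)
    return frozenset(names)


# --------------------------------------------------------------------------
# Assembly


def _set_dotted(root: dict, path: str, value: Any) -> None:
    """Materialize a dotted path with optional [i] indices into the tree.

    Plain segments create nested dicts; ``seg[i]`` creates or extends a
    list of dicts at that element.  The final segment assigns the value.
    """
    node: Any = root
    parts = path.split(".")
    for depth, part in enumerate(parts):
        last = depth == len(parts) - 1
        name, idx = part, None
        if part.endswith("]") and "[" in part:
            name, bracket = part.split("[", 1)
            idx = int(bracket[:-1])
        if idx is None:
            if last:
                node[name] = value
            else:
                node = node.setdefault(name, {})
        else:
            seq = node.setdefault(name, [])
            while len(seq) <= idx:
                seq.append({})
            if last:
                seq[idx] = value
            else:
                node = seq[idx]


def _meta_elements(meta: TermResourceMeta, mode: FhirMode) -> dict[str, Any]:
    """Collect metadata elements keyed by their top-level FHIR name."""
    out: dict[str, Any] = {}
    scalar = {
        "url": meta.url, "version": meta.version, "name": meta.name,
        "title": meta.title, "status": meta.status,
        "experimental": meta.experimental, "date": meta.date,
        "publisher": meta.publisher, "description": meta.description,
        "copyright": meta.copyright,
    }
    for key, value in scalar.items():
        if value is not None:
            out[key] = value
    if meta.identifiers:
        out["identifier"] = meta.identifiers
    if meta.resource_kind == "codesystem":
        if meta.case_sensitive is not None:
            out["caseSensitive"] = meta.case_sensitive
        if meta.hierarchy_meaning is not None:
            out["hierarchyMeaning"] = meta.hierarchy_meaning
        out["content"] = meta.content_mode or "complete"
    for extras in (meta.generic_extras, meta.r5_extras):
        for path, value in extras.items():
            _set_dotted(out, path, value)
    return out


def _concept_tree(entry: ConceptEntry) -> dict[str, Any]:
    node: dict[str, Any] = {"code": entry.code}
    if entry.display is not None:
        node["display"] = entry.display
    if entry.definition is not None:
        node["definition"] = entry.definition
    if entry.designations:
        node["designation"] = [
            {k: v for k, v in (("language", lang), ("use", use),
                               ("value", val)) if v is not None}
            for lang, use, val in entry.designations
        ]
    if entry.properties:
        node["property"] = [
            {"code": code, f"value{tag[0].upper()}{tag[1:]}": value}
            for code, (tag, value) in entry.properties
        ]
    if entry.children:
        node["concept"] = [_concept_tree(child) for child in entry.children]
    return node


def _count_concepts(entries: list[ConceptEntry]) -> int:
    return sum(1 + _count_concepts(e.children) for e in entries)


def _assemble_cs(meta: TermResourceMeta, concepts: list[ConceptEntry],
                 elements: dict[str, Any]) -> None:
    declared: dict[str, PropertyDeclaration] = {}
    for decl in meta.property_declarations:
        declared[decl.code] = decl
    order: list[str] = [d.code for d in meta.property_declarations]

    def visit(entry: ConceptEntry) -> None:
        for code, _value in entry.properties:
            if code not in declared:
                if code in IMPLICIT_PROPERTY_TYPES:
                    declared[code] = PropertyDeclaration(
                        code=code,
                        type=IMPLICIT_PROPERTY_TYPES[code],
                        uri=IMPLICIT_PROPERTY_URI.format(code=code),
                    )
                    order.append(code)
                else:
                    raise UndeclaredPropertyUse(
                        f"concept property '{code}' is neither declared in "
                        f"the resource metadata nor a standard implicit "
                        f"property", line=entry.source_line)
        for child in entry.children:
            visit(child)

    for entry in concepts:
        visit(entry)

    elements["count"] = _count_concepts(concepts)
    if order:
        props = []
        for code in order:
            decl = declared[code]
            node: dict[str, Any] = {"code": decl.code}
            if decl.uri:
                node["uri"] = decl.uri
            node["type"] = decl.type
            props.append(node)
        elements["property"] = props
    if concepts:
        elements["concept"] = [_concept_tree(e) for e in concepts]


def _assemble_vs(entries: list[VsComposeEntry],
                 elements: dict[str, Any]) -> None:
    compose: dict[str, Any] = {}
    for direction in ("include", "exclude"):
        nodes = []
        for entry in entries:
            if entry.direction != direction:
                continue
            node: dict[str, Any] = {}
            if entry.system is not None:
                node["system"] = entry.system
            if entry.version is not None:
                node["version"] = entry.version
            if entry.concepts:
                node["concept"] = [
                    {k: v for k, v in (("code", c), ("display", d))
                     if v is not None}
                    for c, d in entry.concepts
                ]
            if entry.filters:
                node["filter"] = [
                    {"property": p, "op": op, "value": v}
                    for p, op, v in entry.filters
                ]
            if entry.value_sets:
                node["valueSet"] = list(entry.value_sets)
            nodes.append(node)
        if nodes:
            compose[direction] = nodes
    if compose:
        elements["compose"] = compose


def _check_correspondence(code: str, mode: FhirMode) -> None:
    vocab = EQUIVALENCE_CODES_R4B if mode is FhirMode.R4B else RELATIONSHIP_CODES_R5
    if code not in vocab:
        element = "equivalence" if mode is FhirMode.R4B else "relationship"
        raise ModeVocabularyError(
            f"correspondence code '{code}' is not in the {mode.value.upper()} "
            f"{element} vocabulary; codes are not translated between FHIR "
            f"versions automatically")


def _assemble_cm(groups: list[CmGroup], elements: dict[str, Any],
                 mode: FhirMode) -> None:
    corr_element = "equivalence" if mode is FhirMode.R4B else "relationship"
    nodes = []
    for group in groups:
        node: dict[str, Any] = {}
        if mode is FhirMode.R4B:
            if group.source_system is not None:
                node["source"] = group.source_system
            if group.source_version is not None:
                node["sourceVersion"] = group.source_version
            if group.target_system is not None:
                node["target"] = group.target_system
            if group.target_version is not None:
                node["targetVersion"] = group.target_version
        else:
            # R5 dropped group.sourceVersion/targetVersion; a version is
            # carried in the canonical as `system|version`.
            if group.source_system is not None:
                node["source"] = (group.source_system
                                  + (f"|{group.source_version}"
                                     if group.source_version else ""))
            if group.target_system is not None:
                node["target"] = (group.target_system
                                  + (f"|{group.target_version}"
                                     if group.target_version else ""))
        element_nodes = []
        for element in group.elements:
            enode: dict[str, Any] = {"code": element.code}
            if element.display is not None:
                enode["display"] = element.display
            targets = []
            for target in element.targets:
                _check_correspondence(target.correspondence, mode)
                tnode: dict[str, Any] = {"code": target.code}
                if target.display is not None:
                    tnode["display"] = target.display
                tnode[corr_element] = target.correspondence
                if target.comment is not None:
                    tnode["comment"] = target.comment
                targets.append(tnode)
            if targets:
                enode["target"] = targets
            element_nodes.append(enode)
        node["element"] = element_nodes
        nodes.append(node)
    if nodes:
        elements["group"] = nodes


def assemble(meta: TermResourceMeta, bundle: "ContentBundle",
             mode: FhirMode) -> dict[str, Any]:
    """Combine interpreted metadata and plugin content into a resource tree.

    Returns the full JSON-ready tree with elements in the active mode's
    definition order.  Raises :class:`UndeclaredPropertyUse` for concept
    properties that are neither declared nor implicit, and
    :class:`ModeVocabularyError` for ConceptMap correspondence codes from
    the wrong mode's vocabulary.
    """
    if bundle.kind != meta.resource_kind:
        raise ValueError(
            f"content bundle kind '{bundle.kind}' does not match resource "
            f"kind '{meta.resource_kind}'")
    elements = _meta_elements(meta, mode)
    if meta.resource_kind == "codesystem":
        _assemble_cs(meta, bundle.payload, elements)
    elif meta.resource_kind == "valueset":
        _assemble_vs(bundle.payload, elements)
    else:
        _assemble_cm(bundle.payload, elements, mode)

    rtype = meta.resource_type
    tree: dict[str, Any] = {"resourceType": rtype}
    if meta.id is not None:
        tree["id"] = meta.id
    for name in _ORDER_BY_TYPE[rtype][mode]:
        if name in elements:
            tree[name] = elements.pop(name)
    if elements:
        # Anything left over was interpreted upstream but has no slot in
        # this mode's element order — a programming error, not user error.
        raise AssertionError(
            f"elements without a serialization slot: {sorted(elements)}")
    return tree


def serialize(resource: dict[str, Any], mode: FhirMode) -> bytes:
    """Serialize an assembled resource tree to canonical FHIR JSON bytes."""
    return canonical_json_bytes(resource)
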