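"""Deterministic synthetic terminology tables and a brute-force oracle.

Two table layouts are generated, emulating the two catalog shapes the
compiler targets:

* ``hierarchy_csv`` — a small spreadsheet-style CSV with a header row and
  CODE / DISPLAY / INACTIVE / PARENT columns; INACTIVE uses YES/NO cells
  and PARENT holds the parent concept's code.
* ``alpha_like`` — a headerless pipe-separated file in the style of
  large national diagnosis indexes: our own documented 7-column layout
  ``validity|code|primary-code|secondary-code|extra-code|aux-code|text``
  (it does not claim to replicate any official distribution layout).

Generation is seeded and byte-deterministic: the same
``(FixtureSpec, path)`` always writes the same file.  The returned
manifest records ground truth (row/code counts, expected property
counts, planted defects with their line numbers) that tests assert
against compiler output.

Defects can be planted on demand: a duplicate code with a conflicting
display, a dangling parent, a parent cycle (rewiring an existing edge to
a descendant), and a ragged row.

:func:`oracle_codesystem` is the independent correctness oracle: it
builds the expected CodeSystem JSON directly from the table rows by
straightforward record iteration, sharing nothing with the compiler
beyond the canonical JSON byte writer.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from ._json import canonical_json_bytes

DEFECT_KINDS = ("duplicate_display_conflict", "dangling_parent", "cycle",
                "ragged_row")

_WORDS = (
    "acute chronic primary secondary benign malignant congenital acquired "
    "diffuse focal proximal distal bilateral unilateral idiopathic familial "
    "disorder syndrome lesion stenosis atrophy fibrosis necrosis sclerosis "
    "carcinoma deficiency infection inflammation dysplasia hyperplasia "
    "cardiac renal hepatic neural dermal osseous vascular lymphoid gastric "
    "pulmonary thoracic lumbar cervical cranial femoral ulnar radial"
).split()


@dataclass
class FixtureSpec:
    """Parameters of one synthetic table."""

    rows: int
    seed: int
    layout: str = "hierarchy_csv"  # hierarchy_csv | alpha_like
    inactive_fraction: float = 0.15
    max_hierarchy_depth: int = 3
    duplicate_code_fraction: float = 0.0
    defects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.layout not in ("hierarchy_csv", "alpha_like"):
            raise ValueError(f"unknown layout '{self.layout}'")
        for defect in self.defects:
            if defect not in DEFECT_KINDS:
                raise ValueError(f"unknown defect kind '{defect}'")


@dataclass
class Manifest:
    """Ground truth about a generated table."""

    layout: str
    seed: int
    path: str
    row_count: int            # data rows actually written (incl. defect rows)
    distinct_codes: int
    expected_concepts: int
    expected_properties: dict[str, int] = field(default_factory=dict)
    defects: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "layout": self.layout, "seed": self.seed, "path": self.path,
            "row_count": self.row_count,
            "distinct_codes": self.distinct_codes,
            "expected_concepts": self.expected_concepts,
            "expected_properties": self.expected_properties,
            "defects": self.defects,
        }


def _display(rng: random.Random, n_words: int) -> str:
    words = [rng.choice(_WORDS) for _ in range(n_words)]
    return " ".join(words).capitalize()


def generate_table(spec: FixtureSpec, path: str | Path) -> Manifest:
    """Write the table for ``spec`` and return its ground-truth manifest."""
    if spec.layout == "hierarchy_csv":
        return _generate_hierarchy_csv(spec, Path(path))
    return _generate_alpha_like(spec, Path(path))


def _generate_hierarchy_csv(spec: FixtureSpec, path: Path) -> Manifest:
    rng = random.Random(spec.seed)
    codes: list[str] = []
    depth: dict[str, int] = {}
    parent_of: dict[str, str] = {}
    rows: list[list[str]] = []  # CODE, DISPLAY, INACTIVE, PARENT
    display_of: dict[str, str] = {}

    n_unique = max(1, round(spec.rows * (1.0 - spec.duplicate_code_fraction)))
    for i in range(spec.rows):
        if i < n_unique:
            code = f"C{i + 1:04d}"
            display = _display(rng, rng.randint(2, 4))
            parent = ""
            if codes and rng.random() < 0.7:
                candidates = [c for c in codes
                              if depth[c] < spec.max_hierarchy_depth - 1]
                if candidates:
                    parent = rng.choice(candidates)
            inactive = "YES" if rng.random() < spec.inactive_fraction else "NO"
            depth[code] = depth[parent] + 1 if parent else 0
            if parent:
                parent_of[code] = parent
            codes.append(code)
            display_of[code] = display
            rows.append([code, display, inactive, parent])
        else:
            # merge row: same code and display, an extra parent link to an
            # earlier code only, so the hierarchy stays acyclic
            if len(codes) < 2:
                rows.append([codes[0], display_of[codes[0]], "NO", ""])
                continue
            pos = rng.randrange(1, len(codes))
            code = codes[pos]
            extra_parent = rng.choice(codes[:pos])
            rows.append([code, display_of[code], "NO", extra_parent])

    defects: list[dict[str, Any]] = []
    header_offset = 2  # header is line 1; first data row is line 2
    ragged: list[str] | None = None

    if "cycle" in spec.defects:
        victim = next((c for c in codes if c in parent_of), None)
        if victim is None:
            # no hierarchy to rewire: append a two-node cycle
            a, b = "CYCA", "CYCB"
            rows.append([a, "Cycle seed a", "NO", b])
            rows.append([b, "Cycle seed b", "NO", a])
            codes.extend([a, b])
            defects.append({"kind": "cycle", "codes": sorted([a, b]),
                            "line": len(rows) + 1})
        else:
            chain = [victim]
            while chain[-1] in parent_of:
                chain.append(parent_of[chain[-1]])
            root = chain[-1]
            row_idx = next(i for i, r in enumerate(rows) if r[0] == root)
            rows[row_idx] = [root, rows[row_idx][1], rows[row_idx][2], victim]
            defects.append({"kind": "cycle", "codes": sorted(chain),
                            "line": row_idx + header_offset})
    if "duplicate_display_conflict" in spec.defects:
        rows.append([codes[0], "Conflicting display text", "NO", ""])
        defects.append({"kind": "duplicate_display_conflict",
                        "code": codes[0], "line": len(rows) + 1})
    if "dangling_parent" in spec.defects:
        code = f"D{len(codes) + 1:04d}"
        rows.append([code, _display(rng, 2), "NO", "NOSUCHCODE"])
        defects.append({"kind": "dangling_parent", "code": code,
                        "parent": "NOSUCHCODE", "line": len(rows) + 1})
    if "ragged_row" in spec.defects:
        ragged = [f"R{len(rows) + 1:04d}", "Ragged row"]
        defects.append({"kind": "ragged_row", "line": len(rows) + 2})

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["CODE", "DISPLAY", "INACTIVE", "PARENT"])
    writer.writerows(rows)
    if ragged is not None:
        writer.writerow(ragged)
    path.write_text(buf.getvalue(), encoding="utf-8")

    inactive_count = sum(1 for r in rows if r[2] == "YES")
    parent_count = sum(1 for r in rows if r[3] != "")
    return Manifest(
        layout=spec.layout, seed=spec.seed, path=str(path),
        row_count=len(rows) + (1 if ragged is not None else 0),
        distinct_codes=len({r[0] for r in rows}),
        expected_concepts=len({r[0] for r in rows}),
        expected_properties={"inactive": inactive_count,
                             "parent": parent_count},
        defects=defects)


def _icd_code(rng: random.Random) -> str:
    return (f"{rng.choice('ABCDEFGHIJKLMNQ')}{rng.randint(0, 99):02d}"
            f".{rng.randint(0, 9)}")


def _generate_alpha_like(spec: FixtureSpec, path: Path) -> Manifest:
    rng = random.Random(spec.seed)
    rows: list[list[str]] = []
    codes: list[str] = []
    text_of: dict[str, str] = {}
    n_unique = max(1, round(spec.rows * (1.0 - spec.duplicate_code_fraction)))
    for i in range(spec.rows):
        if i < n_unique:
            code = str(1000000 + i)
            validity = "0" if rng.random() < spec.inactive_fraction else "1"
            primary = _icd_code(rng)
            secondary = _icd_code(rng) if rng.random() < 0.4 else ""
            extra = _icd_code(rng) if rng.random() < 0.15 else ""
            orpha = str(rng.randint(1000, 999999)) if rng.random() < 0.3 else ""
            text = _display(rng, rng.randint(3, 6))
            codes.append(code)
            text_of[code] = text
            rows.append([validity, code, primary, secondary, extra, orpha,
                         text])
        else:
            code = rng.choice(codes)
            rows.append(["1", code, _icd_code(rng), "", "", "",
                         text_of[code]])

    defects: list[dict[str, Any]] = []
    ragged: list[str] | None = None
    if "duplicate_display_conflict" in spec.defects:
        rows.append(["1", codes[0], _icd_code(rng), "", "", "",
                     "Conflicting index term"])
        defects.append({"kind": "duplicate_display_conflict",
                        "code": codes[0], "line": len(rows)})
    if "ragged_row" in spec.defects:
        ragged = ["1", str(9999999)]
        defects.append({"kind": "ragged_row", "line": len(rows) + 1})

    lines = ["|".join(r) for r in rows]
    if ragged is not None:
        lines.append("|".join(ragged))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    props = {
        "validity": sum(1 for r in rows if r[0] != ""),
        "icd10": sum(1 for r in rows if r[2] != ""),
        "icd10_alt": sum(1 for r in rows if r[3] != ""),
        "extra_code": sum(1 for r in rows if r[4] != ""),
        "orpha": sum(1 for r in rows if r[5] != ""),
    }
    return Manifest(
        layout=spec.layout, seed=spec.seed, path=str(path),
        row_count=len(rows) + (1 if ragged is not None else 0),
        distinct_codes=len({r[1] for r in rows}),
        expected_concepts=len({r[1] for r in rows}),
        expected_properties=props, defects=defects)


# --------------------------------------------------------------------------
# Brute-force oracle


_IMPLICIT_URI = "http://hl7.org/fhir/concept-properties#{code}"
_IMPLICIT_TYPES = {"parent": "code", "child": "code", "inactive": "boolean",
                   "deprecated": "boolean", "notSelectable": "boolean"}
_VALUE_KEYS = {"code": "valueCode", "string": "valueString",
               "integer": "valueInteger", "boolean": "valueBoolean",
               "dateTime": "valueDateTime", "decimal": "valueDecimal",
               "Coding": "valueCoding"}

# CodeSystem metadata element order, restated independently of the
# compiler's tables on purpose (the oracle must not inherit its bugs).
_ORACLE_META_ORDER = ("url", "version", "name", "title", "status",
                      "experimental", "date", "publisher", "description",
                      "copyright", "caseSensitive", "hierarchyMeaning")


def oracle_codesystem(table_path: str | Path, mapping: dict[str, Any],
                      meta: dict[str, Any]) -> bytes:
    """Build the expected CodeSystem JSON naively from the table.

    ``mapping`` keys: ``delimiter`` (default ``,``), ``has_header``
    (default True), ``code_column`` / ``display_column`` /
    ``inactive_column`` / ``parent_column`` (header names, or 1-based
    indices for headerless tables), ``inactive_true`` (iterable, default
    YES-ish), and ``properties`` — a list of ``(code, column, type)``
    triples.  ``meta`` holds plain metadata values plus an optional
    ``declared_properties`` list of ``(code, uri, type)``.

    Intended for small tables; iterates records directly and shares only
    the canonical JSON writer with the compiler.
    """
    text = Path(table_path).read_text(mapping.get("encoding", "utf-8"))
    delimiter = mapping.get("delimiter", ",")
    raw_lines = [ln for ln in text.split("\n") if ln != ""]
    if delimiter in (",", ";"):
        table = [next(csv.reader(io.StringIO(ln), delimiter=delimiter))
                 for ln in raw_lines]
    else:
        table = [ln.split(delimiter) for ln in raw_lines]

    header: list[str] | None = None
    if mapping.get("has_header", True):
        header = table[0]
        table = table[1:]

    def col(ref: Any) -> int | None:
        if ref is None:
            return None
        if header is not None:
            return header.index(ref)
        return int(ref) - 1

    code_idx = col(mapping["code_column"])
    display_idx = col(mapping.get("display_column"))
    inactive_idx = col(mapping.get("inactive_column"))
    parent_idx = col(mapping.get("parent_column"))
    inactive_true = {v.lower() for v in
                     mapping.get("inactive_true", ("yes", "y", "true", "1"))}
    prop_plan = [(code, col(column), ptype)
                 for code, column, ptype in mapping.get("properties", [])]

    order: list[str] = []
    displays: dict[str, str] = {}
    props: dict[str, list[dict[str, Any]]] = {}

    for cells in table:
        code = cells[code_idx]
        if code not in props:
            order.append(code)
            props[code] = []
            if display_idx is not None and cells[display_idx]:
                displays[code] = cells[display_idx]
        for pcode, pidx, ptype in prop_plan:
            raw = cells[pidx]
            if raw == "":
                continue
            value: Any = raw
            if ptype == "integer":
                value = int(raw)
            elif ptype == "decimal":
                value = float(raw)
            elif ptype == "boolean":
                value = raw.strip().lower() in ("true", "1", "yes", "y")
            props[code].append({"code": pcode, _VALUE_KEYS[ptype]: value})
        if inactive_idx is not None and cells[inactive_idx].lower() in inactive_true:
            props[code].append({"code": "inactive", "valueBoolean": True})
        if parent_idx is not None and cells[parent_idx] != "":
            props[code].append({"code": "parent",
                                "valueCode": cells[parent_idx]})

    # Property declarations: explicit ones first, implicit ones in order
    # of first use walking the concepts (not the rows).
    declared: list[tuple[str, str | None, str]] = [
        (c, u, t) for c, u, t in meta.get("declared_properties", [])]
    declared_codes = [c for c, _u, _t in declared]
    for code in order:
        for prop in props[code]:
            pcode = prop["code"]
            if pcode not in declared_codes:
                declared.append((pcode, _IMPLICIT_URI.format(code=pcode),
                                 _IMPLICIT_TYPES[pcode]))
                declared_codes.append(pcode)

    tree: dict[str, Any] = {"resourceType": "CodeSystem"}
    if meta.get("id") is not None:
        tree["id"] = meta["id"]
    for key in _ORACLE_META_ORDER:
        if meta.get(key) is not None:
            tree[key] = meta[key]
    tree["content"] = meta.get("content", "complete")
    tree["count"] = len(order)
    if declared:
        tree["property"] = [
            {k: v for k, v in (("code", c), ("uri", u), ("type", t))
             if v is not None}
            for c, u, t in declared]
    if order:
        concept_nodes = []
        for code in order:
            node: dict[str, Any] = {"code": code}
            if code in displays:
                node["display"] = displays[code]
            if props[code]:
                node["property"] = props[code]
            concept_nodes.append(node)
        tree["concept"] = concept_nodes
    return canonical_json_bytes(tree)
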