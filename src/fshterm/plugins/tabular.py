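"""Delimited-table content plugin: CSV/TSV/pipe catalogs to concepts.

Terminology catalogs are very often distributed as delimited plain-text
tables — one row per concept with columns for the code, a display text
and additional per-concept properties (validity flags, parent codes,
mapped classification codes, free text).  This plugin maps such tables
onto CodeSystem concept entries with a configurable column mapping.

Dialect rules: comma- and semicolon-delimited files honor RFC-4180-style
double-quote escaping (spreadsheet exports); any other delimiter (pipe,
tab, ...) is split verbatim, matching the raw column format of catalogs
such as the German Alpha-ID-SE index, which does not quote cells.  Rows
sharing a code are merged into a single concept that accumulates the
properties of every row, in row order.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from ..errors import (ArgumentValueError, CompileError, DanglingParent,
                      DuplicateCodeConflict, EmptyCode, FileMissing,
                      DecodeError, RaggedRow, TypeMismatch,
                      UndeclaredProperty)
from ..fhir_model import (IMPLICIT_PROPERTY_TYPES, PROPERTY_TYPES,
                          ConceptEntry, PropertyDeclaration,
                          TermResourceMeta)
from ..plugin_framework import (ArgumentSpec, ContentBundle, ContentPlugin,
                                ParsedArgs, PluginDescriptor)

HIERARCHY_MODES = ("parent", "child", "both", "nested")
DEFAULT_INACTIVE_TRUE = ("YES", "Y", "TRUE", "1")


@dataclass
class PropertyMapping:
    property_code: str
    column: str
    value_type: str | None = None
    translation: dict[str, str] | None = None


@dataclass
class ColumnMapping:
    """Column configuration for one table conversion.

    Column references are header names when ``has_header`` is true, and
    1-based column indices (as strings) otherwise.
    """

    code_column: str
    display_column: str | None = None
    definition_column: str | None = None
    property_mappings: list[PropertyMapping] = field(default_factory=list)
    parent_column: str | None = None
    inactive_column: str | None = None
    inactive_true_values: tuple[str, ...] = DEFAULT_INACTIVE_TRUE
    delimiter: str = ","
    encoding: str = "utf-8"
    has_header: bool = True
    comment_prefix: str | None = None
    hierarchy_mode: str = "parent"
    allow_dangling_parents: bool = False

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ArgumentValueError(
                f"delimiter must be exactly one character, got "
                f"{self.delimiter!r}")
        if self.hierarchy_mode not in HIERARCHY_MODES:
            raise ArgumentValueError(
                f"hierarchy mode must be one of {', '.join(HIERARCHY_MODES)}")


@dataclass
class RowRecord:
    line: int  # 1-based physical line in the source file
    cells: list[str]


def read_table(path: str | Path,
               mapping: ColumnMapping) -> tuple[list[str] | None, list[RowRecord]]:
    """Read and split a delimited file into verbatim cell rows.

    Returns ``(header, rows)`` where ``header`` is None for headerless
    files.  Empty lines and comment-prefixed lines are skipped; CRLF and
    LF line endings yield identical records.  Raises :class:`FileMissing`,
    :class:`DecodeError` (with byte offset) or :class:`RaggedRow` (with
    the 1-based line number of the offending row).
    """
    path = Path(path)
    if not path.is_file():
        raise FileMissing(f"input table not found: {path}", path=str(path))
    data = path.read_bytes()
    try:
        text = data.decode(mapping.encoding)
    except UnicodeDecodeError as exc:
        raise DecodeError(
            f"cannot decode {path} as {mapping.encoding}: byte offset "
            f"{exc.start}", path=str(path)) from exc
    except LookupError as exc:
        raise ArgumentValueError(f"unknown encoding '{mapping.encoding}'") from exc

    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    lines = [ln[:-1] if ln.endswith("\r") else ln for ln in lines]

    use_csv = mapping.delimiter in (",", ";")
    rows: list[RowRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if line == "":
            continue
        if mapping.comment_prefix and line.startswith(mapping.comment_prefix):
            continue
        if use_csv:
            cells = next(csv.reader(io.StringIO(line),
                                    delimiter=mapping.delimiter))
        else:
            cells = line.split(mapping.delimiter)
        rows.append(RowRecord(line=lineno, cells=cells))

    header: list[str] | None = None
    if mapping.has_header:
        if not rows:
            raise RaggedRow(f"{path} has no header row", path=str(path), line=1)
        header = rows.pop(0).cells
    width = len(header) if header is not None else (
        len(rows[0].cells) if rows else 0)
    for row in rows:
        if len(row.cells) != width:
            raise RaggedRow(
                f"row has {len(row.cells)} cells, expected {width}",
                path=str(path), line=row.line)
    return header, rows


def _column_index(ref: str, header: list[str] | None, *,
                  what: str) -> int:
    if header is not None:
        if ref not in header:
            raise ArgumentValueError(
                f"{what} column '{ref}' is not in the header "
                f"({', '.join(header)})")
        return header.index(ref)
    try:
        idx = int(ref)
    except ValueError:
        raise ArgumentValueError(
            f"{what} column '{ref}' must be a 1-based index for "
            f"headerless tables") from None
    if idx < 1:
        raise ArgumentValueError(f"{what} column index must be >= 1")
    return idx - 1


def _convert_cell(raw: str, value_type: str, line: int,
                  code: str) -> tuple[str, Any]:
    if value_type in ("code", "string", "dateTime"):
        return (value_type, raw)
    if value_type == "integer":
        try:
            return ("integer", int(raw))
        except ValueError:
            raise TypeMismatch(
                f"property '{code}': cell '{raw}' is not an integer",
                line=line) from None
    if value_type == "decimal":
        try:
            return ("decimal", float(raw))
        except ValueError:
            raise TypeMismatch(
                f"property '{code}': cell '{raw}' is not a decimal",
                line=line) from None
    if value_type == "boolean":
        lowered = raw.strip().lower()
        if lowered in ("true", "1", "yes", "y"):
            return ("boolean", True)
        if lowered in ("false", "0", "no", "n"):
            return ("boolean", False)
        raise TypeMismatch(
            f"property '{code}': cell '{raw}' is not a boolean", line=line)
    if value_type == "Coding":
        system, sep, rest = raw.partition("#")
        if not sep:
            return ("Coding", {"code": raw})
        coding: dict[str, str] = {}
        if system:
            coding["system"] = system
        coding["code"] = rest
        return ("Coding", coding)
    raise TypeMismatch(f"unsupported property type '{value_type}'", line=line)


def rows_to_concepts(rows: list[RowRecord], mapping: ColumnMapping,
                     declared_properties: list[PropertyDeclaration],
                     header: list[str] | None = None) -> list[ConceptEntry]:
    """Convert table rows into concept entries.

    One entry per distinct non-empty code, in first-appearance order; rows
    sharing a code merge into one concept accumulating properties.  The
    inactive column emits boolean ``inactive=true`` for cells in the
    true-value set; the parent column emits hierarchy links according to
    the hierarchy mode (``parent`` / ``child`` / ``both`` properties, or
    ``nested`` concept nesting).
    """
    code_idx = _column_index(mapping.code_column, header, what="code")
    display_idx = (None if mapping.display_column is None else
                   _column_index(mapping.display_column, header, what="display"))
    definition_idx = (None if mapping.definition_column is None else
                      _column_index(mapping.definition_column, header,
                                    what="definition"))
    parent_idx = (None if mapping.parent_column is None else
                  _column_index(mapping.parent_column, header, what="parent"))
    inactive_idx = (None if mapping.inactive_column is None else
                    _column_index(mapping.inactive_column, header,
                                  what="inactive"))

    declared_types = {d.code: d.type for d in declared_properties}
    prop_plan: list[tuple[str, int, str, dict[str, str] | None]] = []
    for pm in mapping.property_mappings:
        if pm.property_code in declared_types:
            value_type = declared_types[pm.property_code]
            if pm.value_type is not None and pm.value_type != value_type:
                raise ArgumentValueError(
                    f"property '{pm.property_code}' is declared as "
                    f"{value_type} but mapped as {pm.value_type}")
        elif pm.property_code in IMPLICIT_PROPERTY_TYPES:
            value_type = IMPLICIT_PROPERTY_TYPES[pm.property_code]
        else:
            raise UndeclaredProperty(
                f"property '{pm.property_code}' is neither declared in the "
                f"resource metadata nor a standard implicit property")
        if value_type not in PROPERTY_TYPES:
            raise ArgumentValueError(
                f"property '{pm.property_code}': unknown type '{value_type}'")
        idx = _column_index(pm.column, header, what=f"property {pm.property_code}")
        prop_plan.append((pm.property_code, idx, value_type, pm.translation))

    true_values = {v.lower() for v in mapping.inactive_true_values}
    concepts: dict[str, ConceptEntry] = {}
    parent_links: list[tuple[str, str, int]] = []  # (child, parent, line)

    for row in rows:
        cells = row.cells
        code = cells[code_idx]
        if code == "":
            raise EmptyCode("blank code cell", line=row.line)
        display = cells[display_idx] if display_idx is not None else None
        definition = (cells[definition_idx]
                      if definition_idx is not None else None)
        entry = concepts.get(code)
        if entry is None:
            entry = ConceptEntry(code=code, source_line=row.line)
            concepts[code] = entry
            if display:
                entry.display = display
            if definition:
                entry.definition = definition
        else:
            if display:
                if entry.display and entry.display != display:
                    raise DuplicateCodeConflict(
                        f"code '{code}' appears with conflicting displays "
                        f"('{entry.display}' vs '{display}')", line=row.line)
                entry.display = entry.display or display
            if definition:
                if entry.definition and entry.definition != definition:
                    raise DuplicateCodeConflict(
                        f"code '{code}' appears with conflicting definitions",
                        line=row.line)
                entry.definition = entry.definition or definition

        for prop_code, idx, value_type, translation in prop_plan:
            raw = cells[idx]
            if raw == "":
                continue
            if translation:
                raw = translation.get(raw, raw)
            entry.properties.append(
                (prop_code, _convert_cell(raw, value_type, row.line,
                                          prop_code)))
        if inactive_idx is not None and cells[inactive_idx].lower() in true_values:
            entry.properties.append(("inactive", ("boolean", True)))
        if parent_idx is not None and cells[parent_idx] != "":
            # parent properties go inline, in row order; existence of the
            # target (and child/nested links) is settled after all rows.
            if mapping.hierarchy_mode in ("parent", "both"):
                entry.properties.append(
                    ("parent", ("code", cells[parent_idx])))
            parent_links.append((code, cells[parent_idx], row.line))

    return _finish_hierarchy(concepts, parent_links, mapping)


def _finish_hierarchy(concepts: dict[str, ConceptEntry],
                      links: list[tuple[str, str, int]],
                      mapping: ColumnMapping) -> list[ConceptEntry]:
    mode = mapping.hierarchy_mode
    nested_children: set[str] = set()
    for child_code, parent_code, line in links:
        parent = concepts.get(parent_code)
        if parent is None:
            if not mapping.allow_dangling_parents:
                raise DanglingParent(
                    f"parent '{parent_code}' of '{child_code}' names no "
                    f"code in the table", line=line)
            continue
        if mode in ("child", "both"):
            parent.properties.append(("child", ("code", child_code)))
        if mode == "nested":
            parent.children.append(concepts[child_code])
            nested_children.add(child_code)
    if mode == "nested":
        return [e for e in concepts.values() if e.code not in nested_children]
    return list(concepts.values())


class DelimitedTablePlugin(ContentPlugin):
    """``delimited-table``: delimited text tables to CodeSystem concepts."""

    def descriptor(self) -> PluginDescriptor:
        return PluginDescriptor(
            plugin_id="delimited-table",
            summary=("convert a delimited text table (CSV/TSV/pipe) into "
                     "CodeSystem concepts"),
            supported_kinds=frozenset({"codesystem"}),
            arguments=[
                ArgumentSpec("--file", "path of the input table",
                             short_flag="-f", value_kind="path",
                             required=True),
                ArgumentSpec("--delimiter", "cell delimiter (one character)",
                             short_flag="-d", default=","),
                ArgumentSpec("--encoding", "text encoding of the input file",
                             default="utf-8"),
                ArgumentSpec("--no-header",
                             "the table has no header row; column references "
                             "are 1-based indices", value_kind="flag"),
                ArgumentSpec("--code-column",
                             "column holding the concept code",
                             default="CODE"),
                ArgumentSpec("--display-column",
                             "column holding the display text"),
                ArgumentSpec("--definition-column",
                             "column holding the concept definition"),
                ArgumentSpec("--property",
                             "map a column to a concept property, as "
                             "CODE=COLUMN[:TYPE]", value_kind="key_value_pair",
                             repeatable=True),
                ArgumentSpec("--parent-column",
                             "column holding the parent code for the "
                             "hierarchy"),
                ArgumentSpec("--inactive-column",
                             "column flagging deprecated concepts"),
                ArgumentSpec("--inactive-true-values",
                             "comma-separated cell values that mean "
                             "inactive (case-insensitive)",
                             default=",".join(DEFAULT_INACTIVE_TRUE)),
                ArgumentSpec("--hierarchy",
                             "hierarchy representation", value_kind="choice",
                             choices=HIERARCHY_MODES, default="parent"),
                ArgumentSpec("--comment-prefix",
                             "skip lines starting with this character"),
                ArgumentSpec("--allow-dangling-parents",
                             "downgrade parents that name no code in the "
                             "table from an error to a warning",
                             value_kind="flag"),
            ])

    def generate(self, args: ParsedArgs, meta: TermResourceMeta,
                 kind: str) -> ContentBundle:
        prop_mappings = []
        for name, value in args.get("--property", []):
            column, sep, vtype = value.partition(":")
            prop_mappings.append(PropertyMapping(
                property_code=name, column=column,
                value_type=vtype if sep else None))
        mapping = ColumnMapping(
            code_column=args["--code-column"],
            display_column=args.get("--display-column"),
            definition_column=args.get("--definition-column"),
            property_mappings=prop_mappings,
            parent_column=args.get("--parent-column"),
            inactive_column=args.get("--inactive-column"),
            inactive_true_values=tuple(
                v for v in args["--inactive-true-values"].split(",") if v),
            delimiter=args["--delimiter"],
            encoding=args["--encoding"],
            has_header=not args["--no-header"],
            comment_prefix=args.get("--comment-prefix"),
            hierarchy_mode=args["--hierarchy"],
            allow_dangling_parents=args["--allow-dangling-parents"],
        )
        try:
            header, rows = read_table(args["--file"], mapping)
            concepts = rows_to_concepts(rows, mapping,
                                        meta.property_declarations, header)
        except CompileError as exc:
            # row-level findings name the table file, not the FSH source
            if exc.path is None and exc.line is not None:
                exc.path = str(args["--file"])
            raise
        return ContentBundle(
            kind="codesystem", payload=concepts,
            options={"allow_dangling_parents": mapping.allow_dangling_parents,
                     "hierarchy_mode": mapping.hierarchy_mode})
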