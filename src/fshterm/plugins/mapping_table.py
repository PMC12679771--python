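"""``mapping-table`` plugin: delimited mapping tables to ConceptMap groups.

Reads a delimited file whose rows map a source code to a target code with
a correspondence code (an R4B ``equivalence`` or R5 ``relationship``
value, depending on the compilation mode — the codes are passed through
verbatim and checked against the active mode's vocabulary at assembly).
Expected columns, by header name or 1-based index with ``--no-header``:
SOURCE, TARGET, CORRESPONDENCE, and optionally SOURCE_DISPLAY,
TARGET_DISPLAY, COMMENT.
"""

from __future__ import annotations

from ..fhir_model import CmElement, CmGroup, CmTarget, TermResourceMeta
from ..plugin_framework import (ArgumentSpec, ContentBundle, ContentPlugin,
                                ParsedArgs, PluginDescriptor)
from .tabular import ColumnMapping, _column_index, read_table


class MappingTablePlugin(ContentPlugin):

    def descriptor(self) -> PluginDescriptor:
        return PluginDescriptor(
            plugin_id="mapping-table",
            summary="convert a delimited mapping table into one ConceptMap "
                    "group",
            supported_kinds=frozenset({"conceptmap"}),
            arguments=[
                ArgumentSpec("--file", "path of the mapping table",
                             short_flag="-f", value_kind="path",
                             required=True),
                ArgumentSpec("--delimiter", "cell delimiter (one character)",
                             short_flag="-d", default=","),
                ArgumentSpec("--no-header", "the table has no header row",
                             value_kind="flag"),
                ArgumentSpec("--source-system", "canonical URI of the "
                             "source code system", required=True),
                ArgumentSpec("--source-version", "source system version"),
                ArgumentSpec("--target-system", "canonical URI of the "
                             "target code system", required=True),
                ArgumentSpec("--target-version", "target system version"),
                ArgumentSpec("--source-column", "source code column",
                             default="SOURCE"),
                ArgumentSpec("--target-column", "target code column",
                             default="TARGET"),
                ArgumentSpec("--correspondence-column",
                             "column with the equivalence/relationship code",
                             default="CORRESPONDENCE"),
                ArgumentSpec("--comment-column", "optional comment column"),
            ])

    def generate(self, args: ParsedArgs, meta: TermResourceMeta,
                 kind: str) -> ContentBundle:
        mapping = ColumnMapping(
            code_column=args["--source-column"],
            delimiter=args["--delimiter"],
            has_header=not args["--no-header"])
        header, rows = read_table(args["--file"], mapping)
        src_idx = _column_index(args["--source-column"], header, what="source")
        tgt_idx = _column_index(args["--target-column"], header, what="target")
        corr_idx = _column_index(args["--correspondence-column"], header,
                                 what="correspondence")
        comment_idx = (None if args.get("--comment-column") is None else
                       _column_index(args["--comment-column"], header,
                                     what="comment"))
        elements: dict[str, CmElement] = {}
        for row in rows:
            source = row.cells[src_idx]
            element = elements.setdefault(source, CmElement(code=source))
            element.targets.append(CmTarget(
                code=row.cells[tgt_idx],
                correspondence=row.cells[corr_idx],
                comment=(row.cells[comment_idx]
                         if comment_idx is not None and row.cells[comment_idx]
                         else None)))
        group = CmGroup(
            source_system=args["--source-system"],
            source_version=args.get("--source-version"),
            target_system=args["--target-system"],
            target_version=args.get("--target-version"),
            elements=list(elements.values()))
        return ContentBundle(kind="conceptmap", payload=[group])
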