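"""``code-list`` plugin: extensional ValueSet compose entries.

Reads codes either from repeated ``--code CODE[|DISPLAY]`` arguments or
from a plain-text file with one ``code|display`` pair per line (display
optional).  Lines are included by default; ``--exclude`` switches the
whole entry to an exclusion.
"""

from __future__ import annotations

from pathlib import Path

from ..errors import ArgumentValueError, FileMissing
from ..fhir_model import TermResourceMeta, VsComposeEntry
from ..plugin_framework import (ArgumentSpec, ContentBundle, ContentPlugin,
                                ParsedArgs, PluginDescriptor)


class CodeListPlugin(ContentPlugin):

    def descriptor(self) -> PluginDescriptor:
        return PluginDescriptor(
            plugin_id="code-list",
            summary="build an extensional ValueSet entry from listed codes",
            supported_kinds=frozenset({"valueset"}),
            arguments=[
                ArgumentSpec("--system", "canonical URI of the code system "
                             "the codes come from", short_flag="-s",
                             required=True),
                ArgumentSpec("--system-version",
                             "version of the code system"),
                ArgumentSpec("--code", "a code to include, as CODE or "
                             "CODE|DISPLAY", short_flag="-c",
                             repeatable=True, mutex_group="source"),
                ArgumentSpec("--file", "file with one CODE|DISPLAY per line",
                             short_flag="-f", value_kind="path",
                             mutex_group="source"),
                ArgumentSpec("--exclude", "emit an exclusion instead of an "
                             "inclusion", value_kind="flag"),
            ])

    def generate(self, args: ParsedArgs, meta: TermResourceMeta,
                 kind: str) -> ContentBundle:
        pairs: list[tuple[str, str | None]] = []
        raw_codes: list[str] = list(args.get("--code", []))
        if args.get("--file") is not None:
            path = Path(args["--file"])
            if not path.is_file():
                raise FileMissing(f"code list file not found: {path}",
                                  path=str(path))
            raw_codes.extend(
                ln for ln in path.read_text("utf-8").splitlines() if ln.strip())
        if not raw_codes:
            raise ArgumentValueError(
                "code-list needs at least one --code or a --file")
        for raw in raw_codes:
            code, sep, display = raw.partition("|")
            pairs.append((code, display if sep else None))
        entry = VsComposeEntry(
            direction="exclude" if args["--exclude"] else "include",
            system=args["--system"],
            version=args.get("--system-version"),
            concepts=pairs)
        return ContentBundle(kind="valueset", payload=[entry])
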