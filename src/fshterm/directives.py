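"""Directive recognition and command-line-style tokenization.

Content-generation instructions are embedded in the FSH source inside
ordinary block comments carrying a recognition token: a directive opens
with ``/*^babelfsh`` (the token immediately follows ``/*``, no space) and
closes with ``^babelfsh*/``.  Plain ``/* ... */`` comments are never
treated as directives, so standard FSH comments keep their meaning and the
source stays compatible with stock FSH tooling.

The directive body is tokenized shell-style into a plugin id plus an
argument vector: tokens are whitespace-separated (newlines count as
whitespace), double quotes group tokens containing spaces or delimiter
characters, and a backslash escapes the next character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EmptyDirective, UnbalancedQuote, UnterminatedDirective

OPEN_TOKEN = "/*^babelfsh"
CLOSE_TOKEN = "^babelfsh*/"


@dataclass
class DirectiveRegion:
    """A raw recognized directive region before tokenization."""

    start: int          # character offset of the opening '/'
    end: int            # character offset one past the closing '/'
    start_line: int     # 1-based
    end_line: int       # 1-based
    raw_body: str       # text between the recognition tokens


@dataclass
class DirectiveBlock:
    """A tokenized directive: plugin id plus argument vector."""

    plugin_id: str
    argv: list[str] = field(default_factory=list)
    start_line: int = 0
    end_line: int = 0
    owner_item: str | None = None

    def __post_init__(self) -> None:
        if not self.plugin_id or any(ch.isspace() for ch in self.plugin_id):
            raise ValueError("plugin_id must be a non-empty token without whitespace")
        if self.start_line > self.end_line:
            raise ValueError("start_line must not exceed end_line")


def _line_of(text: str, offset: int) -> int:
    return text.count("\n", 0, offset) + 1


def extract_directives(text: str) -> list[DirectiveRegion]:
    """Find every directive region in document order.

    Regions may span multiple lines.  The scan is string-aware only at the
    region level: an opening token inside an ordinary comment or string is
    not recognized here — the FSH scanner performs the context-aware pass
    and calls this only on raw text when lossless extraction is needed.

    Raises :class:`UnterminatedDirective` when an opening token has no
    matching closer before end of file.
    """
    regions: list[DirectiveRegion] = []
    pos = 0
    while True:
        start = text.find(OPEN_TOKEN, pos)
        if start < 0:
            break
        body_start = start + len(OPEN_TOKEN)
        close = text.find(CLOSE_TOKEN, body_start)
        if close < 0:
            raise UnterminatedDirective(
                f"directive opened with '{OPEN_TOKEN}' is never closed with "
                f"'{CLOSE_TOKEN}'", line=_line_of(text, start))
        end = close + len(CLOSE_TOKEN)
        regions.append(DirectiveRegion(
            start=start, end=end,
            start_line=_line_of(text, start),
            end_line=_line_of(text, end - 1),
            raw_body=text[body_start:close],
        ))
        pos = end
    return regions


def tokenize_arguments(raw_body: str, *, line: int | None = None) -> tuple[str, list[str]]:
    """Split a directive body into ``(plugin_id, argv)``.

    Whitespace separates tokens; double quotes group; backslash escapes the
    next character (inside and outside quotes).  Raises
    :class:`EmptyDirective` when no tokens remain and
    :class:`UnbalancedQuote` on an unclosed double quote.
    """
    tokens: list[str] = []
    current: list[str] = []
    have_current = False
    in_quote = False
    i = 0
    n = len(raw_body)
    while i < n:
        ch = raw_body[i]
        if ch == "\\":
            if i + 1 >= n:
                raise UnbalancedQuote("trailing backslash in directive", line=line)
            current.append(raw_body[i + 1])
            have_current = True
            i += 2
            continue
        if ch == '"':
            in_quote = not in_quote
            have_current = True  # "" is a legal empty token
            i += 1
            continue
        if not in_quote and ch.isspace():
            if have_current:
                tokens.append("".join(current))
                current.clear()
                have_current = False
            i += 1
            continue
        current.append(ch)
        have_current = True
        i += 1
    if in_quote:
        raise UnbalancedQuote("unclosed double quote in directive", line=line)
    if have_current:
        tokens.append("".join(current))
    if not tokens:
        raise EmptyDirective("directive contains no plugin id", line=line)
    return tokens[0], tokens[1:]


def render_arguments(plugin_id: str, argv: list[str]) -> str:
    """Re-quote an argument vector into a directive body (inverse of
    :func:`tokenize_arguments` up to whitespace)."""
    parts = [plugin_id]
    for token in argv:
        if token == "" or any(ch.isspace() for ch in token) or '"' in token or "\\" in token:
            escaped = token.replace("\\", "\\\\").replace('"', '\\"')
            parts.append(f'"{escaped}"')
        else:
            parts.append(token)
    return " ".join(parts)
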