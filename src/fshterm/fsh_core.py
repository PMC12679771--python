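"""Parser and interpreter for the terminology-focused FSH subset.

The accepted language is a strict subset of FHIR Shorthand: ``Alias:``
declarations, ``CodeSystem:`` / ``ValueSet:`` items, ``Instance:`` items of
``ConceptMap``, parameterized ``RuleSet:`` definitions, the item keywords
``Id:`` / ``Title:`` / ``Description:``, caret value rules, plain
assignment rules (instances only), ``insert`` rules, and C-style line and
block comments.  Everything else in full FSH (profiles, extensions,
inline concept rules, path rules) is rejected with a targeted message, so
that a source file accepted here is also a valid FSH file for stock
tooling.

Three passes:

1. a character scanner that blanks comments (preserving line structure),
   recognizes directive regions, and leaves string literals intact;
2. a line-oriented parser producing the :class:`FshDocument`;
3. interpretation passes — :func:`expand_rulesets` (textual macro
   substitution of ``{param}`` placeholders, recursive, cycle-checked) and
   :func:`interpret_metadata` (mapping rules onto the version-agnostic
   :class:`~fshterm.fhir_model.TermResourceMeta`).

Parsing is total: a call either returns a complete document or raises a
positioned :class:`~fshterm.errors.FshSyntaxError`; there is no partial
silent output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Any, Mapping

from .directives import (CLOSE_TOKEN, OPEN_TOKEN, DirectiveBlock,
                         DirectiveRegion, tokenize_arguments)
from .errors import (ArityMismatch, CycleError, FshSyntaxError, ModeError,
                     TypeMismatch, UnknownPath, UnknownRuleSet,
                     UnterminatedDirective)
from .fhir_model import (PROPERTY_TYPES, FhirMode, PropertyDeclaration,
                         TermResourceMeta)

log = logging.getLogger(__name__)

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_-]*$")
_PATH_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*(\[\d+\])?"
                      r"(\.[A-Za-z_][A-Za-z0-9_]*(\[\d+\])?)*$")
_KEYWORD_RE = re.compile(r"^([A-Za-z][A-Za-z]*)\s*:\s*(.*)$")
_INT_RE = re.compile(r"^[+-]?\d+$")
_DEC_RE = re.compile(r"^[+-]?\d+\.\d+$")
_DATETIME_RE = re.compile(r"^\d{4}(-\d{2}(-\d{2})?)?"
                          r"(T\d{2}:\d{2}(:\d{2}(\.\d+)?)?([+-]\d{2}:\d{2}|Z)?)?$")
_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_-]*)\}")

#: FSH keywords that exist in the full language but are outside this
#: terminology subset; they get a targeted rejection instead of a generic
#: syntax error.
_REJECTED_KEYWORDS = frozenset({
    "Profile", "Extension", "Logical", "Resource", "Mapping", "Invariant",
    "Parent", "Severity", "XPath", "Expression", "Source", "Target",
    "Context", "Characteristics",
})

_ITEM_KEYWORDS = frozenset({"CodeSystem", "ValueSet", "Instance"})
_MEMBER_KEYWORDS = frozenset({"Id", "Title", "Description", "InstanceOf",
                              "Usage"})


@dataclass
class TypedValue:
    """The value side of an FSH assignment rule.

    ``type_tag`` is one of ``string``, ``multiline_string``, ``code``,
    ``boolean``, ``integer``, ``decimal``, ``datetime``, ``canonical``.
    ``raw_text`` preserves the source spelling verbatim; ``parsed`` holds
    the typed payload (for codes, a ``(system, code, display)`` triple).
    """

    type_tag: str
    raw_text: str
    parsed: Any


@dataclass
class Rule:
    variant: str  # caret_value | plain_assignment | insert
    line: int
    path: str | None = None
    value: TypedValue | None = None
    ruleset_name: str | None = None
    arguments: list[str] = field(default_factory=list)
    origin_ruleset: str | None = None
    origin_line: int | None = None


@dataclass
class RuleSetDef:
    name: str
    parameters: list[str]
    body: list[tuple[int, str]]  # (source line, raw rule text)
    decl_line: int


@dataclass
class FshItem:
    kind: str  # codesystem | valueset | instance
    name: str
    decl_line: int
    instance_of: str | None = None
    usage: str | None = None
    keyword_meta: dict[str, str] = field(default_factory=dict)
    rules: list[Rule] = field(default_factory=list)
    directives: list[DirectiveBlock] = field(default_factory=list)

    @property
    def resource_kind(self) -> str:
        if self.kind == "instance":
            return "conceptmap"
        return self.kind


@dataclass
class FshDocument:
    source_path: str
    aliases: dict[str, str] = field(default_factory=dict)
    rulesets: dict[str, RuleSetDef] = field(default_factory=dict)
    items: list[FshItem] = field(default_factory=list)
    line_count: int = 0


# --------------------------------------------------------------------------
# Pass 1: scanner


def _scan(text: str) -> tuple[str, list[DirectiveRegion]]:
    """Blank comments out of the source, keeping line structure intact.

    Returns the cleaned text (same length; comment characters replaced by
    spaces, newlines preserved) and the directive regions found.  String
    literals are honored so that comment markers inside strings survive.
    """
    out: list[str] = []
    regions: list[DirectiveRegion] = []
    i = 0
    n = len(text)
    line = 1

    def blank(upto: int) -> None:
        nonlocal i, line
        while i < upto:
            ch = text[i]
            if ch == "\n":
                out.append("\n")
                line += 1
            else:
                out.append(" ")
            i += 1

    def copy(upto: int) -> None:
        nonlocal i, line
        while i < upto:
            ch = text[i]
            out.append(ch)
            if ch == "\n":
                line += 1
            i += 1

    while i < n:
        if text.startswith(OPEN_TOKEN, i):
            close = text.find(CLOSE_TOKEN, i + len(OPEN_TOKEN))
            if close < 0:
                raise UnterminatedDirective(
                    f"directive opened with '{OPEN_TOKEN}' is never closed",
                    line=line)
            start_line = line
            body = text[i + len(OPEN_TOKEN):close]
            end = close + len(CLOSE_TOKEN)
            start = i
            blank(end)
            regions.append(DirectiveRegion(
                start=start, end=end, start_line=start_line,
                end_line=line, raw_body=body))
            continue
        if text.startswith("/*", i):
            close = text.find("*/", i + 2)
            if close < 0:
                raise FshSyntaxError("unterminated block comment", line=line,
                                     column=1)
            blank(close + 2)
            continue
        # '//' starts a line comment only at line start or after
        # whitespace, so unquoted URLs (alias values) keep their scheme.
        if text.startswith("//", i) and (i == 0 or text[i - 1] in " \t\n"):
            nl = text.find("\n", i)
            blank(n if nl < 0 else nl)
            continue
        if text.startswith('"""', i):
            close = text.find('"""', i + 3)
            if close < 0:
                raise FshSyntaxError("unterminated multiline string",
                                     line=line, column=1)
            copy(close + 3)
            continue
        if text[i] == '"':
            j = i + 1
            while j < n:
                if text[j] == "\\":
                    j += 2
                    continue
                if text[j] == '"' or text[j] == "\n":
                    break
                j += 1
            if j >= n or text[j] == "\n":
                raise FshSyntaxError("unterminated string literal",
                                     line=line, column=1)
            copy(j + 1)
            continue
        copy(i + 1)
    return "".join(out), regions


# --------------------------------------------------------------------------
# Value parsing


def _unescape_string(body: str, line: int) -> str:
    out: list[str] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "\\":
            if i + 1 >= len(body):
                raise FshSyntaxError("dangling escape in string", line=line)
            nxt = body[i + 1]
            out.append({"n": "\n", "t": "\t", '"': '"', "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _trim_multiline(body: str) -> str:
    """Minimal-common-indent trimming for triple-quoted strings."""
    lines = body.split("\n")
    if lines and lines[0].strip() == "":
        lines = lines[1:]
    if lines and lines[-1].strip() == "":
        lines = lines[:-1]
    indents = [len(ln) - len(ln.lstrip()) for ln in lines if ln.strip()]
    cut = min(indents) if indents else 0
    return "\n".join(ln[cut:] if ln.strip() else "" for ln in lines)


def parse_value(raw: str, line: int, aliases: Mapping[str, str]) -> TypedValue:
    """Parse the right-hand side of an assignment rule into a TypedValue."""
    raw = raw.strip()
    if not raw:
        raise FshSyntaxError("missing value after '='", line=line)
    if raw.startswith('"""'):
        if not raw.endswith('"""') or len(raw) < 6:
            raise FshSyntaxError("malformed multiline string", line=line)
        return TypedValue("multiline_string", raw, _trim_multiline(raw[3:-3]))
    if raw.startswith('"'):
        if not raw.endswith('"') or len(raw) < 2:
            raise FshSyntaxError("unterminated string literal", line=line)
        return TypedValue("string", raw, _unescape_string(raw[1:-1], line))
    if raw in ("true", "false"):
        return TypedValue("boolean", raw, raw == "true")
    if _INT_RE.match(raw):
        return TypedValue("integer", raw, int(raw))
    if _DEC_RE.match(raw):
        return TypedValue("decimal", raw, float(raw))
    if _DATETIME_RE.match(raw):
        return TypedValue("datetime", raw, raw)
    if "#" in raw:
        return _parse_code(raw, line, aliases)
    if raw.startswith("$"):
        token = raw.split()[0]
        if token not in aliases:
            raise FshSyntaxError(f"unknown alias '{token}'", line=line)
        return TypedValue("canonical", raw, aliases[token])
    if "://" in raw or raw.startswith("urn:"):
        return TypedValue("canonical", raw, raw)
    raise FshSyntaxError(f"cannot parse value '{raw}'", line=line)


def _parse_code(raw: str, line: int, aliases: Mapping[str, str]) -> TypedValue:
    """Parse ``[system]#code ["display"]`` preserving the raw spelling."""
    system_part, _, rest = raw.partition("#")
    system = None
    if system_part:
        system_part = system_part.strip()
        if system_part.startswith("$"):
            if system_part not in aliases:
                raise FshSyntaxError(f"unknown alias '{system_part}'", line=line)
            system = aliases[system_part]
        else:
            system = system_part
    display = None
    if '"' in rest:
        code, _, disp = rest.partition('"')
        code = code.strip()
        if not disp.endswith('"'):
            raise FshSyntaxError("unterminated display string in code value",
                                 line=line)
        display = _unescape_string(disp[:-1], line)
    else:
        code = rest.strip()
    if not code:
        raise FshSyntaxError("empty code after '#'", line=line)
    return TypedValue("code", raw, (system, code, display))


# --------------------------------------------------------------------------
# Rule parsing


def _find_unquoted(text: str, needle: str) -> int:
    in_quote = False
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and in_quote:
            i += 2
            continue
        if ch == '"':
            in_quote = not in_quote
        elif not in_quote and text.startswith(needle, i):
            return i
        i += 1
    return -1


def _split_insert_args(argtext: str, line: int) -> list[str]:
    """Split insert-rule arguments on top-level commas.

    A literal ``,`` or ``)`` inside an argument must be escaped with a
    backslash; the escape is removed here.
    """
    args: list[str] = []
    current: list[str] = []
    i = 0
    while i < len(argtext):
        ch = argtext[i]
        if ch == "\\" and i + 1 < len(argtext):
            current.append(argtext[i + 1])
            i += 2
            continue
        if ch == ",":
            args.append("".join(current).strip())
            current = []
            i += 1
            continue
        current.append(ch)
        i += 1
    args.append("".join(current).strip())
    return args


def _parse_rule_text(text: str, line: int, aliases: Mapping[str, str],
                     item_kind: str) -> Rule:
    body = text.strip()
    if not body.startswith("*"):
        raise FshSyntaxError("rule must start with '*'", line=line, column=1)
    body = body[1:].strip()
    if body.startswith("insert "):
        rest = body[len("insert "):].strip()
        match = re.match(r"^([A-Za-z_][A-Za-z0-9_-]*)\s*(\((.*)\))?\s*$",
                         rest, re.DOTALL)
        if not match:
            raise FshSyntaxError(f"malformed insert rule '{body}'", line=line)
        name = match.group(1)
        args = (_split_insert_args(match.group(3), line)
                if match.group(2) is not None else [])
        if args == [""]:
            args = []
        return Rule(variant="insert", line=line, ruleset_name=name,
                    arguments=args)
    if body.startswith("#"):
        raise FshSyntaxError(
            "inline concept rules are not supported: CodeSystem content is "
            "generated by a plugin directive (/*^babelfsh ... ^babelfsh*/), "
            "not by FSH concept rules", line=line)
    caret = body.startswith("^")
    eq = _find_unquoted(body, "=")
    if eq < 0:
        raise FshSyntaxError(f"expected '=' in rule '{body}'", line=line,
                             column=text.index("*") + 1)
    path = body[1:eq].strip() if caret else body[:eq].strip()
    value_text = body[eq + 1:].strip()
    if not _PATH_RE.match(path):
        raise FshSyntaxError(f"malformed element path '{path}'", line=line)
    value = parse_value(value_text, line, aliases)
    if caret:
        if item_kind == "instance":
            raise FshSyntaxError(
                "caret rules are not used in Instance items; assign the "
                "element path directly", line=line)
        return Rule(variant="caret_value", line=line, path=path, value=value)
    if item_kind != "instance":
        raise FshSyntaxError(
            "plain assignment rules are only valid in Instance items; "
            "use '* ^path = value' for resource metadata", line=line)
    return Rule(variant="plain_assignment", line=line, path=path, value=value)


# --------------------------------------------------------------------------
# Pass 2: document parser


def _collect_logical_lines(lines: list[str]) -> list[tuple[int, str]]:
    """Join physical lines into logical lines, honoring multiline strings.

    A line with an odd number of triple-quote markers continues onto the
    following physical lines until the string closes.
    """
    logical: list[tuple[int, str]] = []
    i = 0
    while i < len(lines):
        start = i
        buf = lines[i]
        while buf.count('"""') % 2 == 1:
            i += 1
            if i >= len(lines):
                raise FshSyntaxError("unterminated multiline string",
                                     line=start + 1)
            buf += "\n" + lines[i]
        logical.append((start + 1, buf))
        i += 1
    return logical


def parse_document(text: str, source_path: str = "<string>") -> FshDocument:
    """Parse one source file into an :class:`FshDocument`.

    Comments are removed from rule content; directive comments are
    tokenized and attached to the lexically enclosing item.  Raises a
    positioned error on the first construct outside the supported subset.
    """
    if text.startswith("\ufeff"):
        text = text[1:]
    clean, regions = _scan(text)
    doc = FshDocument(source_path=source_path,
                      line_count=clean.count("\n") + (0 if clean.endswith("\n") or not clean else 1))

    lines = clean.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    doc.line_count = len(lines)

    current_item: FshItem | None = None
    current_ruleset: RuleSetDef | None = None
    # extents: (start_line, owner) where owner is an FshItem or RuleSetDef
    extents: list[tuple[int, object]] = []

    for lineno, raw in _collect_logical_lines(lines):
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.startswith("*"):
            if current_ruleset is not None:
                current_ruleset.body.append((lineno, raw))
                continue
            if current_item is None:
                raise FshSyntaxError("rule outside of any item", line=lineno,
                                     column=len(raw) - len(raw.lstrip()) + 1)
            current_item.rules.append(
                _parse_rule_text(raw, lineno, doc.aliases,
                                 current_item.kind))
            continue
        match = _KEYWORD_RE.match(stripped)
        if not match:
            raise FshSyntaxError(
                f"unrecognized line '{stripped[:40]}'", line=lineno,
                column=len(raw) - len(raw.lstrip()) + 1)
        keyword, rest = match.group(1), match.group(2).strip()
        if keyword in _REJECTED_KEYWORDS:
            raise FshSyntaxError(
                f"'{keyword}:' is valid FSH but outside this terminology "
                f"subset (CodeSystem, ValueSet, ConceptMap instances, "
                f"RuleSets and Aliases only)", line=lineno)
        if keyword == "Alias":
            current_item, current_ruleset = None, None
            _parse_alias(rest, lineno, doc)
            continue
        if keyword == "RuleSet":
            current_item = None
            current_ruleset = _parse_ruleset_header(rest, lineno, doc)
            extents.append((lineno, current_ruleset))
            continue
        if keyword in _ITEM_KEYWORDS:
            current_ruleset = None
            if not _IDENT_RE.match(rest):
                raise FshSyntaxError(f"invalid item name '{rest}'",
                                     line=lineno)
            kind = keyword.lower() if keyword != "Instance" else "instance"
            current_item = FshItem(kind=kind, name=rest, decl_line=lineno)
            doc.items.append(current_item)
            extents.append((lineno, current_item))
            continue
        if keyword in _MEMBER_KEYWORDS:
            if current_item is None:
                raise FshSyntaxError(f"'{keyword}:' outside of an item",
                                     line=lineno)
            _apply_member_keyword(current_item, keyword, rest, lineno,
                                  doc.aliases)
            continue
        raise FshSyntaxError(f"unknown keyword '{keyword}:'", line=lineno)

    for item in doc.items:
        if item.kind == "instance":
            if item.instance_of is None:
                raise FshSyntaxError(
                    f"Instance '{item.name}' lacks an InstanceOf declaration",
                    line=item.decl_line)
    for ruleset in doc.rulesets.values():
        _check_placeholders(ruleset)

    _attach_directives(doc, regions, extents)
    return doc


def _parse_alias(rest: str, lineno: int, doc: FshDocument) -> None:
    match = re.match(r"^(\$[A-Za-z_][A-Za-z0-9_-]*)\s*=\s*(\S+)$", rest)
    if not match:
        raise FshSyntaxError(
            "malformed alias; expected 'Alias: $name = uri'", line=lineno)
    name, uri = match.group(1), match.group(2)
    if name in doc.aliases:
        raise FshSyntaxError(f"duplicate alias '{name}'", line=lineno)
    doc.aliases[name] = uri


def _parse_ruleset_header(rest: str, lineno: int,
                          doc: FshDocument) -> RuleSetDef:
    match = re.match(r"^([A-Za-z_][A-Za-z0-9_-]*)\s*(\(([^)]*)\))?\s*$", rest)
    if not match:
        raise FshSyntaxError(f"malformed RuleSet declaration '{rest}'",
                             line=lineno)
    name = match.group(1)
    params = []
    if match.group(2) is not None:
        params = [p.strip() for p in match.group(3).split(",") if p.strip()]
        for p in params:
            if not _IDENT_RE.match(p):
                raise FshSyntaxError(f"invalid RuleSet parameter '{p}'",
                                     line=lineno)
    if name in doc.rulesets:
        raise FshSyntaxError(f"duplicate RuleSet '{name}'", line=lineno)
    ruleset = RuleSetDef(name=name, parameters=params, body=[],
                         decl_line=lineno)
    doc.rulesets[name] = ruleset
    return ruleset


def _check_placeholders(ruleset: RuleSetDef) -> None:
    declared = set(ruleset.parameters)
    for lineno, raw in ruleset.body:
        for match in _PLACEHOLDER_RE.finditer(raw):
            if match.group(1) not in declared:
                raise FshSyntaxError(
                    f"RuleSet '{ruleset.name}' uses placeholder "
                    f"'{{{match.group(1)}}}' which is not a declared "
                    f"parameter", line=lineno)


def _apply_member_keyword(item: FshItem, keyword: str, rest: str,
                          lineno: int, aliases: Mapping[str, str]) -> None:
    if keyword == "InstanceOf":
        if item.kind != "instance":
            raise FshSyntaxError("InstanceOf is only valid in Instance items",
                                 line=lineno)
        if rest != "ConceptMap":
            raise FshSyntaxError(
                f"Instance items are supported for ConceptMap only, "
                f"not '{rest}'", line=lineno)
        item.instance_of = rest
        return
    if keyword == "Usage":
        if item.kind != "instance":
            raise FshSyntaxError("Usage is only valid in Instance items",
                                 line=lineno)
        item.usage = rest
        return
    if keyword in item.keyword_meta:
        raise FshSyntaxError(f"'{keyword}:' given more than once for item "
                             f"'{item.name}'", line=lineno)
    if keyword in ("Title", "Description") and rest.startswith('"'):
        value = parse_value(rest, lineno, aliases)
        item.keyword_meta[keyword] = value.parsed
    else:
        item.keyword_meta[keyword] = rest


def _attach_directives(doc: FshDocument, regions: list[DirectiveRegion],
                       extents: list[tuple[int, object]]) -> None:
    for region in regions:
        owner: FshItem | None = None
        for start_line, candidate in extents:
            if start_line <= region.start_line:
                owner = candidate if isinstance(candidate, FshItem) else None
            else:
                break
        if owner is None:
            raise FshSyntaxError(
                "directive is not within the lexical extent of a "
                "CodeSystem, ValueSet or Instance item", line=region.start_line)
        plugin_id, argv = tokenize_arguments(region.raw_body,
                                             line=region.start_line)
        owner.directives.append(DirectiveBlock(
            plugin_id=plugin_id, argv=argv,
            start_line=region.start_line, end_line=region.end_line,
            owner_item=owner.name))


# --------------------------------------------------------------------------
# RuleSet expansion


def expand_rulesets(doc: FshDocument,
                    extra_rulesets: Mapping[str, RuleSetDef] | None = None
                    ) -> FshDocument:
    """Replace every insert rule by the referenced RuleSet's body.

    Substitution is purely textual on ``{param}`` placeholders before the
    substituted lines are re-parsed as rules; nested inserts expand
    recursively.  Each expanded rule records the RuleSet body line it came
    from (``origin_line``/``origin_ruleset``) and the insertion-site line
    (``line``).  The document is modified in place and returned.
    """
    namespace: dict[str, RuleSetDef] = dict(extra_rulesets or {})
    namespace.update(doc.rulesets)

    for item in doc.items:
        expanded: list[Rule] = []
        for rule in item.rules:
            if rule.variant == "insert":
                expanded.extend(_expand_insert(rule, namespace, doc.aliases,
                                               item.kind, stack=()))
            else:
                expanded.append(rule)
        item.rules = expanded
    return doc


def _expand_insert(rule: Rule, namespace: Mapping[str, RuleSetDef],
                   aliases: Mapping[str, str], item_kind: str,
                   stack: tuple[str, ...]) -> list[Rule]:
    name = rule.ruleset_name
    assert name is not None
    if name in stack:
        chain = " -> ".join(stack + (name,))
        raise CycleError(f"RuleSet insertion cycle: {chain}", line=rule.line)
    ruleset = namespace.get(name)
    if ruleset is None:
        known = ", ".join(sorted(namespace)) or "none defined"
        raise UnknownRuleSet(f"unknown RuleSet '{name}' (known: {known})",
                             line=rule.line)
    if len(rule.arguments) != len(ruleset.parameters):
        raise ArityMismatch(
            f"RuleSet '{name}' takes {len(ruleset.parameters)} parameter(s) "
            f"but {len(rule.arguments)} argument(s) were given",
            line=rule.line)
    substitutions = dict(zip(ruleset.parameters, rule.arguments))
    out: list[Rule] = []
    for body_line, raw in ruleset.body:
        text = _PLACEHOLDER_RE.sub(
            lambda m: substitutions.get(m.group(1), m.group(0)), raw)
        parsed = _parse_rule_text(text, rule.line, aliases, item_kind)
        if parsed.variant == "insert":
            out.extend(_expand_insert(parsed, namespace, aliases, item_kind,
                                      stack + (name,)))
        else:
            parsed.origin_ruleset = name
            parsed.origin_line = body_line
            out.append(parsed)
    return out


# --------------------------------------------------------------------------
# Metadata interpretation


#: First-class scalar metadata paths: path -> (attribute, accepted tags,
#: restricted resource kinds or None).
_SCALAR_PATHS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...] | None]] = {
    "url": ("url", ("canonical", "string"), None),
    "version": ("version", ("string", "integer", "decimal", "datetime"), None),
    "name": ("name", ("string",), None),
    "title": ("title", ("string",), None),
    "status": ("status", ("code",), None),
    "experimental": ("experimental", ("boolean",), None),
    "date": ("date", ("datetime", "string"), None),
    "publisher": ("publisher", ("string",), None),
    "description": ("description", ("string", "multiline_string"), None),
    "copyright": ("copyright", ("string", "multiline_string"), None),
    "content": ("content_mode", ("code",), ("codesystem",)),
    "caseSensitive": ("case_sensitive", ("boolean",), ("codesystem",)),
    "hierarchyMeaning": ("hierarchy_meaning", ("code",), ("codesystem",)),
}

#: Recognized FHIR paths outside the first-class set, retained verbatim as
#: generic extras: head -> restricted resource kinds (or None for all).
_GENERIC_HEADS: dict[str, tuple[str, ...] | None] = {
    "purpose": None,
    "contact": None,
    "immutable": ("valueset",),
    "compositional": ("codesystem",),
    "versionNeeded": ("codesystem",),
    "supplements": ("codesystem",),
    "valueSet": ("codesystem",),
}

#: R5-only metadata heads; list-valued ones get an implicit [0] index.
_R5_HEADS = frozenset({
    "editor", "reviewer", "author", "endorser", "topic", "copyrightLabel",
    "approvalDate", "lastReviewDate", "effectivePeriod", "relatedArtifact",
    "versionAlgorithmString", "versionAlgorithmCoding",
    "sourceScopeUri", "sourceScopeCanonical", "targetScopeUri",
    "targetScopeCanonical",
})
_R5_LIST_HEADS = frozenset({"editor", "reviewer", "author", "endorser",
                            "topic", "relatedArtifact"})
#: ConceptMap scope heads that only exist in R4B.
_R4B_ONLY_HEADS = frozenset({"sourceUri", "sourceCanonical", "targetUri",
                             "targetCanonical"})


def _plain(value: TypedValue) -> Any:
    """Collapse a TypedValue to the plain JSON-ready payload."""
    if value.type_tag == "code":
        return value.parsed[1]
    return value.parsed


def interpret_metadata(item: FshItem, mode: FhirMode) -> TermResourceMeta:
    """Map an item's keywords and rules onto a :class:`TermResourceMeta`.

    Later rules on the same path overwrite earlier ones (standard FSH
    assignment semantics); an info-level log line records each overwrite.
    R5-only paths under R4B mode raise :class:`ModeError`; paths outside
    the supported metadata surface raise :class:`UnknownPath`.
    """
    kind = item.resource_kind
    meta = TermResourceMeta(resource_kind=kind, name=item.name,
                            source_path=None, decl_line=item.decl_line)
    if "Id" in item.keyword_meta:
        meta.id = item.keyword_meta["Id"]
    if "Title" in item.keyword_meta:
        meta.title = item.keyword_meta["Title"]
    if "Description" in item.keyword_meta:
        meta.description = item.keyword_meta["Description"]

    identifier_parts: dict[int, dict[str, Any]] = {}
    property_parts: dict[int, dict[str, Any]] = {}
    seen_paths: set[str] = set()

    for rule in item.rules:
        if rule.variant == "insert":
            raise ValueError(
                f"item '{item.name}' still contains an unexpanded insert "
                f"rule at line {rule.line}; call expand_rulesets first")
        path = rule.path or ""
        value = rule.value
        assert value is not None
        if path in seen_paths:
            log.info("rule on '%s' at line %d overrides an earlier value",
                     path, rule.line)
        seen_paths.add(path)
        _apply_metadata_rule(meta, kind, path, value, rule.line, mode,
                             identifier_parts, property_parts)

    meta.identifiers = [identifier_parts[i] for i in sorted(identifier_parts)]
    meta.property_declarations = _finish_property_declarations(
        property_parts, item)
    return meta


def _apply_metadata_rule(meta: TermResourceMeta, kind: str, path: str,
                         value: TypedValue, line: int, mode: FhirMode,
                         identifier_parts: dict[int, dict[str, Any]],
                         property_parts: dict[int, dict[str, Any]]) -> None:
    head_match = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)(\[(\d+)\])?(\.(.+))?$",
                          path)
    if not head_match:
        raise UnknownPath(f"unsupported metadata path '{path}'", line=line)
    head = head_match.group(1)
    index = int(head_match.group(3)) if head_match.group(3) else None
    tail = head_match.group(5)

    if head in _R5_HEADS:
        if mode is not FhirMode.R5:
            raise ModeError(
                f"'{path}' is an R5-only element; it is unknown to the R4B "
                f"schema — compile with the R5 mode to use it", line=line)
        norm = path
        if head in _R5_LIST_HEADS and index is None:
            norm = f"{head}[0]" + (f".{tail}" if tail else "")
        meta.r5_extras[norm] = _plain(value)
        return
    if head in _R4B_ONLY_HEADS:
        if kind != "conceptmap":
            raise UnknownPath(f"'{path}' is a ConceptMap element", line=line)
        if mode is not FhirMode.R4B:
            raise ModeError(
                f"'{path}' exists only in R4B; R5 uses the sourceScope/"
                f"targetScope elements", line=line)
        meta.generic_extras[path] = _plain(value)
        return

    if head == "identifier":
        idx = index if index is not None else 0
        if not tail or tail not in ("system", "value", "use"):
            raise UnknownPath(
                f"unsupported identifier sub-path '{path}'", line=line)
        identifier_parts.setdefault(idx, {})[tail] = _plain(value)
        return
    if head == "property" and kind == "codesystem":
        idx = index if index is not None else 0
        if not tail or tail not in ("code", "uri", "type"):
            raise UnknownPath(
                f"unsupported property declaration sub-path '{path}'",
                line=line)
        expected = {"code": ("code",), "type": ("code",),
                    "uri": ("canonical", "string")}[tail]
        if value.type_tag not in expected:
            raise TypeMismatch(
                f"property {tail} must be a {' or '.join(expected)} value, "
                f"got {value.type_tag}", line=line)
        property_parts.setdefault(idx, {"line": line})[tail] = _plain(value)
        return

    if head in _SCALAR_PATHS and tail is None and index is None:
        attr, accepted, kinds = _SCALAR_PATHS[head]
        if kinds is not None and kind not in kinds:
            raise UnknownPath(
                f"'{path}' is not an element of {meta.resource_type}",
                line=line)
        if value.type_tag not in accepted:
            raise TypeMismatch(
                f"'{path}' expects a {' or '.join(accepted)} value, got "
                f"{value.type_tag} ({value.raw_text})", line=line)
        payload = _plain(value)
        if head == "version" and value.type_tag != "string":
            payload = value.raw_text
        setattr(meta, attr, payload)
        return

    if head in _GENERIC_HEADS:
        kinds = _GENERIC_HEADS[head]
        if kinds is not None and kind not in kinds:
            raise UnknownPath(
                f"'{path}' is not an element of {meta.resource_type}",
                line=line)
        meta.generic_extras[path] = _plain(value)
        return

    raise UnknownPath(
        f"'{path}' is not in the supported metadata surface for "
        f"{meta.resource_type} items", line=line)


def _finish_property_declarations(parts: dict[int, dict[str, Any]],
                                  item: FshItem) -> list[PropertyDeclaration]:
    declarations: list[PropertyDeclaration] = []
    seen: set[str] = set()
    for idx in sorted(parts):
        part = parts[idx]
        line = part.pop("line", item.decl_line)
        if "code" not in part:
            raise FshSyntaxError(
                f"property declaration [{idx}] of '{item.name}' has no "
                f"^property[{idx}].code rule", line=line)
        ptype = part.get("type", "code")
        if ptype not in PROPERTY_TYPES:
            raise TypeMismatch(
                f"property type '{ptype}' is not one of "
                f"{', '.join(PROPERTY_TYPES)}", line=line)
        if part["code"] in seen:
            raise FshSyntaxError(
                f"duplicate property declaration '{part['code']}'", line=line)
        seen.add(part["code"])
        declarations.append(PropertyDeclaration(
            code=part["code"], type=ptype, uri=part.get("uri")))
    return declarations
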