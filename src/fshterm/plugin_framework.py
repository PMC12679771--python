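"""Plugin contract, registry, typed argument parsing and help generation.

A content plugin converts an external terminology source into
version-agnostic proxy content: concept entries for a CodeSystem, compose
entries for a ValueSet, or groups for a ConceptMap.  Plugins never build
serialized FHIR — assembly and mode-specific serialization happen in
:mod:`fshterm.fhir_model`.

A plugin implements exactly two responsibilities:

* declare its arguments (a :class:`PluginDescriptor` with
  :class:`ArgumentSpec` entries, each carrying mandatory help text), and
* generate content from the parsed, type-checked arguments.

The framework owns everything around that: id-based lookup, shell-style
argument parsing with long/short flags, repeatable flags, defaults,
mutually-exclusive groups, and deterministic help rendering — so argument
misuse produces detailed feedback without any per-plugin effort.

Built-in plugins are registered statically; third-party plugins are
discovered through ``importlib.metadata`` entry points in the group
``fshterm.plugins`` (each entry point resolves to a ``ContentPlugin``
subclass or factory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.metadata import entry_points
from pathlib import Path
from typing import Any, Callable

from .errors import (ArgumentValueError, MissingRequired, MutexViolation,
                     PluginError, RegistryError, UnknownFlag, UnknownPlugin)
from .fhir_model import TermResourceMeta

ENTRY_POINT_GROUP = "fshterm.plugins"

VALUE_KINDS = ("string", "integer", "path", "choice", "flag",
               "key_value_pair")


@dataclass
class ArgumentSpec:
    """Declaration of one plugin argument.

    ``value_kind`` is one of :data:`VALUE_KINDS`; ``choice`` requires
    ``choices``.  ``key_value_pair`` arguments use ``NAME=VALUE`` syntax
    and are delivered to the plugin as ``(name, value)`` tuples.
    """

    long_flag: str
    help_text: str
    short_flag: str | None = None
    value_kind: str = "string"
    choices: tuple[str, ...] = ()
    repeatable: bool = False
    required: bool = False
    default: Any = None
    mutex_group: str | None = None

    def __post_init__(self) -> None:
        if not self.long_flag.startswith("--"):
            raise ValueError(f"long flag must start with '--': {self.long_flag}")
        if self.short_flag is not None and not (
                self.short_flag.startswith("-") and len(self.short_flag) == 2):
            raise ValueError(f"short flag must look like '-x': {self.short_flag}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind '{self.value_kind}'")
        if self.value_kind == "choice" and not self.choices:
            raise ValueError(f"{self.long_flag}: choice kind requires choices")
        if not self.help_text.strip():
            raise ValueError(f"{self.long_flag}: help text is mandatory")
        if self.required and self.default is not None:
            raise ValueError(f"{self.long_flag}: required arguments take no default")
        if self.value_kind == "flag" and self.required:
            raise ValueError(f"{self.long_flag}: a flag cannot be required")


@dataclass
class PluginDescriptor:
    """Identity and argument surface of one plugin."""

    plugin_id: str
    summary: str
    supported_kinds: frozenset[str]  # subset of codesystem/valueset/conceptmap
    arguments: list[ArgumentSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        longs: set[str] = set()
        shorts: set[str] = set()
        for spec in self.arguments:
            if spec.long_flag in longs:
                raise ValueError(f"duplicate flag {spec.long_flag} in "
                                 f"plugin '{self.plugin_id}'")
            longs.add(spec.long_flag)
            if spec.short_flag is not None:
                if spec.short_flag in shorts:
                    raise ValueError(f"duplicate short flag {spec.short_flag} "
                                     f"in plugin '{self.plugin_id}'")
                shorts.add(spec.short_flag)


@dataclass
class ParsedArgs:
    """Typed argument values keyed by long flag, with provenance."""

    values: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # given|default

    def __getitem__(self, flag: str) -> Any:
        return self.values[flag]

    def get(self, flag: str, fallback: Any = None) -> Any:
        return self.values.get(flag, fallback)

    def given(self, flag: str) -> bool:
        return self.provenance.get(flag) == "given"


@dataclass
class ContentBundle:
    """Kind-discriminated proxy content produced by a plugin.

    ``options`` carries plugin decisions downstream consumers may need
    (e.g. whether dangling parents were explicitly tolerated, so the
    structural validator downgrades its check to a warning).
    """

    kind: str  # codesystem | valueset | conceptmap
    payload: list[Any] = field(default_factory=list)
    options: dict[str, Any] = field(default_factory=dict)


class ContentPlugin:
    """Base class for content plugins: declare arguments, generate content."""

    def descriptor(self) -> PluginDescriptor:
        raise NotImplementedError

    def generate(self, args: ParsedArgs, meta: TermResourceMeta,
                 kind: str) -> ContentBundle:
        raise NotImplementedError


# --------------------------------------------------------------------------
# Registry


class PluginRegistry:
    """Id-keyed plugin registry with exact-match lookup."""

    def __init__(self) -> None:
        self._plugins: dict[str, ContentPlugin] = {}

    def register(self, plugin: ContentPlugin) -> None:
        descriptor = plugin.descriptor()
        pid = descriptor.plugin_id
        if pid in self._plugins:
            raise RegistryError(f"plugin id '{pid}' registered twice")
        self._plugins[pid] = plugin

    def discover(self) -> None:
        """Register third-party plugins from entry points."""
        for ep in entry_points(group=ENTRY_POINT_GROUP):
            obj = ep.load()
            plugin = obj() if isinstance(obj, type) or callable(obj) else obj
            self.register(plugin)

    @property
    def plugin_ids(self) -> list[str]:
        return sorted(self._plugins)

    def resolve(self, plugin_id: str) -> ContentPlugin:
        try:
            return self._plugins[plugin_id]
        except KeyError:
            available = ", ".join(self.plugin_ids) or "none"
            raise UnknownPlugin(
                f"unknown plugin '{plugin_id}' (registered plugins: "
                f"{available})") from None


def default_registry() -> PluginRegistry:
    """Registry with the built-in plugins plus discovered third parties."""
    from .plugins import BUILTIN_PLUGINS
    registry = PluginRegistry()
    for factory in BUILTIN_PLUGINS:
        registry.register(factory())
    registry.discover()
    return registry


def resolve_plugin(plugin_id: str,
                   registry: PluginRegistry | None = None) -> PluginDescriptor:
    """Exact-match descriptor lookup; raises :class:`UnknownPlugin`."""
    registry = registry or default_registry()
    return registry.resolve(plugin_id).descriptor()


# --------------------------------------------------------------------------
# Argument parsing


def _convert(spec: ArgumentSpec, token: str, line: int | None) -> Any:
    kind = spec.value_kind
    if kind == "string":
        return token
    if kind == "integer":
        try:
            return int(token)
        except ValueError:
            raise ArgumentValueError(
                f"{spec.long_flag} expects an integer, got '{token}'",
                line=line) from None
    if kind == "path":
        return Path(token)
    if kind == "choice":
        if token not in spec.choices:
            raise ArgumentValueError(
                f"{spec.long_flag} must be one of "
                f"{', '.join(spec.choices)}; got '{token}'", line=line)
        return token
    if kind == "key_value_pair":
        name, sep, value = token.partition("=")
        if not sep or not name:
            raise ArgumentValueError(
                f"{spec.long_flag} expects NAME=VALUE, got '{token}'",
                line=line)
        return (name, value)
    raise AssertionError(kind)


def parse_args(descriptor: PluginDescriptor, argv: list[str],
               *, line: int | None = None) -> ParsedArgs:
    """Parse a directive argument vector against a plugin's declaration.

    Long and short flags are both accepted; repeatable flags accumulate in
    order; defaults fill absent optional arguments; at most one member of
    a mutex group may be given.  Errors echo the argument's help text so
    the user gets actionable feedback.
    """
    by_flag: dict[str, ArgumentSpec] = {}
    for spec in descriptor.arguments:
        by_flag[spec.long_flag] = spec
        if spec.short_flag:
            by_flag[spec.short_flag] = spec

    parsed = ParsedArgs()
    given_mutex: dict[str, str] = {}
    i = 0
    while i < len(argv):
        token = argv[i]
        spec = by_flag.get(token)
        if spec is None:
            raise UnknownFlag(
                f"plugin '{descriptor.plugin_id}' does not accept '{token}'",
                line=line)
        if spec.mutex_group is not None:
            other = given_mutex.get(spec.mutex_group)
            if other is not None and other != spec.long_flag:
                raise MutexViolation(
                    f"{other} and {spec.long_flag} are mutually exclusive",
                    line=line)
            given_mutex[spec.mutex_group] = spec.long_flag
        if spec.value_kind == "flag":
            value: Any = True
            i += 1
        else:
            if i + 1 >= len(argv):
                raise ArgumentValueError(
                    f"{spec.long_flag} requires a value ({spec.help_text})",
                    line=line)
            value = _convert(spec, argv[i + 1], line)
            i += 2
        if spec.repeatable:
            parsed.values.setdefault(spec.long_flag, []).append(value)
        else:
            parsed.values[spec.long_flag] = value
        parsed.provenance[spec.long_flag] = "given"

    for spec in descriptor.arguments:
        if spec.long_flag in parsed.values:
            continue
        if spec.required:
            raise MissingRequired(
                f"{spec.long_flag} is required: {spec.help_text}", line=line)
        if spec.value_kind == "flag":
            parsed.values[spec.long_flag] = False
            parsed.provenance[spec.long_flag] = "default"
        elif spec.repeatable:
            parsed.values[spec.long_flag] = (
                list(spec.default) if spec.default else [])
            parsed.provenance[spec.long_flag] = "default"
        elif spec.default is not None:
            parsed.values[spec.long_flag] = spec.default
            parsed.provenance[spec.long_flag] = "default"
    return parsed


# --------------------------------------------------------------------------
# Help rendering


def render_help(descriptor: PluginDescriptor) -> str:
    """Deterministic plain-text help generated from the argument specs."""
    lines = [f"{descriptor.plugin_id} — {descriptor.summary}",
             f"supported kinds: "
             f"{', '.join(sorted(descriptor.supported_kinds))}"]
    if descriptor.arguments:
        lines.append("arguments:")
    for spec in descriptor.arguments:
        flags = spec.long_flag
        if spec.short_flag:
            flags += f", {spec.short_flag}"
        qualifiers = [spec.value_kind]
        if spec.value_kind == "choice":
            qualifiers.append("one of: " + "|".join(spec.choices))
        if spec.required:
            qualifiers.append("required")
        elif spec.value_kind != "flag" and spec.default is not None:
            qualifiers.append(f"default: {spec.default}")
        if spec.repeatable:
            qualifiers.append("repeatable")
        lines.append(f"  {flags}  ({'; '.join(qualifiers)})")
        lines.append(f"      {spec.help_text}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Dispatch


def generate_content(plugin: ContentPlugin, parsed: ParsedArgs,
                     meta: TermResourceMeta, kind: str) -> ContentBundle:
    """Dispatch to the plugin's content method with error wrapping.

    Compiler-typed errors raised by the plugin (missing file, ragged row,
    ...) propagate unchanged so their specific codes survive; anything
    else is wrapped in :class:`PluginError` carrying the plugin id.
    """
    descriptor = plugin.descriptor()
    if kind not in descriptor.supported_kinds:
        raise PluginError(
            f"plugin '{descriptor.plugin_id}' does not support "
            f"{kind} items (supported: "
            f"{', '.join(sorted(descriptor.supported_kinds))})")
    from .errors import CompileError
    try:
        bundle = plugin.generate(parsed, meta, kind)
    except CompileError:
        raise
    except Exception as exc:
        raise PluginError(
            f"plugin '{descriptor.plugin_id}' failed for item "
            f"'{meta.name}': {exc}") from exc
    if bundle.kind != kind:
        raise PluginError(
            f"plugin '{descriptor.plugin_id}' returned a {bundle.kind} "
            f"bundle for a {kind} item")
    return bundle
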