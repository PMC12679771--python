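"""Command-line application: source discovery, compilation, output writing.

The pipeline per source file: parse → expand RuleSets → per item:
interpret metadata → resolve the directive's plugin → parse its arguments
→ generate content → assemble → validate → serialize → write.  Items
compile independently: one item's failure never aborts its siblings
unless ``--fail-fast`` is set.  RuleSets share a single project-wide
namespace across all source files, so common metadata can be factored
into one file and inserted everywhere.

Exit codes: 0 — everything compiled without errors; 1 — at least one
compile or validation error; 2 — command-line usage error.  All
diagnostics go to standard error.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click

from .directives import DirectiveBlock
from .errors import (CompileError, MissingDirective, MultipleDirectives,
                     NoSources, OutputCollision, PathMissing)
from .fhir_model import FhirMode, TermResourceMeta, assemble, serialize
from .fsh_core import (FshDocument, FshItem, RuleSetDef, expand_rulesets,
                       interpret_metadata, parse_document)
from .plugin_framework import (PluginRegistry, default_registry,
                               generate_content, parse_args, render_help)
from .validation import Issue, validate_structural

log = logging.getLogger("fshterm")

SOURCE_EXTENSIONS = (".babel.fsh", ".babelfsh.fsh")


@dataclass
class CompileConfig:
    inputs: list[Path]
    fhir_mode: FhirMode
    out_dir: Path = Path("out")
    deep_validate: str | None = None
    fail_fast: bool = False
    findings_path: Path | None = None


@dataclass
class CompileResult:
    written: list[Path] = field(default_factory=list)
    issues: list[Issue] = field(default_factory=list)
    skipped_items: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(issue.blocks_output for issue in self.issues)


def _matches_extension(path: Path) -> bool:
    name = path.name
    return any(name.endswith(ext) for ext in SOURCE_EXTENSIONS)


def discover_sources(paths: list[Path]) -> list[Path]:
    """Resolve input paths to the ordered list of source files.

    Directories are scanned recursively; only files with the
    ``.babel.fsh`` / ``.babelfsh.fsh`` extensions are considered, sorted
    lexicographically by path for determinism.  Explicitly listed files
    must match the extensions too.
    """
    found: list[Path] = []
    for path in paths:
        if path.is_dir():
            found.extend(p for p in path.rglob("*")
                         if p.is_file() and _matches_extension(p))
        elif path.is_file():
            if not _matches_extension(path):
                raise PathMissing(
                    f"{path} does not have a recognized source extension "
                    f"({' or '.join(SOURCE_EXTENSIONS)})", path=str(path))
            found.append(path)
        else:
            raise PathMissing(f"input path does not exist: {path}",
                              path=str(path))
    found = sorted(set(found), key=lambda p: str(p))
    if not found:
        raise NoSources(
            f"no source files matching {' or '.join(SOURCE_EXTENSIONS)} "
            f"found under the given paths")
    return found


def _issue_from_error(exc: CompileError, source_file: str) -> Issue:
    return Issue(severity="error", code=exc.code, message=exc.message,
                 source_file=exc.path or source_file, line=exc.line)


def _compile_item(item: FshItem, doc: FshDocument, config: CompileConfig,
                  registry: PluginRegistry,
                  result: CompileResult) -> tuple[str, bytes] | None:
    """Compile one item to (filename, serialized bytes); None on failure
    or when the item was skipped (``--help`` directive)."""
    source = doc.source_path
    meta = interpret_metadata(item, config.fhir_mode)
    meta.source_path = source

    if len(item.directives) == 0:
        raise MissingDirective(
            f"item '{item.name}' has no content directive; every item "
            f"needs exactly one /*^babelfsh ... ^babelfsh*/ comment",
            line=item.decl_line)
    if len(item.directives) > 1:
        raise MultipleDirectives(
            f"item '{item.name}' has {len(item.directives)} directives; "
            f"exactly one is allowed",
            line=item.directives[1].start_line)
    directive: DirectiveBlock = item.directives[0]

    try:
        plugin = registry.resolve(directive.plugin_id)
        descriptor = plugin.descriptor()
        if directive.argv == ["--help"]:
            sys.stderr.write(render_help(descriptor))
            result.skipped_items.append(item.name)
            return None
        parsed = parse_args(descriptor, directive.argv,
                            line=directive.start_line)
        _resolve_path_args(parsed, descriptor, Path(source).parent)
        bundle = generate_content(plugin, parsed, meta, item.resource_kind)
    except CompileError as exc:
        # errors with no location of their own point at the directive
        if exc.line is None and exc.path is None:
            exc.line = directive.start_line
        raise

    resource = assemble(meta, bundle, config.fhir_mode)
    line_index = {}
    if item.resource_kind == "codesystem":
        def collect(entries):
            for entry in entries:
                if entry.source_line is not None:
                    line_index.setdefault(entry.code, entry.source_line)
                collect(entry.children)
        collect(bundle.payload)
    issues = validate_structural(
        resource, config.fhir_mode, line_index=line_index,
        allow_dangling_parents=bundle.options.get("allow_dangling_parents",
                                                  False),
        source_file=source)
    result.issues.extend(issues)
    if any(issue.blocks_output for issue in issues):
        return None
    resource_id = meta.id or meta.name
    filename = f"{meta.resource_type}-{resource_id}.json"
    return filename, serialize(resource, config.fhir_mode)


def compile_file(path: Path, config: CompileConfig,
                 registry: PluginRegistry | None = None,
                 extra_rulesets: dict[str, RuleSetDef] | None = None
                 ) -> CompileResult:
    """Compile a single source file (convenience over compile_project)."""
    return compile_project(
        CompileConfig(inputs=[path], fhir_mode=config.fhir_mode,
                      out_dir=config.out_dir,
                      deep_validate=config.deep_validate,
                      fail_fast=config.fail_fast,
                      findings_path=config.findings_path),
        registry=registry)


def compile_project(config: CompileConfig,
                    registry: PluginRegistry | None = None) -> CompileResult:
    """Compile every source under the configured inputs.

    Returns the written files and all issues.  Output files are written
    only for items whose validation produced no errors.
    """
    registry = registry or default_registry()
    result = CompileResult()
    try:
        sources = discover_sources(config.inputs)
    except CompileError as exc:
        result.issues.append(_issue_from_error(exc, ""))
        return result

    docs: list[FshDocument] = []
    for source in sources:
        try:
            raw = source.read_bytes().decode("utf-8")
            docs.append(parse_document(raw, source_path=str(source)))
        except UnicodeDecodeError as exc:
            result.issues.append(Issue(
                severity="error", code="decode-error",
                message=f"{source} is not valid UTF-8 at byte {exc.start}",
                source_file=str(source)))
            if config.fail_fast:
                return result
        except CompileError as exc:
            result.issues.append(_issue_from_error(exc, str(source)))
            if config.fail_fast:
                return result

    # Project-wide RuleSet namespace; duplicate names across files clash.
    namespace: dict[str, RuleSetDef] = {}
    owners: dict[str, str] = {}
    for doc in docs:
        for name, ruleset in doc.rulesets.items():
            if name in namespace:
                result.issues.append(Issue(
                    severity="error", code="duplicate-ruleset",
                    message=(f"RuleSet '{name}' defined in both "
                             f"{owners[name]} and {doc.source_path}"),
                    source_file=doc.source_path, line=ruleset.decl_line))
            else:
                namespace[name] = ruleset
                owners[name] = doc.source_path

    outputs: dict[str, tuple[bytes, str]] = {}
    for doc in docs:
        try:
            expand_rulesets(doc, extra_rulesets=namespace)
        except CompileError as exc:
            result.issues.append(_issue_from_error(exc, doc.source_path))
            if config.fail_fast:
                break
            continue
        for item in doc.items:
            try:
                compiled = _compile_item(item, doc, config, registry, result)
            except CompileError as exc:
                result.issues.append(_issue_from_error(exc, doc.source_path))
                if config.fail_fast:
                    return _finish(result, outputs, config)
                continue
            if compiled is None:
                continue
            filename, payload = compiled
            if filename in outputs:
                result.issues.append(Issue(
                    severity="error", code=OutputCollision.code,
                    message=(f"output file {filename} produced by more than "
                             f"one item"),
                    source_file=doc.source_path, line=item.decl_line))
                continue
            outputs[filename] = (payload, doc.source_path)
    return _finish(result, outputs, config)


def _finish(result: CompileResult, outputs: dict[str, tuple[bytes, str]],
            config: CompileConfig) -> CompileResult:
    config.out_dir.mkdir(parents=True, exist_ok=True)
    for filename, (payload, _source) in outputs.items():
        target = config.out_dir / filename
        target.write_bytes(payload)
        result.written.append(target)
        log.info("wrote %s (%d bytes)", target, len(payload))
    if config.deep_validate:
        _run_deep_validation(result, config)
    if config.findings_path:
        with open(config.findings_path, "w", encoding="utf-8") as fh:
            for issue in result.issues:
                fh.write(issue.to_json() + "\n")
    for issue in result.issues:
        log.log(logging.ERROR if issue.blocks_output else logging.WARNING,
                "[%s] %s%s", issue.code, issue.message,
                f" ({issue.source_file}:{issue.line})"
                if issue.source_file and issue.line else "")
    return result


def _run_deep_validation(result: CompileResult,
                         config: CompileConfig) -> None:
    """Opt-in hook: run an external validator command on each written file.

    Failures are relayed as warnings and never terminate the run.
    """
    base = shlex.split(config.deep_validate or "")
    for path in result.written:
        try:
            proc = subprocess.run(base + [str(path)], capture_output=True,
                                  text=True)
        except OSError as exc:
            result.issues.append(Issue(
                severity="warning", code="deep-validation",
                message=f"deep validation command failed to start: {exc}"))
            return
        if proc.returncode != 0:
            result.issues.append(Issue(
                severity="warning", code="deep-validation",
                message=(f"external validator exited {proc.returncode} for "
                         f"{path.name}: {proc.stderr.strip()[:500]}")))


def _resolve_path_args(parsed, descriptor, base_dir: Path) -> None:
    """Resolve relative path-kind arguments against the source file's
    directory, not the working directory."""
    kinds = {spec.long_flag: spec.value_kind for spec in descriptor.arguments}
    for flag, value in list(parsed.values.items()):
        if kinds.get(flag) != "path" or value is None:
            continue
        if isinstance(value, list):
            parsed.values[flag] = [
                v if Path(v).is_absolute() else base_dir / v for v in value]
        else:
            path = Path(value)
            parsed.values[flag] = path if path.is_absolute() else base_dir / path


# --------------------------------------------------------------------------
# CLI


@click.group()
@click.option("--log-level", default="info",
              type=click.Choice(["debug", "info", "warning", "error"]),
              help="verbosity of diagnostics on standard error")
def cli(log_level: str) -> None:
    """Compile FSH-dialect terminology sources to FHIR JSON."""
    logging.basicConfig(stream=sys.stderr,
                        format="%(levelname)s %(message)s",
                        level=getattr(logging, log_level.upper()))


@cli.command("compile")
@click.argument("inputs", nargs=-1, required=True,
                type=click.Path(path_type=Path))
@click.option("--fhir-version", "fhir_version", required=True,
              type=click.Choice(["r4b", "r5"]),
              help="FHIR version of the generated resources (one per run)")
@click.option("--out", "out_dir", default=Path("out"),
              type=click.Path(path_type=Path), show_default=True,
              help="output directory for the generated JSON files")
@click.option("--deep-validate", "deep_validate", default=None,
              help="external validator command to run on each written file "
                   "(opt-in; failures are warnings)")
@click.option("--fail-fast", is_flag=True,
              help="stop at the first failing item")
@click.option("--findings", "findings_path", default=None,
              type=click.Path(path_type=Path),
              help="write issues as JSON lines to this file")
@click.pass_context
def compile_cmd(ctx: click.Context, inputs: tuple[Path, ...],
                fhir_version: str, out_dir: Path,
                deep_validate: str | None, fail_fast: bool,
                findings_path: Path | None) -> None:
    """Compile source files or directories to FHIR JSON resources."""
    config = CompileConfig(inputs=list(inputs),
                           fhir_mode=FhirMode(fhir_version),
                           out_dir=out_dir, deep_validate=deep_validate,
                           fail_fast=fail_fast, findings_path=findings_path)
    result = compile_project(config)
    for path in result.written:
        click.echo(str(path))
    if not result.ok:
        ctx.exit(1)


@cli.command("fixtures")
@click.option("--layout", type=click.Choice(["hierarchy_csv", "alpha_like"]),
              default="hierarchy_csv", show_default=True,
              help="synthetic table layout to generate")
@click.option("--rows", type=int, default=33, show_default=True)
@click.option("--seed", type=int, default=42, show_default=True)
@click.option("--out", "out_path", required=True,
              type=click.Path(path_type=Path),
              help="path of the table file to write; the manifest goes to "
                   "<out>.manifest.json")
def fixtures_cmd(layout: str, rows: int, seed: int, out_path: Path) -> None:
    """Generate a deterministic synthetic terminology table."""
    from .fixtures import FixtureSpec, generate_table
    spec = FixtureSpec(rows=rows, seed=seed, layout=layout)
    manifest = generate_table(spec, out_path)
    click.echo(json.dumps(manifest.to_dict(), indent=2))


def main(argv: list[str] | None = None) -> int:
    """Entry point returning a process exit code (0 ok, 1 errors, 2 usage)."""
    try:
        rv = cli.main(args=argv, standalone_mode=False)
        if isinstance(rv, int):
            return rv
    except click.UsageError as exc:
        exc.show(file=sys.stderr)
        return 2
    except click.exceptions.Exit as exc:
        return exc.exit_code
    except click.Abort:
        return 130
    except CompileError as exc:
        sys.stderr.write(f"error: {exc}\n")
        return 1
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
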