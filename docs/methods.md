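# Methods

This note documents the language, the conversion model, the validation
semantics and the deliberate design decisions of `fshterm`, in the order
a resource flows through the pipeline: parse → expand → interpret →
generate → assemble → validate → serialize.

## The FSH subset

The parser accepts a strict subset of FHIR Shorthand chosen so that any
accepted source file is also a valid file for stock FSH tooling:

* `Alias: $name = uri` declarations;
* `CodeSystem:` and `ValueSet:` items;
* `Instance:` items with `InstanceOf: ConceptMap` (the only instance
  type in scope) and an optional `Usage:` keyword;
* `RuleSet: Name(p1, p2)` definitions and `* insert Name(a, b)` rules;
* the item keywords `Id:`, `Title:`, `Description:`;
* caret value rules (`* ^path = value`) on CodeSystem/ValueSet items and
  plain assignment rules (`* path = value`) on ConceptMap instances;
* `//` line comments (only at line start or after whitespace, so
  unquoted URIs keep their `//`) and `/* */` block comments.

Everything else in full FSH — profiles, extensions, logicals, mappings,
path rules — is rejected with a targeted message naming the subset.
Inline concept rules (`* #code "Display"`) inside a CodeSystem are a
hard error that points at the plugin mechanism: content never comes from
FSH rules, which is the central separation the tool enforces.  Which
item keywords the subset should accept was an open design choice; the
list above is the smallest one that covers terminology metadata
authoring.

Values are typed at parse time: quoted strings (with `\"`, `\\`, `\n`,
`\t` escapes), triple-quoted multiline strings (trimmed by the
minimal-common-indent rule, bit-exact), `true`/`false`, integers,
decimals, ISO dates/datetimes, `[system]#code ["display"]` tokens, and
canonicals (URIs, `urn:` values, or `$alias` references).  Unresolvable
`$alias` tokens are a parse error.  Files are UTF-8 only; a BOM is
tolerated and stripped.  Parsing is total: the caller gets either a
complete document or a positioned error (1-based line, column where
meaningful) — never partial output.

## Directives

A directive is a block comment whose opening token `/*^babelfsh`
immediately follows the `/*` (case-sensitive, no intervening space —
stricter than necessary, but unambiguous) and which closes with
`^babelfsh*/`.  Ordinary comments are never interpreted.  The body is
tokenized shell-style: whitespace separates tokens, double quotes group,
backslash escapes the next character, newlines count as whitespace.

Two binding rules that the directive concept itself leaves open were
fixed as follows:

* **Attachment** — a directive belongs to the item whose lexical extent
  (declaration line up to the next item/RuleSet declaration or EOF)
  contains it.  A directive before the first item, or inside a RuleSet,
  is a compile error.
* **Cardinality** — exactly one directive per item.  Zero means the item
  has no content source (an error rather than a silently empty
  resource); more than one is ambiguous and also an error.  A directive
  whose entire argument vector is `--help` prints the plugin's generated
  help and marks the item as skipped instead of failing the run.

## RuleSet expansion

`insert` rules are macro substitution, applied before any
interpretation: the referenced RuleSet's body lines have `{param}`
placeholders replaced textually by the insert arguments, then each line
is re-parsed as a rule; nested inserts expand recursively.  Arguments
containing `,` or `)` must be escaped with a backslash (a documented
dialect decision).  Undefined RuleSets, argument-count mismatches and
insertion cycles are errors; placeholders that name no declared
parameter are rejected at definition time.  Each expanded rule remembers
both the RuleSet body line it came from and the insertion-site line, so
diagnostics can point at either.  RuleSets share one project-wide
namespace across all source files of a run (duplicate names across
files are an error); this makes shared metadata RuleSets in a common
file the natural idiom for multi-version catalogs.

## Metadata interpretation

Keyword metadata maps directly (`Id` → `id`, item name → `name`,
`Title` → `title`, `Description` → `description`).  Caret/plain rules
cover: `url`, `version`, `status`, `experimental`, `date`, `publisher`,
`description`, `copyright`, `content`, `caseSensitive`,
`hierarchyMeaning`, `identifier[i].{system,value,use}` and
`property[i].{code,uri,type}` declarations, plus a retained generic set
(`purpose`, `contact`, `immutable`, `compositional`, `versionNeeded`,
`supplements`, `valueSet`) that is serialized verbatim at its path.
Later rules on the same path overwrite earlier ones (FSH assignment
semantics) with an info-level log line.  Type checks are enforced where
FHIR fixes the type (`status` takes a code, `experimental` a boolean,
…); violations raise a typed error with the rule's line.

Version gating is symmetric: R5-only elements (`editor`, `reviewer`,
`author`, `topic`, `copyrightLabel`, the `sourceScope*`/`targetScope*`
ConceptMap elements, …) are an error under R4B, and the R4B-only
ConceptMap scope elements (`sourceUri`, `sourceCanonical`, …) are an
error under R5.  Anything outside this surface is an unknown-path error
rather than silently passed through.

## Plugin contract and argument model

A plugin implements two things: a descriptor (id, summary, supported
item kinds, argument specs) and a content generator.  Argument specs
declare long/short flags, a value kind (`string`, `integer`, `path`,
`choice`, `flag`, `key_value_pair`), repeatability, requiredness,
defaults, mutually-exclusive groups — and a mandatory help text.  The
framework derives parsing, type conversion, mutex enforcement, default
filling and deterministic help rendering from the same specs, so help
and parser can never disagree.  `key_value_pair` arguments use
`NAME=VALUE` syntax (e.g. `--property validity=1`), delivered to the
plugin as structured pairs.  Relative `path` arguments resolve against
the directive's source-file directory, not the working directory.

Plugins emit proxy content only (never serialized FHIR).  Built-ins are
registered statically; third-party plugins are discovered via the
`fshterm.plugins` entry-point group.  Plugin ids are unique; a duplicate
registration is an error at registry construction.  Aliases from the
FSH source are *not* resolved inside directive arguments.

## The delimited-table conversion

Dialect: comma- and semicolon-delimited files are parsed with
RFC-4180-style quoting (spreadsheet exports); any other delimiter (pipe,
tab) is split verbatim, matching large catalog distributions that do
not quote cells.  Cell values are taken verbatim — no trimming beyond
line terminators; CRLF and LF files yield identical records.  Column
references are header names, or 1-based indices with `--no-header`.

Conversion semantics:

* one concept per distinct non-empty code, in first-appearance order; a
  blank code cell is an error with its line;
* rows sharing a code merge into one concept, accumulating properties
  in row order; conflicting displays or definitions on merge are an
  error (silent last-wins would hide catalog defects);
* empty property cells emit nothing; typed conversion failures are
  per-cell errors with line numbers;
* property value types come from the metadata declaration when the
  property is declared; implicit standard properties (`parent`, `child`,
  `inactive`, `deprecated`, `notSelectable`) use their standard types; a
  mapped property that is neither declared nor implicit is an error;
* the inactive column emits `inactive=true` for cells in the true-value
  set — default `{YES, Y, TRUE, 1}`, case-insensitive, overridable via
  `--inactive-true-values`;
* the parent column emits hierarchy links per `--hierarchy`:
  `parent` (default — the representation terminology servers generally
  prefer), `child`, `both` (reciprocal links), or `nested` (concept
  nesting, with no parent/child properties, since FHIR says the two
  representations should not be used concurrently);
* a parent value naming no code in the table is an error by default;
  `--allow-dangling-parents` downgrades it to a warning, because real
  catalogs ship partial extracts and forward references.

Multiple parents (poly-hierarchy) are legal and produce no finding.

## Assembly and canonical serialization

Assembly combines metadata and content into a JSON tree with elements
in FHIR definition order for the selected mode.  For CodeSystem:
implicit properties used by any concept are auto-declared on first use
with `http://hl7.org/fhir/concept-properties#<code>` URIs; `count` is
always computed and emitted (total concepts at all nesting levels —
terminology servers rely on it); `content` defaults to `complete`.
`status` is never defaulted — a missing status is a validation error,
since FHIR requires it and guessing a publication status would be
wrong more often than right.

ConceptMap correspondence codes are checked against the active mode's
vocabulary (R4B `equivalence` vs R5 `relationship`); no automatic
translation is attempted.  R5 dropped the group-level
`sourceVersion`/`targetVersion` elements, so under R5 a stated version
is appended to the group's canonical as `system|version`.

Serialization is canonical and byte-deterministic: UTF-8,
`resourceType` first, 2-space indent, LF endings, no trailing
whitespace, one trailing newline.  Output files are named
`<ResourceType>-<id>.json` (the item name stands in when no `Id` is
declared); name collisions are an error.  R4 and R4B are treated as one
mode labeled R4B, as the terminology module is unchanged between them.

## Validation

Structural validation runs on the assembled tree and returns findings
instead of raising; `fatal`/`error` findings block writing, `warning`
and `info` never do.  Issue codes: `missing-status`, `missing-content`,
`invalid-url`, `duplicate-code`, `undeclared-property`,
`dangling-parent`, `parent-cycle`, `concurrent-hierarchy` (warning),
`name-convention` (warning), `empty-display` (warning),
`invalid-compose-entry`, `mode-vocabulary`.  The pipeline additionally
surfaces parse/argument/plugin errors under their own codes
(`syntax-error`, `unknown-plugin`, `missing-required-argument`,
`mutex-violation`, `ragged-row`, …), each with the most specific source
location available: FSH line, directive line, or table row — table-level
findings name the table file.  Cycle detection is an iterative
gray/black DFS over the code→parents graph (iterative so deep
hierarchies cannot exhaust the recursion limit); each distinct cycle is
reported once, rotated to start at its lexicographically smallest code.
Issue order is deterministic: document order, then check order.

Deep validation against the full FHIR specification is exposed only as
an opt-in hook (`--deep-validate CMD`) that runs an external command per
written file and relays non-zero exits as warnings; no validator is
bundled, and its findings never terminate the run.

## Synthetic fixtures and the oracle

The generator produces two layouts: `hierarchy_csv` (header row,
CODE/DISPLAY/INACTIVE/PARENT, YES/NO inactive cells, parent codes
forming a forest of bounded depth) and `alpha_like` (headerless,
pipe-separated, seven columns
`validity|code|primary-code|secondary-code|extra-code|aux-code|text` —
our own documented layout in the style of national diagnosis indexes,
not a replica of any official distribution).  Defaults: 15% inactive
fraction, hierarchy depth ≤ 3, no duplicate codes unless requested.
Display text comes from a fixed word list under a seeded generator;
the same spec and seed always produce byte-identical files, and each
generation returns a manifest recording ground truth (row and distinct-
code counts, expected property counts, planted defects with line
numbers).  Four defect classes can be planted on demand: a duplicate
code with a conflicting display, a dangling parent, a parent cycle
(rewiring an existing edge from a root to its descendant), and a ragged
row.

What the fixtures do *not* emulate: real catalog quoting quirks, mixed
encodings within one file, multi-million-row scale, and the semantic
structure of real classifications (ICD-style code semantics, meaningful
hierarchies).  Passing tests therefore demonstrate the mechanics of
conversion, conservation and defect detection — not fitness of any
particular real catalog's column mapping.

The correctness oracle builds the expected CodeSystem JSON directly
from table rows by naive record iteration — separate column resolution,
separate merging, its own copy of the element order — and shares only
the canonical JSON byte writer with the compiler.  Equivalence tests
compare compiler output to oracle output byte for byte across 200
seeded fixtures of ≤ 50 rows in both layouts, including merged
duplicate codes and empty tables.

## Problem sizes and runtime

The test suite exercises the full pipeline at 90,400 rows (the scale
check compiles in a few seconds on one CPU; the suite asserts a loose
60 s engineering bound), the 33-row worked example (< 1 s), 200 oracle
fixtures (< 2 min), and a 1,000-node random DAG for cycle detection.
These sizes were chosen to keep the default test run fast while still
demonstrating linear scaling; the conversion itself is O(rows) with
dictionary-based merging.

## Known limitations

* Content ingestion is limited to delimited text (plus inline code
  lists); ClaML/OWL/XML/spreadsheet/web-API sources need third-party
  plugins.
* ValueSet content support is extensional only; intensional definitions
  beyond simple filters are better authored in plain FSH.
* Metadata validation is structural, not schema-complete: complex
  elements (e.g. full `contact` details) are passed through verbatim
  and left to the external deep-validation hook.
* The `version` of a ConceptMap group under R5 is folded into the
  canonical; consumers that expect unversioned canonicals must account
  for this.
* Line attribution for findings inside multi-line constructs points at
  the construct's first line.
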