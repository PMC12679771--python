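# fshterm

A compiler toolkit that turns heterogeneous terminology source files —
delimited-text catalogs such as diagnosis indexes, local code lists and
mapping tables — into HL7 FHIR **CodeSystem**, **ValueSet** and
**ConceptMap** JSON resources.

FHIR terminology servers can only serve what exists as FHIR resources,
but most code systems are distributed in other formats: pipe-separated
catalog files, spreadsheet CSV exports, database extracts.  Writing the
concepts out as plain FHIR Shorthand (FSH) and compiling them with a
general-purpose FSH compiler scales badly — a 90,000-row catalog balloons
into half a million lines of generated FSH.  `fshterm` is for the people
who provision terminology servers: it keeps the *metadata* of each
resource in a concise, strict subset of FSH, and delegates the *content*
to small conversion plugins configured directly in the source file.

## How it works

A source file (extension `.babel.fsh` or `.babelfsh.fsh`) declares the
resource and its metadata with ordinary FSH rules, and carries exactly
one *directive* per item — a block comment opening with `/*^babelfsh` and
closing with `^babelfsh*/` that names a content plugin and its
command-line-style arguments:

```
CodeSystem: DemoDiagnoses
Id: demo-diagnoses
Title: "Demo diagnosis catalog"
* ^url = "http://example.org/fhir/CodeSystem/demo-diagnoses"
* ^version = "1.0.0"
* ^status = #active
* ^caseSensitive = true
* ^content = #complete
/*^babelfsh delimited-table --file table.csv
    --code-column CODE --display-column DISPLAY
    --inactive-column INACTIVE --parent-column PARENT ^babelfsh*/
```

Because directives live inside comments, every source file remains a
valid FSH file for standard tooling; deleting the directives changes
nothing about how the metadata parses.

Plugins produce version-agnostic proxy content (concept entries, compose
entries, mapping groups); only the final serialization step consults the
selected FHIR version.  One invocation targets exactly one version —
`r4b` or `r5` — because the two dialects differ (R5-only metadata
elements such as `editor`/`reviewer`; the ConceptMap `equivalence` →
`relationship` redesign, whose vocabularies are deliberately *not*
translated automatically).

Built-in plugins:

| plugin | item kind | converts |
| --- | --- | --- |
| `delimited-table` | CodeSystem | CSV/TSV/pipe tables with configurable code/display/property/hierarchy columns |
| `code-list` | ValueSet | explicit code lists (inline or from a file) into compose includes/excludes |
| `mapping-table` | ConceptMap | delimited source→target mapping tables into groups |

Third-party plugins register through the `fshterm.plugins` entry-point
group and declare typed arguments (with mandatory help texts), from which
argument parsing, validation and `--help` output are generated.

Every assembled resource is validated structurally before writing:
missing required elements, malformed canonical URIs, duplicate concept
codes, undeclared properties, dangling parents, hierarchy cycles,
mode-incompatible mapping vocabularies.  Errors block output; warnings
never do.  An optional `--deep-validate CMD` hook runs an external
validator over each written file and relays failures as warnings.

## Worked example

```
$ fshterm fixtures --rows 5 --seed 42 --out table.csv
$ cat table.csv
CODE,DISPLAY,INACTIVE,PARENT
C0001,Acquired chronic syndrome familial,NO,
C0002,Congenital cranial dermal malignant,YES,C0001
C0003,Idiopathic hepatic,NO,C0001
C0004,Dermal infection idiopathic dysplasia,NO,C0001
C0005,Femoral inflammation,NO,C0002
$ fshterm compile . --fhir-version r4b --out out
INFO wrote out/CodeSystem-demo-diagnoses.json (1519 bytes)
out/CodeSystem-demo-diagnoses.json
```

The generated resource starts:

```json
{
  "resourceType": "CodeSystem",
  "id": "demo-diagnoses",
  "url": "http://example.org/fhir/CodeSystem/demo-diagnoses",
  "version": "1.0.0",
  "name": "DemoDiagnoses",
  "title": "Demo diagnosis catalog",
  "status": "active",
  "caseSensitive": true,
  "content": "complete",
  "count": 5,
```

`count` is the total number of concepts; the YES cell in the INACTIVE
column became a boolean `inactive` property on `C0002`, the PARENT cells
became code-typed `parent` properties, and both properties were
auto-declared with their standard
`http://hl7.org/fhir/concept-properties#…` URIs because the FHIR
specification pre-defines them.  Output is canonical: element order
follows the FHIR definition, 2-space indent, LF endings —
byte-identical across runs.

Exit codes: `0` clean, `1` any compile/validation error, `2` usage error.

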