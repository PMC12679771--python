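"""Shared helpers: source templates, compile wrapper, oracle parameters."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from fshterm.app import CompileConfig, compile_project
from fshterm.fhir_model import FhirMode
from fshterm.plugin_framework import default_registry

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def compile_fsh(tmp_path, registry):
    """Write sources into a temp project and compile it."""

    def _compile(sources: dict[str, str], mode: FhirMode = FhirMode.R4B,
                 **config):
        for name, text in sources.items():
            target = tmp_path / name
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_text(text, encoding="utf-8")
        result = compile_project(
            CompileConfig(inputs=[tmp_path], fhir_mode=mode,
                          out_dir=tmp_path / "out", **config),
            registry=registry)
        return result

    _compile.root = tmp_path
    return _compile


# ---------------------------------------------------------------------------
# Source templates shared between unit, property and acceptance tests.

HIERARCHY_META = {
    "id": "demo-cs",
    "url": "http://example.org/fhir/CodeSystem/demo-cs",
    "version": "2025",
    "name": "DemoCS",
    "title": "Demo code system",
    "status": "active",
    "description": "A small synthetic demo.",
    "caseSensitive": True,
}


def hierarchy_source(table_name: str) -> str:
    """An FSH item for a CODE/DISPLAY/INACTIVE/PARENT table."""
    return f"""\
CodeSystem: DemoCS
Id: demo-cs
Title: "Demo code system"
Description: "A small synthetic demo."
* ^url = "http://example.org/fhir/CodeSystem/demo-cs"
* ^version = "2025"
* ^status = #active
* ^caseSensitive = true
* ^content = #complete
/*^babelfsh delimited-table --file {table_name} --code-column CODE --display-column DISPLAY --inactive-column INACTIVE --parent-column PARENT ^babelfsh*/
"""


def hierarchy_oracle_mapping() -> dict:
    return {"code_column": "CODE", "display_column": "DISPLAY",
            "inactive_column": "INACTIVE", "parent_column": "PARENT"}


def hierarchy_oracle_meta() -> dict:
    return dict(HIERARCHY_META)


ALPHA_META = {
    "id": "alpha-index",
    "url": "http://example.org/fhir/CodeSystem/alpha-index",
    "version": "2025",
    "name": "AlphaIndex",
    "title": "Synthetic alphabetical diagnosis index",
    "status": "active",
    "caseSensitive": True,
    "declared_properties": [
        ("validity", None, "code"),
        ("icd10", None, "code"),
        ("icd10_alt", None, "code"),
        ("extra_code", None, "code"),
        ("orpha", None, "code"),
    ],
}


def alpha_source(table_name: str) -> str:
    """An FSH item for the headerless 7-column pipe layout."""
    return f"""\
CodeSystem: AlphaIndex
Id: alpha-index
Title: "Synthetic alphabetical diagnosis index"
* ^url = "http://example.org/fhir/CodeSystem/alpha-index"
* ^version = "2025"
* ^status = #active
* ^caseSensitive = true
* ^content = #complete
* ^property[0].code = #validity
* ^property[0].type = #code
* ^property[1].code = #icd10
* ^property[1].type = #code
* ^property[2].code = #icd10_alt
* ^property[2].type = #code
* ^property[3].code = #extra_code
* ^property[3].type = #code
* ^property[4].code = #orpha
* ^property[4].type = #code
/*^babelfsh delimited-table --file {table_name} -d "|" --no-header --code-column 2 --display-column 7 --property validity=1 --property icd10=3 --property icd10_alt=4 --property extra_code=5 --property orpha=6 ^babelfsh*/
"""


def alpha_oracle_mapping() -> dict:
    return {"delimiter": "|", "has_header": False, "code_column": 2,
            "display_column": 7,
            "properties": [("validity", 1, "code"), ("icd10", 3, "code"),
                           ("icd10_alt", 4, "code"),
                           ("extra_code", 5, "code"), ("orpha", 6, "code")]}


def alpha_oracle_meta() -> dict:
    return dict(ALPHA_META)


VALUESET_SOURCE = """\
ValueSet: DemoVS
Id: demo-vs
Title: "Demo value set"
* ^url = "http://example.org/fhir/ValueSet/demo-vs"
* ^status = #active
/*^babelfsh code-list --system http://example.org/fhir/CodeSystem/demo-cs --code C0001|First --code C0002 ^babelfsh*/
"""


def conceptmap_source(table_name: str, extra_rules: str = "") -> str:
    return f"""\
Instance: DemoMap
InstanceOf: ConceptMap
Usage: #definition
Id: demo-map
* url = "http://example.org/fhir/ConceptMap/demo-map"
* name = "DemoMap"
* status = #active
{extra_rules}\
/*^babelfsh mapping-table --file {table_name} --source-system http://example.org/fhir/CodeSystem/demo-cs --target-system http://example.org/other ^babelfsh*/
"""


MAPPING_TABLE_EQUIVALENT = """\
SOURCE,TARGET,CORRESPONDENCE
C0001,X1,equivalent
C0002,X2,equivalent
"""

MAPPING_TABLE_R4B_ONLY = """\
SOURCE,TARGET,CORRESPONDENCE
C0001,X1,wider
C0002,X2,relatedto
"""
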