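"""Parsing, RuleSet expansion and metadata interpretation."""

import pytest

from fshterm.errors import (ArityMismatch, CycleError, FshSyntaxError,
                            ModeError, TypeMismatch, UnknownPath,
                            UnknownRuleSet)
from fshterm.fhir_model import FhirMode
from fshterm.fsh_core import (expand_rulesets, interpret_metadata,
                              parse_document, parse_value)

R4B, R5 = FhirMode.R4B, FhirMode.R5


class TestParseDocument:

    def test_minimal_wellformed_item(self):
        doc = parse_document(
            'CodeSystem: Demo\nId: demo\n* ^url = "http://example.org/cs"\n')
        (item,) = doc.items
        assert item.kind == "codesystem"
        assert item.name == "Demo"
        assert item.keyword_meta["Id"] == "demo"
        (rule,) = item.rules
        assert (rule.variant, rule.path) == ("caret_value", "url")
        assert rule.value.parsed == "http://example.org/cs"

    def test_plain_comment_is_discarded_not_hijacked(self):
        doc = parse_document(
            "/* a note */\nCodeSystem: Demo\nId: demo\n")
        (item,) = doc.items
        assert item.directives == []
        assert item.keyword_meta["Id"] == "demo"

    def test_syntax_error_carries_line(self):
        text = ("CodeSystem: Demo\nId: demo\n\n"
                '* ^version = "1"\n\n\n'
                '* ^url "missing equals"\n')
        with pytest.raises(FshSyntaxError) as err:
            parse_document(text)
        assert err.value.line == 7

    def test_error_line_within_file_range(self):
        bad_sources = [
            "CodeSystem: Demo\n* ^url = \n",
            "CodeSystem: Demo\nwhat is this\n",
            "* ^url = \"x\"\n",
            "CodeSystem: Demo\n* ^status = #\n",
        ]
        for text in bad_sources:
            with pytest.raises(FshSyntaxError) as err:
                parse_document(text)
            assert 1 <= err.value.line <= text.count("\n") + 1

    def test_alias_resolution_and_duplicates(self):
        doc = parse_document(
            "Alias: $base = http://example.org\n"
            "CodeSystem: Demo\n* ^url = $base\n")
        assert doc.items[0].rules[0].value.parsed == "http://example.org"
        with pytest.raises(FshSyntaxError):
            parse_document("Alias: $a = http://x\nAlias: $a = http://y\n")
        with pytest.raises(FshSyntaxError) as err:
            parse_document("CodeSystem: Demo\n* ^url = $nope\n")
        assert "alias" in err.value.message

    def test_comment_markers_inside_strings_survive(self):
        doc = parse_document(
            'CodeSystem: Demo\n* ^copyright = "see http://x // not a comment"\n')
        assert doc.items[0].rules[0].value.parsed == \
            "see http://x // not a comment"

    def test_multiline_string_common_indent_trimming(self):
        text = ('CodeSystem: Demo\n* ^description = """\n'
                '    First line\n      indented\n    Last line\n    """\n')
        doc = parse_document(text)
        assert doc.items[0].rules[0].value.parsed == \
            "First line\n  indented\nLast line"

    def test_directive_attaches_to_enclosing_item(self):
        text = ("CodeSystem: One\nId: one\n"
                "/*^babelfsh plug-a ^babelfsh*/\n"
                "CodeSystem: Two\nId: two\n"
                "/*^babelfsh plug-b --x 1 ^babelfsh*/\n")
        doc = parse_document(text)
        assert [i.directives[0].plugin_id for i in doc.items] == \
            ["plug-a", "plug-b"]
        assert doc.items[1].directives[0].owner_item == "Two"
        assert doc.items[1].directives[0].start_line == 6

    def test_directive_before_first_item_is_error(self):
        with pytest.raises(FshSyntaxError):
            parse_document("/*^babelfsh plug ^babelfsh*/\nCodeSystem: A\n")

    def test_directive_inside_ruleset_extent_is_error(self):
        text = ("CodeSystem: A\nRuleSet: M\n* ^version = \"1\"\n"
                "/*^babelfsh plug ^babelfsh*/\n")
        with pytest.raises(FshSyntaxError):
            parse_document(text)

    def test_unsupported_fsh_keyword_rejected_with_targeted_message(self):
        with pytest.raises(FshSyntaxError) as err:
            parse_document("Profile: MyProfile\nParent: Patient\n")
        assert "subset" in err.value.message

    def test_inline_concept_rule_names_plugin_mechanism(self):
        with pytest.raises(FshSyntaxError) as err:
            parse_document('CodeSystem: A\n* #foo "Foo display"\n')
        assert "plugin" in err.value.message

    def test_duplicate_keyword_meta_rejected(self):
        with pytest.raises(FshSyntaxError):
            parse_document("CodeSystem: A\nId: one\nId: two\n")

    def test_instance_must_be_conceptmap(self):
        with pytest.raises(FshSyntaxError):
            parse_document("Instance: X\nInstanceOf: Patient\n")
        with pytest.raises(FshSyntaxError):
            parse_document("Instance: X\n* status = #active\n")

    def test_parse_is_deterministic(self):
        text = ("Alias: $s = http://example.org\n"
                "RuleSet: M(v)\n* ^version = \"{v}\"\n"
                "CodeSystem: A\nId: a\n* insert M(1)\n"
                "/*^babelfsh plug --x 1 ^babelfsh*/\n")
        assert parse_document(text) == parse_document(text)

    def test_bom_is_tolerated(self):
        doc = parse_document("﻿CodeSystem: Demo\n")
        assert doc.items[0].name == "Demo"


class TestValues:

    @pytest.mark.parametrize("raw,tag,parsed", [
        ('"text"', "string", "text"),
        ("true", "boolean", True),
        ("false", "boolean", False),
        ("42", "integer", 42),
        ("2.5", "decimal", 2.5),
        ("2025-01-31", "datetime", "2025-01-31"),
        ("2025", "integer", 2025),
        ("#active", "code", (None, "active", None)),
        ('#active "Active"', "code", (None, "active", "Active")),
        ("http://x#c", "code", ("http://x", "c", None)),
        ("http://example.org/vs", "canonical", "http://example.org/vs"),
        ("urn:oid:1.2.3", "canonical", "urn:oid:1.2.3"),
        (r'"escaped \"x\" and \n"', "string", 'escaped "x" and \n'),
    ])
    def test_typed_value_parsing(self, raw, tag, parsed):
        value = parse_value(raw, 1, {})
        assert (value.type_tag, value.parsed) == (tag, parsed)
        assert value.raw_text == raw.strip()

    def test_bare_word_is_rejected(self):
        with pytest.raises(FshSyntaxError):
            parse_value("notquoted", 1, {})


class TestRuleSetExpansion:

    def test_parameter_substitution(self):
        doc = parse_document(
            'RuleSet: v(ver)\n* ^version = "{ver}"\n'
            "CodeSystem: A\n* insert v(2025)\n")
        expand_rulesets(doc)
        (rule,) = doc.items[0].rules
        assert rule.variant == "caret_value"
        assert (rule.path, rule.value.parsed) == ("version", "2025")
        assert rule.origin_ruleset == "v"
        assert rule.origin_line == 2  # body line in the RuleSet
        assert rule.line == 4         # insertion site

    def test_nested_rulesets_expand_transitively(self):
        doc = parse_document(
            'RuleSet: B\n* ^publisher = "Org"\n'
            "RuleSet: A\n* insert B\n"
            "CodeSystem: CS\n* insert A\n")
        expand_rulesets(doc)
        (rule,) = doc.items[0].rules
        assert (rule.path, rule.value.parsed) == ("publisher", "Org")

    def test_self_insertion_cycle(self):
        doc = parse_document(
            "RuleSet: A\n* insert A\nCodeSystem: CS\n* insert A\n")
        with pytest.raises(CycleError):
            expand_rulesets(doc)

    def test_unknown_and_arity_errors(self):
        doc = parse_document("CodeSystem: CS\n* insert Nope\n")
        with pytest.raises(UnknownRuleSet):
            expand_rulesets(doc)
        doc = parse_document(
            'RuleSet: v(a, b)\n* ^version = "{a}{b}"\n'
            "CodeSystem: CS\n* insert v(1)\n")
        with pytest.raises(ArityMismatch):
            expand_rulesets(doc)

    def test_undeclared_placeholder_rejected_at_parse(self):
        with pytest.raises(FshSyntaxError):
            parse_document('RuleSet: v(a)\n* ^version = "{b}"\n')

    def test_escaped_comma_and_paren_in_arguments(self):
        doc = parse_document(
            'RuleSet: t(x)\n* ^title = "{x}"\n'
            "CodeSystem: CS\n* insert t(a\\, b \\(c\\))\n")
        expand_rulesets(doc)
        assert doc.items[0].rules[0].value.parsed == "a, b (c)"

    @pytest.mark.parametrize("args", [["2025"], ["a b"], ["x", "y"]])
    def test_expansion_matches_manual_macro_substitution(self, args):
        """Independent oracle: plain string templating of the body must
        equal the expander's output."""
        params = [f"p{i}" for i in range(len(args))]
        body = "* ^title = \"" + " / ".join("{%s}" % p for p in params) + "\""
        source = (f"RuleSet: T({', '.join(params)})\n{body}\n"
                  f"CodeSystem: CS\n"
                  f"* insert T({', '.join(args)})\n")
        doc = parse_document(source)
        expand_rulesets(doc)
        expected = body
        for param, arg in zip(params, args):
            expected = expected.replace("{%s}" % param, arg)
        expected_value = expected.split("=", 1)[1].strip().strip('"')
        assert doc.items[0].rules[0].value.parsed == expected_value


class TestInterpretMetadata:

    def _item(self, source):
        doc = parse_document(source)
        expand_rulesets(doc)
        return doc.items[0]

    def test_direct_field_mapping(self):
        item = self._item(
            "CodeSystem: Demo\nId: demo\nTitle: \"T\"\n"
            '* ^url = "http://example.org/cs"\n* ^version = "2025"\n'
            "* ^status = #active\n")
        meta = interpret_metadata(item, R4B)
        assert meta.url == "http://example.org/cs"
        assert meta.version == "2025"
        assert meta.status == "active"
        assert (meta.id, meta.name, meta.title) == ("demo", "Demo", "T")

    def test_property_declaration_from_indexed_rules(self):
        item = self._item(
            "CodeSystem: Demo\n"
            "* ^property[0].code = #validity\n"
            "* ^property[0].type = #code\n")
        meta = interpret_metadata(item, R4B)
        (decl,) = meta.property_declarations
        assert (decl.code, decl.type) == ("validity", "code")

    def test_r5_only_path_is_mode_gated(self):
        item = self._item('CodeSystem: Demo\n* ^editor.name = "X"\n')
        with pytest.raises(ModeError):
            interpret_metadata(item, R4B)
        meta = interpret_metadata(item, R5)
        assert meta.r5_extras == {"editor[0].name": "X"}

    def test_unknown_path_rejected(self):
        item = self._item('CodeSystem: Demo\n* ^nonsenseElement = "x"\n')
        with pytest.raises(UnknownPath):
            interpret_metadata(item, R4B)

    def test_type_mismatch_on_status(self):
        item = self._item('CodeSystem: Demo\n* ^status = "active"\n')
        with pytest.raises(TypeMismatch):
            interpret_metadata(item, R4B)

    def test_last_rule_wins_on_same_path(self):
        item = self._item(
            'CodeSystem: Demo\n* ^version = "1"\n* ^version = "2"\n')
        assert interpret_metadata(item, R4B).version == "2"

    def test_conceptmap_scope_paths_are_version_specific(self):
        source = ("Instance: M\nInstanceOf: ConceptMap\n"
                  '* sourceUri = "http://example.org/src"\n')
        item = self._item(source)
        meta = interpret_metadata(item, R4B)
        assert meta.generic_extras["sourceUri"] == "http://example.org/src"
        with pytest.raises(ModeError):
            interpret_metadata(item, R5)
        source5 = ("Instance: M\nInstanceOf: ConceptMap\n"
                   '* sourceScopeUri = "http://example.org/src"\n')
        item5 = self._item(source5)
        assert interpret_metadata(item5, R5).r5_extras[
            "sourceScopeUri"] == "http://example.org/src"
        with pytest.raises(ModeError):
            interpret_metadata(item5, R4B)
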