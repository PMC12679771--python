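"""Delimited-table reading and row→concept conversion."""

import pytest

from fshterm.errors import (ArgumentValueError, DanglingParent,
                            DecodeError, DuplicateCodeConflict, EmptyCode,
                            FileMissing, RaggedRow, TypeMismatch,
                            UndeclaredProperty)
from fshterm.fhir_model import PropertyDeclaration
from fshterm.fixtures import FixtureSpec, generate_table
from fshterm.plugins.tabular import (ColumnMapping, PropertyMapping,
                                     read_table, rows_to_concepts)


def pipe_mapping(**kw):
    defaults = dict(code_column="2", delimiter="|", has_header=False)
    defaults.update(kw)
    return ColumnMapping(**defaults)


def csv_mapping(**kw):
    defaults = dict(code_column="CODE", display_column="DISPLAY",
                    inactive_column="INACTIVE", parent_column="PARENT")
    defaults.update(kw)
    return ColumnMapping(**defaults)


FIG_TABLE = ("CODE,DISPLAY,INACTIVE,PARENT\n"
             "A,Root,NO,\n"
             "B,Leaf,NO,A\n"
             "C,Old leaf,YES,A\n")


class TestReadTable:

    def test_pipe_file_with_header(self, tmp_path):
        path = tmp_path / "t.psv"
        path.write_text("CODE|DISPLAY\nA|Alpha\nB|Beta\nC|Gamma\n")
        header, rows = read_table(path, ColumnMapping(
            code_column="CODE", delimiter="|"))
        assert header == ["CODE", "DISPLAY"]
        assert [r.cells for r in rows] == [["A", "Alpha"], ["B", "Beta"],
                                           ["C", "Gamma"]]
        assert [r.line for r in rows] == [2, 3, 4]

    def test_ragged_row_carries_line_number(self, tmp_path):
        path = tmp_path / "t.csv"
        lines = ["CODE,DISPLAY"] + [f"C{i},D{i}" for i in range(1, 11)]
        lines.append("SHORT")  # line 12
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(RaggedRow) as err:
            read_table(path, ColumnMapping(code_column="CODE"))
        assert err.value.line == 12

    def test_crlf_and_lf_produce_identical_records(self, tmp_path):
        lf, crlf = tmp_path / "lf.csv", tmp_path / "crlf.csv"
        lf.write_text(FIG_TABLE)
        crlf.write_bytes(FIG_TABLE.replace("\n", "\r\n").encode())
        assert read_table(lf, csv_mapping()) == read_table(crlf, csv_mapping())

    def test_comment_and_blank_lines_skipped(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("CODE,DISPLAY\n# note\n\nA,Alpha\n")
        _, rows = read_table(path, ColumnMapping(code_column="CODE",
                                                 comment_prefix="#"))
        assert [r.cells for r in rows] == [["A", "Alpha"]]

    def test_rfc4180_quoting_for_comma_but_raw_split_for_pipe(self, tmp_path):
        quoted = tmp_path / "q.csv"
        quoted.write_text('CODE,DISPLAY\nA,"a, with comma"\n')
        _, rows = read_table(quoted, ColumnMapping(code_column="CODE"))
        assert rows[0].cells == ["A", "a, with comma"]
        raw = tmp_path / "r.psv"
        raw.write_text('A|"not quoted\n')
        _, rows = read_table(raw, pipe_mapping())
        assert rows[0].cells == ["A", '"not quoted']

    def test_missing_file_and_bad_encoding(self, tmp_path):
        with pytest.raises(FileMissing):
            read_table(tmp_path / "absent.csv", csv_mapping())
        path = tmp_path / "t.csv"
        path.write_bytes(b"CODE,DISPLAY\nA,\xff\xfe\n")
        with pytest.raises(DecodeError) as err:
            read_table(path, csv_mapping())
        assert "byte offset" in err.value.message

    def test_latin1_encoding_supported(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_bytes("CODE,DISPLAY\nA,Schädel\n".encode("latin-1"))
        _, rows = read_table(path, csv_mapping(encoding="latin-1"))
        assert rows[0].cells == ["A", "Schädel"]

    def test_delimiter_must_be_single_character(self):
        with pytest.raises(ArgumentValueError):
            ColumnMapping(code_column="CODE", delimiter="||")


class TestRowsToConcepts:

    def _convert(self, tmp_path, text, mapping, declared=()):
        path = tmp_path / "t.csv"
        path.write_text(text)
        header, rows = read_table(path, mapping)
        return rows_to_concepts(rows, mapping, list(declared), header)

    def test_parent_and_inactive_columns(self, tmp_path):
        concepts = self._convert(tmp_path, FIG_TABLE, csv_mapping())
        by_code = {c.code: c for c in concepts}
        assert set(by_code) == {"A", "B", "C"}
        assert by_code["A"].properties == []
        assert by_code["B"].properties == [("parent", ("code", "A"))]
        assert by_code["C"].properties == [("inactive", ("boolean", True)),
                                           ("parent", ("code", "A"))]

    def test_rows_with_same_code_merge_in_row_order(self, tmp_path):
        text = ("CODE,DISPLAY,ICD\nZ,Same,A10\nZ,Same,B20\n")
        mapping = ColumnMapping(
            code_column="CODE", display_column="DISPLAY",
            property_mappings=[PropertyMapping("icd", "ICD")])
        declared = [PropertyDeclaration(code="icd", type="code")]
        (concept,) = self._convert(tmp_path, text, mapping, declared)
        assert concept.properties == [("icd", ("code", "A10")),
                                      ("icd", ("code", "B20"))]

    def test_conflicting_display_on_merge(self, tmp_path):
        text = "CODE,DISPLAY\nZ,One\nZ,Other\n"
        with pytest.raises(DuplicateCodeConflict) as err:
            self._convert(tmp_path, text,
                          ColumnMapping(code_column="CODE",
                                        display_column="DISPLAY"))
        assert err.value.line == 3

    def test_blank_code_cell(self, tmp_path):
        with pytest.raises(EmptyCode) as err:
            self._convert(tmp_path, "CODE,DISPLAY\n,Blank\n",
                          ColumnMapping(code_column="CODE"))
        assert err.value.line == 2

    def test_undeclared_property_is_rejected(self, tmp_path):
        mapping = ColumnMapping(
            code_column="CODE",
            property_mappings=[PropertyMapping("mystery", "DISPLAY")])
        with pytest.raises(UndeclaredProperty):
            self._convert(tmp_path, "CODE,DISPLAY\nA,x\n", mapping)

    def test_implicit_property_needs_no_declaration(self, tmp_path):
        mapping = ColumnMapping(
            code_column="CODE",
            property_mappings=[PropertyMapping("notSelectable", "FLAG")])
        (concept,) = self._convert(tmp_path, "CODE,FLAG\nA,true\n", mapping)
        assert concept.properties == [("notSelectable", ("boolean", True))]

    def test_dangling_parent_default_error_and_downgrade(self, tmp_path):
        text = "CODE,DISPLAY,INACTIVE,PARENT\nB,Leaf,NO,ZZZ\n"
        with pytest.raises(DanglingParent) as err:
            self._convert(tmp_path, text, csv_mapping())
        assert err.value.line == 2
        concepts = self._convert(tmp_path, text,
                                 csv_mapping(allow_dangling_parents=True))
        assert concepts[0].properties == [("parent", ("code", "ZZZ"))]

    @pytest.mark.parametrize("mode,expected", [
        ("parent", {"B": [("parent", ("code", "A"))], "A": []}),
        ("child", {"A": [("child", ("code", "B"))], "B": []}),
        ("both", {"A": [("child", ("code", "B"))],
                  "B": [("parent", ("code", "A"))]}),
    ])
    def test_hierarchy_property_modes(self, tmp_path, mode, expected):
        text = "CODE,DISPLAY,INACTIVE,PARENT\nA,Root,NO,\nB,Leaf,NO,A\n"
        concepts = self._convert(tmp_path, text,
                                 csv_mapping(hierarchy_mode=mode))
        got = {c.code: c.properties for c in concepts}
        assert got == expected

    def test_nested_mode_builds_tree_without_properties(self, tmp_path):
        text = ("CODE,DISPLAY,INACTIVE,PARENT\nA,Root,NO,\n"
                "B,Leaf,NO,A\nC,Leaf2,NO,A\n")
        concepts = self._convert(tmp_path, text,
                                 csv_mapping(hierarchy_mode="nested"))
        (root,) = concepts
        assert root.code == "A"
        assert sorted(ch.code for ch in root.children) == ["B", "C"]
        assert root.properties == []
        assert all(ch.properties == [] for ch in root.children)

    def test_cell_type_conversion_errors_carry_line(self, tmp_path):
        mapping = ColumnMapping(
            code_column="CODE",
            property_mappings=[PropertyMapping("rank", "RANK")])
        declared = [PropertyDeclaration(code="rank", type="integer")]
        with pytest.raises(TypeMismatch) as err:
            self._convert(tmp_path, "CODE,RANK\nA,1\nB,high\n",
                          mapping, declared)
        assert err.value.line == 3

    def test_unknown_column_reference(self, tmp_path):
        with pytest.raises(ArgumentValueError):
            self._convert(tmp_path, "CODE\nA\n",
                          ColumnMapping(code_column="NOPE"))

    def test_headerless_index_mapping(self, tmp_path):
        path = tmp_path / "t.psv"
        path.write_text("1|100|Alpha\n1|200|Beta\n")
        mapping = pipe_mapping(display_column="3")
        header, rows = read_table(path, mapping)
        concepts = rows_to_concepts(rows, mapping, [], header)
        assert [(c.code, c.display) for c in concepts] == \
            [("100", "Alpha"), ("200", "Beta")]


class TestConservation:

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_counts_match_fixture_manifest(self, tmp_path, seed):
        """Concept count equals distinct codes; property counts equal the
        number of true-flagged / non-empty cells."""
        spec = FixtureSpec(rows=40, seed=seed, inactive_fraction=0.3,
                           duplicate_code_fraction=0.1)
        manifest = generate_table(spec, tmp_path / "t.csv")
        mapping = csv_mapping()
        header, rows = read_table(tmp_path / "t.csv", mapping)
        concepts = rows_to_concepts(rows, mapping, [], header)
        assert len(concepts) == manifest.expected_concepts
        emitted = {}
        for concept in concepts:
            for code, _v in concept.properties:
                emitted[code] = emitted.get(code, 0) + 1
        assert emitted.get("inactive", 0) == \
            manifest.expected_properties["inactive"]
        assert emitted.get("parent", 0) == \
            manifest.expected_properties["parent"]

    def test_unique_codes_concept_count_equals_row_count(self, tmp_path):
        spec = FixtureSpec(rows=120, seed=5, layout="alpha_like")
        manifest = generate_table(spec, tmp_path / "t.psv")
        mapping = pipe_mapping()
        header, rows = read_table(tmp_path / "t.psv", mapping)
        concepts = rows_to_concepts(rows, mapping, [], header)
        assert len(rows) == manifest.row_count == 120
        assert len(concepts) == 120
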