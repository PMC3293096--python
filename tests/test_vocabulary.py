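"""Vocabulary hierarchy: normalization, tree building, phrases, tables."""

from __future__ import annotations

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellvocab import (
    TableRow,
    VocabularyTable,
    add_term,
    build_tree,
    concat_path,
    normalize_term,
    parse_phrase,
    read_table,
    render_folders,
    to_table,
    write_table,
)
from cellvocab.errors import (
    DuplicateTermError,
    InvalidLabelError,
    InvalidTermError,
    SynonymCollisionWarning,
    TableFormatError,
    UnknownPathError,
)

# strategy for raw term labels: words of letters/digits joined by the
# separators normalization must ignore
_words = st.lists(
    st.text(alphabet="abcdefghijklmnopqrstuvwxyz0123456789", min_size=1, max_size=6),
    min_size=1,
    max_size=4,
)
labels = _words.map(lambda ws: " ".join(ws))
label_paths = st.lists(labels, min_size=1, max_size=5)


class TestNormalizeTerm:
    @pytest.mark.parametrize(
        "variants, key",
        [
            (["cell line", "cell_line", "cellline"], "cellline"),
            (["Time (of) Lapse", "time lapse", "time-lapse"], "timelapse"),
            (["Maintenance Culture", "maintenance_culture"], "maintenanceculture"),
            (["plating density (cells/cm2)"], "platingdensitycellscm2"),
        ],
    )
    def test_synonym_class_collapses(self, variants, key):
        """Labels differing only in case, separators, parentheses or stop
        words map to one canonical key."""
        assert {normalize_term(v) for v in variants} == {key}

    def test_distinct_content_stays_distinct(self):
        assert normalize_term("cell line") != normalize_term("cell type")
        # stop words are removed as whole words only
        assert normalize_term("offer") == "offer"

    def test_stop_word_only_label_keeps_content(self):
        assert normalize_term("of") == "of"

    @pytest.mark.parametrize("bad", ["", "   ", "()", "--"])
    def test_invalid_labels_rejected(self, bad):
        with pytest.raises(InvalidTermError):
            normalize_term(bad)

    @given(labels)
    @settings(max_examples=200)
    def test_idempotent(self, label):
        once = normalize_term(label)
        assert normalize_term(once) == once


class TestPhrases:
    def test_figure_phrase(self):
        labels = ["cell", "history", "maintenance_culture", "passaging",
                  "plating_density"]
        assert concat_path(labels) == (
            "cell:history:maintenance_culture:passaging:plating_density"
        )

    def test_single_label(self):
        assert concat_path(["study"]) == "study"

    def test_delimiter_in_label_rejected(self):
        with pytest.raises(InvalidLabelError):
            concat_path(["cell", "a:b"])

    @given(label_paths)
    @settings(max_examples=1000)
    def test_round_trip(self, path):
        assert list(parse_phrase(concat_path(path))) == path


class TestBuildTree:
    def test_fixture_layout_roots(self, toy_table):
        tree = build_tree(toy_table)
        assert [r.label for r in tree.roots] == [
            "assay", "cell", "instrument", "study",
        ]

    def test_empty_table(self):
        tree = build_tree(VocabularyTable())
        assert tree.roots == [] and tree.node_count() == 0

    def test_shared_prefixes_share_nodes(self):
        table = VocabularyTable([
            TableRow(("cell", "history"), "receipt_date"),
            TableRow(("cell", "history"), "thaw_date"),
        ])
        tree = build_tree(table)
        assert tree.node_count() == 4  # cell, history, two tokens

    def test_normalized_prefixes_unify_with_warning(self):
        table = VocabularyTable([
            TableRow(("cell", "history"), "receipt_date"),
            TableRow(("Cell", "History"), "thaw_date"),
        ])
        with pytest.warns(SynonymCollisionWarning):
            tree = build_tree(table, on_collision="warn")
        assert tree.node_count() == 4
        with pytest.raises(DuplicateTermError):
            build_tree(table, on_collision="error")

    def test_example_values_attach_to_tokens(self, toy_tree):
        node = toy_tree.resolve("cell:cell_line")
        assert node is not None and node.example_value == "A10"


class TestAddTerm:
    def test_time_lapse_extension(self, toy_tree):
        """Extending the hierarchy with time-lapse terms under the
        collection-basis folder makes the new paths resolvable."""
        parent = "assay:image series details:collection basis"
        add_term(toy_tree, parent, "time lapse")
        add_term(toy_tree, parent + ":time lapse", "total time")
        add_term(toy_tree, parent + ":time lapse", "time interval")
        assert toy_tree.resolve(parent + ":time lapse:total time") is not None
        assert toy_tree.resolve(parent + ":time lapse:time interval") is not None

    def test_root_label_may_recur_at_depth(self, toy_tree):
        add_term(toy_tree, "cell", "assay")
        assert toy_tree.resolve("cell:assay") is not None
        assert toy_tree.resolve("assay") is not None  # root untouched

    def test_duplicate_by_normalization_rejected(self, toy_tree):
        with pytest.raises(DuplicateTermError):
            add_term(toy_tree, "cell", "Cell_Line")

    def test_unknown_parent(self, toy_tree):
        with pytest.raises(UnknownPathError):
            add_term(toy_tree, "cell:no_such_folder", "x")

    def test_adds_exactly_one_node_and_keeps_paths(self, toy_tree):
        before_paths = set(toy_tree.paths())
        n = toy_tree.node_count()
        add_term(toy_tree, "study", "abstract")
        assert toy_tree.node_count() == n + 1
        assert before_paths <= set(toy_tree.paths())


class TestRenderFolders:
    def test_single_root_child(self):
        table = VocabularyTable([TableRow(("study",), "personnel")])
        out = render_folders(build_tree(table))
        assert out.splitlines() == ["study", "  personnel"]

    def test_line_count_equals_node_count(self, toy_tree):
        assert len(render_folders(toy_tree).splitlines()) == toy_tree.node_count()

    def test_deterministic(self, toy_tree):
        assert render_folders(toy_tree) == render_folders(toy_tree)


class TestTableIO:
    def test_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "vocab.csv"
        write_table(toy_table, path)
        again = read_table(path)
        assert [r.path for r in again] == [r.path for r in toy_table]
        assert [r.value for r in again] == [r.value for r in toy_table]
        # a second write is byte-identical
        path2 = tmp_path / "vocab2.csv"
        write_table(again, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_four_roots_in_fixture_table(self, toy_table):
        assert len(toy_table.root_labels()) == 4

    def test_figure_row_yields_phrase(self):
        csv_text = (
            "level1,level2,level3,level4,token,value\n"
            "cell,history,maintenance_culture,passaging,plating_density,"
            "800 cells/cm2\n"
        )
        table = read_table(io.StringIO(csv_text))
        assert table.rows[0].phrase == (
            "cell:history:maintenance_culture:passaging:plating_density"
        )
        assert table.rows[0].value == "800 cells/cm2"

    def test_empty_token_reports_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("level1,token,value\ncell,cell_line,A10\nstudy,,x\n")
        with pytest.raises(TableFormatError, match="row 3"):
            read_table(path)

    def test_gapped_hierarchy_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("level1,level2,level3,token,value\ncell,,history,x,\n")
        with pytest.raises(TableFormatError, match="left-aligned"):
            read_table(path)


class TestTableTreeRoundTrip:
    def test_toy_round_trip(self, toy_tree):
        rebuilt = build_tree(to_table(toy_tree), on_collision="error")
        assert rebuilt.normalized_paths() == toy_tree.normalized_paths()

    @given(st.lists(label_paths, min_size=0, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_random_round_trip(self, raw_paths):
        """build_tree(to_table(t)) reproduces t's path set for arbitrary
        trees assembled from random rows."""
        table = VocabularyTable(
            [TableRow(tuple(p[:-1]), p[-1]) for p in raw_paths]
        )
        tree = build_tree(table, on_collision="ignore")
        rebuilt = build_tree(to_table(tree), on_collision="ignore")
        assert rebuilt.normalized_paths() == tree.normalized_paths()
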