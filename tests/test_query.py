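"""Query evaluation against a linear-scan oracle, and dataset comparison."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellvocab import (
    Catalog,
    Query,
    Selection,
    TableRow,
    VocabularyTable,
    build_tree,
    compare,
    evaluate,
    normalize_term,
    parse_phrase,
    parse_selection,
)
from cellvocab.errors import UnknownSeriesError, UnknownTermError
from cellvocab.query import DIFFERS, EQUAL, MISSING_A, MISSING_B


def _scan_oracle(catalog: Catalog, query: Query) -> set[str]:
    """Brute-force reference: re-derive the result by scanning every series
    and re-checking each selection from the raw metadata dict."""
    out = set()
    for name in catalog.series_names:
        metadata = catalog.series(name).metadata
        norm = {
            tuple(normalize_term(l) for l in parse_phrase(k)): v
            for k, v in metadata.items()
        }
        ok = True
        for sel in query.selections:
            path = tuple(normalize_term(l) for l in parse_phrase(sel.phrase))
            if sel.is_wildcard:
                ok = ok and any(k[: len(path)] == path for k in norm)
            else:
                ok = ok and norm.get(path, object()) in {
                    v.strip() for v in sel.values
                }
        if ok:
            out.add(name)
    return out


# --- randomized catalogs ---------------------------------------------------

_PHRASES = [
    "cell:cell_line",
    "cell:organism",
    "assay:datatype",
    "instrument:microscope:model",
    "assay:image series details:collection basis:modality",
]
_VALUES = ["A10", "NIH3T3", "raw", "derived", "x", "y"]


def _random_catalog(rng: random.Random) -> Catalog:
    rows = [
        TableRow(tuple(parse_phrase(p)[:-1]), parse_phrase(p)[-1])
        for p in _PHRASES
    ]
    cat = Catalog(build_tree(VocabularyTable(rows)))
    for i in range(rng.randint(0, 12)):
        md = {
            p: rng.choice(_VALUES)
            for p in rng.sample(_PHRASES, rng.randint(0, len(_PHRASES)))
        }
        cat.register_series(f"s{i}", md)
    return cat


def _random_query(rng: random.Random) -> Query:
    sels = []
    for _ in range(rng.randint(0, 3)):
        phrase = rng.choice(_PHRASES + ["cell", "assay", "instrument"])
        kind = rng.random()
        if kind < 0.3:
            sels.append(Selection.present(phrase))
        elif kind < 0.7:
            sels.append(Selection.equals(phrase, rng.choice(_VALUES)))
        else:
            sels.append(Selection.is_in(phrase, rng.sample(_VALUES, 2)))
    return Query(tuple(sels))


class TestEvaluate:
    def test_empty_query_returns_all_series(self, small_catalog):
        assert evaluate(small_catalog, Query()) == set(
            small_catalog.series_names
        )

    def test_cell_line_selection_matches_scan(self, default_catalog):
        q = Query((Selection.equals("cell:cell_line", "A10"),))
        result = evaluate(default_catalog, q)
        assert result == _scan_oracle(default_catalog, q)
        assert result == {"A10_well1", "A10_well2", "A10_well3", "A10_masks"}

    def test_conjunction_is_intersection(self, default_catalog):
        a = Query((Selection.equals("cell:cell_line", "A10"),))
        b = Query((Selection.equals("assay:datatype", "raw"),))
        both = Query(a.selections + b.selections)
        assert evaluate(default_catalog, both) == (
            evaluate(default_catalog, a) & evaluate(default_catalog, b)
        )

    def test_folder_level_selection(self, default_catalog):
        """A wildcard selection on an interior phrase matches every series
        holding any key beneath that folder."""
        q = Query((Selection.present("instrument:benchmark"),))
        assert evaluate(default_catalog, q) == {"instrument_benchmarks"}

    def test_unresolvable_phrase_raises(self, small_catalog):
        with pytest.raises(UnknownTermError):
            evaluate(
                small_catalog, Query((Selection.present("cell:no_such"),))
            )

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_linear_scan_on_random_catalogs(self, seed):
        rng = random.Random(seed)
        cat = _random_catalog(rng)
        query = _random_query(rng)
        assert evaluate(cat, query) == _scan_oracle(cat, query)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_adding_a_selection_never_enlarges(self, seed):
        rng = random.Random(seed)
        cat = _random_catalog(rng)
        query = _random_query(rng)
        narrowed = query.and_(
            Selection.equals(rng.choice(_PHRASES), rng.choice(_VALUES))
        )
        assert evaluate(cat, narrowed) <= evaluate(cat, query)


class TestParseSelection:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("cell:cell_line=A10", Selection.equals("cell:cell_line", "A10")),
            ("assay:datatype=raw|derived",
             Selection.is_in("assay:datatype", ["raw", "derived"])),
            ("instrument", Selection.present("instrument")),
            ("cell:cell_line=*", Selection.present("cell:cell_line")),
        ],
    )
    def test_cli_syntax(self, text, expected):
        assert parse_selection(text) == expected


class TestCompare:
    def test_self_comparison_all_equal(self, default_catalog):
        report = compare(default_catalog, "A10_well1", "A10_well1")
        assert report.verdicts and report.all_equal()

    def test_plating_density_differs_between_cell_types(self, default_catalog):
        phrase = "cell:history:maintenance_culture:passaging:plating_density"
        report = compare(
            default_catalog, "A10_well1", "NIH3T3_well1", [phrase]
        )
        (v,) = report.verdicts
        assert v.relation == DIFFERS
        assert v.value_a == "800 cells/cm2"
        assert v.value_b == "1200 cells/cm2"

    def test_instrument_folder_all_equal_across_fixture_series(
        self, default_catalog
    ):
        """Instrument metadata is constructed identically for every fixture
        series, so comparing the whole instrument folder finds no
        difference — and matches a direct map comparison."""
        report = compare(
            default_catalog, "A10_well2", "NIH3T3_well3", ["instrument"]
        )
        assert report.verdicts and report.all_equal()
        ma = default_catalog.series("A10_well2").metadata
        mb = default_catalog.series("NIH3T3_well3").metadata
        keys = {k for k in ma if k.startswith("instrument")}
        assert keys == {k for k in mb if k.startswith("instrument")}
        assert all(ma[k] == mb[k] for k in keys)
        assert len(report.verdicts) == len(keys)

    def test_missing_terms_are_flagged_symmetrically(self, default_catalog):
        phrase = "assay:segmentation:method"
        ab = compare(default_catalog, "A10_well1", "A10_masks", [phrase])
        ba = compare(default_catalog, "A10_masks", "A10_well1", [phrase])
        assert ab.verdicts[0].relation == MISSING_A
        assert ba.verdicts[0].relation == MISSING_B
        assert ab.verdicts[0].value_b == ba.verdicts[0].value_a

    def test_unknown_series(self, default_catalog):
        with pytest.raises(UnknownSeriesError):
            compare(default_catalog, "A10_well1", "nope")
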