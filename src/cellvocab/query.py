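"""Selecting and comparing image series through term-path/value selections.

A query is the programmatic mirror of drilling down a visual data tree:
the user opens folders (term paths) and picks values, and every selection
narrows the result.  Selections therefore combine conjunctively; OR is
expressed as set-membership inside one selection.  Values are opaque strings
("800 cells/cm2" is never parsed as a number) compared exactly after
whitespace trimming.

A selection on an interior (folder) phrase uses folder semantics: with the
wildcard predicate it matches any series holding *any* metadata key at or
beneath that phrase.  Value predicates (equality, membership) apply to the
value stored at the exact phrase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .catalog import Catalog
from .errors import UnknownTermError
from .vocabulary import normalize_term, parse_phrase

#: Sentinel predicate: the term is present (at or beneath the phrase).
ANY = "*"


@dataclass(frozen=True)
class Selection:
    """One (term phrase, value predicate) pair.

    ``values`` is a frozenset of acceptable values; empty means the wildcard
    predicate (term present).  Equality is the one-element case.
    """

    phrase: str
    values: frozenset[str] = frozenset()

    @classmethod
    def equals(cls, phrase: str, value: str) -> "Selection":
        return cls(phrase, frozenset({value.strip()}))

    @classmethod
    def is_in(cls, phrase: str, values: Iterable[str]) -> "Selection":
        return cls(phrase, frozenset(v.strip() for v in values))

    @classmethod
    def present(cls, phrase: str) -> "Selection":
        return cls(phrase)

    @property
    def is_wildcard(self) -> bool:
        return not self.values


@dataclass(frozen=True)
class Query:
    """A conjunction of selections; the empty query is universal."""

    selections: tuple[Selection, ...] = ()

    def and_(self, selection: Selection) -> "Query":
        return Query(self.selections + (selection,))


def parse_selection(text: str) -> Selection:
    """Parse CLI syntax: ``phrase=value``, ``phrase=v1|v2`` or ``phrase``."""
    if "=" not in text:
        return Selection.present(text.strip())
    phrase, _, value = text.partition("=")
    values = [v for v in value.split("|") if v.strip()]
    if not values or value.strip() == ANY:
        return Selection.present(phrase.strip())
    return Selection.is_in(phrase.strip(), values)


def _npath(catalog: Catalog, phrase: str) -> tuple[str, ...]:
    stop = catalog.vocabulary.stop_words
    return tuple(normalize_term(l, stop) for l in parse_phrase(phrase))


def _matches(
    selection_path: tuple[str, ...],
    values: frozenset[str],
    metadata: dict[tuple[str, ...], str],
) -> bool:
    if not values:  # wildcard: key at or beneath the phrase
        return any(
            key[: len(selection_path)] == selection_path for key in metadata
        )
    value = metadata.get(selection_path)
    return value is not None and value.strip() in values


def evaluate(catalog: Catalog, query: Query) -> set[str]:
    """Return the names of exactly the series satisfying every selection.

    Phrases must resolve in the catalog vocabulary — when queries are built
    by clicking the visualized tree this holds by construction, so the
    :class:`UnknownTermError` is only reachable programmatically.  Adding a
    selection can only shrink the result (conjunction is anti-monotone);
    the empty query returns every series.
    """
    compiled: list[tuple[tuple[str, ...], frozenset[str]]] = []
    for sel in query.selections:
        if sel.phrase not in catalog.vocabulary:
            raise UnknownTermError(
                f"query phrase does not resolve in the vocabulary: {sel.phrase!r}"
            )
        compiled.append((_npath(catalog, sel.phrase), sel.values))
    result: set[str] = set()
    for name in catalog.series_names:
        metadata = catalog.normalized_metadata(name)
        if all(_matches(path, values, metadata) for path, values in compiled):
            result.add(name)
    return result


# ---------------------------------------------------------------------------
# dataset comparison
# ---------------------------------------------------------------------------

#: verdict relations
EQUAL, DIFFERS, MISSING_A, MISSING_B = "equal", "differs", "missing_A", "missing_B"


@dataclass(frozen=True)
class Verdict:
    phrase: str
    value_a: str | None
    value_b: str | None
    relation: str


@dataclass
class ComparisonReport:
    """Per-term verdicts from comparing two series' metadata records."""

    series_a: str
    series_b: str
    verdicts: list[Verdict] = field(default_factory=list)

    def relation(self, phrase: str) -> str:
        for v in self.verdicts:
            if v.phrase == phrase:
                return v.relation
        raise KeyError(phrase)

    def all_equal(self) -> bool:
        return all(v.relation == EQUAL for v in self.verdicts)


def compare(
    catalog: Catalog,
    series_a: str,
    series_b: str,
    phrases: Sequence[str] | None = None,
) -> ComparisonReport:
    """Compare two series' metadata values term by term.

    Without ``phrases``, the union of both series' keys is compared.  A
    requested interior phrase (e.g. ``instrument``) expands to every key at
    or beneath it in either series, so whole folders can be compared at
    once.  Values are judged equal after whitespace trimming; a phrase held
    by only one series yields a ``missing_A``/``missing_B`` verdict.  The
    report is symmetric: swapping the series swaps value columns and the
    missing labels.
    """
    meta_a = catalog.series(series_a).metadata
    meta_b = catalog.series(series_b).metadata
    na = {_npath(catalog, p): (p, v) for p, v in meta_a.items()}
    nb = {_npath(catalog, p): (p, v) for p, v in meta_b.items()}

    if phrases is None:
        targets = sorted(set(na) | set(nb))
    else:
        targets = []
        for phrase in phrases:
            prefix = _npath(catalog, phrase)
            beneath = sorted(
                k for k in set(na) | set(nb) if k[: len(prefix)] == prefix
            )
            targets.extend(beneath or [prefix])
        targets = list(dict.fromkeys(targets))  # dedupe, keep order

    verdicts = []
    for key in targets:
        pa, va = na.get(key, (None, None))
        pb, vb = nb.get(key, (None, None))
        phrase = pa or pb or ":".join(key)
        if va is None and vb is None:
            relation = EQUAL  # vacuously: neither series holds the term
        elif va is None:
            relation = MISSING_A
        elif vb is None:
            relation = MISSING_B
        else:
            relation = EQUAL if va.strip() == vb.strip() else DIFFERS
        verdicts.append(Verdict(phrase, va, vb, relation))
    return ComparisonReport(series_a, series_b, verdicts)
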