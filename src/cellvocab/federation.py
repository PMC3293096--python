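"""Merging vocabulary trees from independent federated sites.

Each site grows its own hierarchy under the shared root terms.  Because the
roots (and any other shared prefixes) coincide after normalization, trees can
be merged by unifying nodes with equal normalized paths; everything a site
added locally simply coexists under the common ancestors.  The one failure
mode is synonymy: if site A says ``instrument`` and site B says
``apparatus``, alignment fails silently and the merged tree grows an extra
root.  No automatic synonym inference is attempted — the caller may supply an
explicit label→label synonym map, and every rewrite it causes is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .vocabulary import (
    VocabularyTree,
    add_path,
    concat_path,
    normalize_term,
)


@dataclass
class MergeReport:
    """Result of merging site vocabularies.

    ``shared_paths`` counts normalized paths present in more than one input;
    ``conflicts`` lists every synonym-map rewrite as
    (site index, original phrase, rewritten phrase) — empty iff the synonym
    map never fired.
    """

    merged_tree: VocabularyTree
    shared_paths: int = 0
    conflicts: list[tuple[int, str, str]] = field(default_factory=list)


def merge_trees(
    trees: Sequence[VocabularyTree],
    synonym_map: Mapping[str, str] | None = None,
) -> MergeReport:
    """Merge site trees by aligning nodes with equal normalized paths.

    The merged path set is exactly the union of the inputs' normalized path
    sets: merging is total, idempotent, and commutative/associative at the
    path-set level, and never drops a path present in any input.  When two
    sites attach different example values to the same token, both are kept,
    tagged with their site of origin.  ``synonym_map`` labels are matched on
    their normalized form and rewritten before alignment.
    """
    syn = {
        normalize_term(k): v for k, v in (synonym_map or {}).items()
    }
    merged = VocabularyTree()
    values: dict[tuple[str, ...], list[tuple[int, str]]] = {}
    seen_in: dict[tuple[str, ...], set[int]] = {}
    conflicts: list[tuple[int, str, str]] = []

    for site, tree in enumerate(trees):
        for labels, node in tree.walk():
            rewritten = tuple(syn.get(normalize_term(l), l) for l in labels)
            if rewritten != labels:
                conflicts.append(
                    (site, concat_path(labels), concat_path(rewritten))
                )
            target = add_path(merged, rewritten, on_collision="ignore")
            npath = tuple(normalize_term(l) for l in rewritten)
            seen_in.setdefault(npath, set()).add(site)
            if node.example_value:
                values.setdefault(npath, []).append((site, node.example_value))

    # attach example values; conflicting ones are tagged, not overwritten
    for npath, pairs in values.items():
        node = _resolve_normalized(merged, npath)
        distinct = {v for _, v in pairs}
        if len(distinct) == 1:
            node.example_value = pairs[0][1]
        else:
            node.example_value = " | ".join(
                f"[site{site}] {value}" for site, value in pairs
            )

    shared = sum(1 for sites in seen_in.values() if len(sites) > 1)
    return MergeReport(merged_tree=merged, shared_paths=shared, conflicts=conflicts)


def _resolve_normalized(tree: VocabularyTree, npath: tuple[str, ...]):
    level = {r.normalized_key: r for r in tree.roots}
    node = None
    for key in npath:
        node = level[key]
        level = {c.normalized_key: c for c in node.children}
    return node


def detect_unaligned_roots(trees: Sequence[VocabularyTree]) -> list[str]:
    """Root labels (normalized) present in some but not all input trees.

    These are the points where root alignment fails — typically synonyms
    such as ``apparatus`` next to ``instrument``.  Requires at least two
    trees.
    """
    if len(trees) < 2:
        raise ValueError("detecting unaligned roots needs at least two trees")
    root_sets = [
        {normalize_term(r.label, t.stop_words) for r in t.roots} for t in trees
    ]
    everywhere = set.intersection(*root_sets)
    anywhere = set.union(*root_sets)
    return sorted(anywhere - everywhere)
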