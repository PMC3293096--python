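"""Root-term vocabulary hierarchies.

A vocabulary is a tree of free-text terms organized like nested folders:
a small set of highly reusable root terms (by default ``study``, ``assay``,
``cell`` and ``instrument``) under which experimentalists append ever more
specific terms.  The parent-child relationship carries no name; the position
of a term in the tree is its meaning.  A path from a root down to a term,
joined with ``:``, forms a *phrase* such as::

    cell:history:maintenance_culture:passaging:plating_density

Trees serialize to and from a row-per-term table (the spreadsheet layout an
experimentalist actually fills in): hierarchy columns from general to
specific, a *token* column holding the most specific term of the row, and an
optional example value.

Two labels denote the same term when they differ only in case, whitespace,
dashes, underscores, parentheses/punctuation, or stop words such as "of" —
``cell line``, ``cell_line`` and ``cellline`` are one term.  That equivalence
is implemented by :func:`normalize_term` and used everywhere terms are
compared.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import (
    DuplicateTermError,
    InvalidLabelError,
    InvalidTermError,
    SynonymCollisionWarning,
    TableFormatError,
    UnknownPathError,
)

#: Path delimiter used in phrases.  Labels may contain spaces or underscores
#: but never this character.
PATH_DELIMITER = ":"

#: Default root terms: short, general words reused across many biology
#: ontologies, chosen as the alignment points between federated vocabularies.
DEFAULT_ROOT_TERMS = ("study", "assay", "cell", "instrument")

#: Words ignored when comparing terms.  Only a few are exemplified in
#: practice ("of", parentheses); the list is configurable per call.
DEFAULT_STOP_WORDS = frozenset({"of", "the", "a", "an", "and", "in", "for"})

_WORD_SPLIT = re.compile(r"[^0-9a-z]+")


def normalize_term(label: str, stop_words: frozenset[str] = DEFAULT_STOP_WORDS) -> str:
    """Return the canonical key under which a term label is compared.

    Lower-cases the label, splits it into alphanumeric words (so dashes,
    underscores, whitespace and parentheses all act as separators), drops
    stop words, and concatenates the remainder.  Idempotent: applying it to
    its own output is a no-op.  If dropping stop words would leave nothing
    (a label consisting solely of stop words), the words are kept so the
    label still maps to a non-empty key.

    >>> normalize_term("cell line") == normalize_term("cell_line") == "cellline"
    True
    >>> normalize_term("Time (of) Lapse")
    'timelapse'

    Raises :class:`InvalidTermError` for labels with no alphanumeric content.
    """
    if not isinstance(label, str) or not label.strip():
        raise InvalidTermError(f"term label is empty or whitespace-only: {label!r}")
    words = [w for w in _WORD_SPLIT.split(label.lower()) if w]
    if not words:
        raise InvalidTermError(f"term label has no alphanumeric content: {label!r}")
    kept = [w for w in words if w not in stop_words]
    if not kept:  # label made only of stop words keeps its content
        kept = words
    return "".join(kept)


# ---------------------------------------------------------------------------
# term paths / phrases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermPath:
    """An ordered label sequence from a root down to a target node."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise InvalidLabelError("a term path needs at least one label")
        for lab in self.labels:
            if PATH_DELIMITER in lab:
                raise InvalidLabelError(
                    f"label {lab!r} contains the path delimiter {PATH_DELIMITER!r}"
                )
            if not lab.strip():
                raise InvalidTermError("term path contains an empty label")

    @property
    def phrase(self) -> str:
        return PATH_DELIMITER.join(self.labels)

    @classmethod
    def from_phrase(cls, phrase: str) -> "TermPath":
        return cls(tuple(phrase.split(PATH_DELIMITER)))

    def normalized(self, stop_words: frozenset[str] = DEFAULT_STOP_WORDS) -> tuple[str, ...]:
        return tuple(normalize_term(l, stop_words) for l in self.labels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.phrase


def concat_path(labels: Sequence[str]) -> str:
    """Join labels into a phrase; inverse of :func:`parse_phrase`."""
    return TermPath(tuple(labels)).phrase


def parse_phrase(phrase: str) -> tuple[str, ...]:
    """Split a phrase back into its labels."""
    return TermPath.from_phrase(phrase).labels


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

@dataclass
class TermNode:
    """One folder in the vocabulary hierarchy.

    ``label`` is the term exactly as first entered; ``normalized_key`` is its
    canonical form, unique among siblings.  Children are kept sorted by
    normalized key so traversal order is deterministic.
    """

    label: str
    normalized_key: str
    depth: int = 0
    example_value: str | None = None
    _children: dict[str, "TermNode"] = field(default_factory=dict, repr=False)

    @property
    def children(self) -> list["TermNode"]:
        return [self._children[k] for k in sorted(self._children)]

    def child(self, key: str) -> "TermNode | None":
        return self._children.get(key)

    def is_leaf(self) -> bool:
        return not self._children


class VocabularyTree:
    """An ordered forest of :class:`TermNode` roots.

    Every node is reachable from exactly one parent (a tree, not a DAG); a
    label — including a root label — may recur at several depths, so "root
    terms may be placed at any level" holds without sharing nodes.
    """

    def __init__(self, stop_words: frozenset[str] = DEFAULT_STOP_WORDS) -> None:
        self.stop_words = stop_words
        self._roots: dict[str, TermNode] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def with_default_roots(
        cls, stop_words: frozenset[str] = DEFAULT_STOP_WORDS
    ) -> "VocabularyTree":
        tree = cls(stop_words)
        for label in DEFAULT_ROOT_TERMS:
            tree._ensure_path((label,))
        return tree

    def _ensure_path(
        self, labels: Sequence[str], on_collision: str = "error"
    ) -> TermNode:
        """Walk/create nodes along ``labels``; return the final node.

        ``on_collision`` controls what happens when an existing sibling has
        the same normalized key but a different raw label: "error" raises
        :class:`DuplicateTermError`, "warn" emits a
        :class:`SynonymCollisionWarning` and reuses the existing node,
        "ignore" silently reuses it.
        """
        level = self._roots
        node: TermNode | None = None
        for depth, label in enumerate(labels):
            key = normalize_term(label, self.stop_words)
            existing = level.get(key)
            if existing is None:
                existing = TermNode(label=label, normalized_key=key, depth=depth)
                level[key] = existing
            elif existing.label != label and normalize_term(
                existing.label, self.stop_words
            ) == key:
                msg = (
                    f"label {label!r} collides with existing sibling "
                    f"{existing.label!r} (both normalize to {key!r})"
                )
                if on_collision == "error":
                    raise DuplicateTermError(msg)
                if on_collision == "warn":
                    warnings.warn(msg, SynonymCollisionWarning, stacklevel=3)
            node = existing
            level = existing._children
        assert node is not None
        return node

    # -- queries -----------------------------------------------------------

    @property
    def roots(self) -> list[TermNode]:
        return [self._roots[k] for k in sorted(self._roots)]

    def resolve(self, path: TermPath | str | Sequence[str]) -> TermNode | None:
        """Return the node a path points at, or None."""
        labels = _as_labels(path)
        level = self._roots
        node: TermNode | None = None
        for label in labels:
            node = level.get(normalize_term(label, self.stop_words))
            if node is None:
                return None
            level = node._children
        return node

    def __contains__(self, path: TermPath | str | Sequence[str]) -> bool:
        return self.resolve(path) is not None

    def walk(self) -> Iterator[tuple[tuple[str, ...], TermNode]]:
        """Depth-first traversal yielding (label path, node), children sorted."""
        stack = [((root.label,), root) for root in reversed(self.roots)]
        while stack:
            labels, node = stack.pop()
            yield labels, node
            for child in reversed(node.children):
                stack.append((labels + (child.label,), child))

    def paths(self) -> list[tuple[str, ...]]:
        """Label paths of every node (not just leaves), depth-first."""
        return [labels for labels, _ in self.walk()]

    def normalized_paths(self) -> set[tuple[str, ...]]:
        return {
            tuple(normalize_term(l, self.stop_words) for l in labels)
            for labels in self.paths()
        }

    def node_count(self) -> int:
        return sum(1 for _ in self.walk())

    def leaf_paths(self) -> list[tuple[str, ...]]:
        return [labels for labels, node in self.walk() if node.is_leaf()]


def _as_labels(path: TermPath | str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(path, TermPath):
        return path.labels
    if isinstance(path, str):
        return parse_phrase(path)
    return tuple(path)


def add_term(
    tree: VocabularyTree,
    parent: TermPath | str | Sequence[str],
    label: str,
    example_value: str | None = None,
) -> VocabularyTree:
    """Append ``label`` as a new child under ``parent`` and return the tree.

    The parent path must already resolve; a sibling whose label normalizes to
    the same key is refused (new terms must be substantially different from
    existing ones).  On success the node count grows by exactly one and no
    existing path changes.
    """
    parent_node = tree.resolve(parent)
    if parent_node is None:
        phrase = concat_path(_as_labels(parent))
        raise UnknownPathError(f"parent path does not resolve: {phrase!r}")
    key = normalize_term(label, tree.stop_words)
    existing = parent_node.child(key)
    if existing is not None:
        raise DuplicateTermError(
            f"{label!r} is not substantially different from existing sibling "
            f"{existing.label!r} (both normalize to {key!r})"
        )
    node = TermNode(
        label=label, normalized_key=key, depth=parent_node.depth + 1,
        example_value=example_value,
    )
    parent_node._children[key] = node
    return tree


def add_path(
    tree: VocabularyTree,
    path: TermPath | str | Sequence[str],
    example_value: str | None = None,
    on_collision: str = "error",
) -> TermNode:
    """Ensure every node along ``path`` exists (creating as needed)."""
    node = tree._ensure_path(_as_labels(path), on_collision=on_collision)
    if example_value is not None:
        node.example_value = example_value
    return node


def render_folders(tree: VocabularyTree, indent: str = "  ") -> str:
    """Render the tree as the indented folder listing a query UI would show.

    One line per node, depth-first, children in normalized-key order; the
    line count therefore equals the node count and the output is a pure
    function of the tree.
    """
    lines = [indent * node.depth + node.label for _, node in tree.walk()]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# tabular serialization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableRow:
    """One spreadsheet row: hierarchy cells (general→specific), the token
    (most specific term, never empty) and an optional example value."""

    hierarchy: tuple[str, ...]
    token: str
    value: str = ""

    @property
    def path(self) -> tuple[str, ...]:
        return self.hierarchy + (self.token,)

    @property
    def phrase(self) -> str:
        return concat_path(self.path)


@dataclass
class VocabularyTable:
    """Row-per-term serialization of a vocabulary tree."""

    rows: list[TableRow] = field(default_factory=list)

    def __iter__(self) -> Iterator[TableRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def depth(self) -> int:
        """Number of hierarchy columns needed (longest hierarchy)."""
        return max((len(r.hierarchy) for r in self.rows), default=0)

    def root_labels(self) -> list[str]:
        seen: dict[str, str] = {}
        for row in self.rows:
            root = row.path[0]
            seen.setdefault(normalize_term(root), root)
        return [seen[k] for k in sorted(seen)]


def build_tree(
    table: VocabularyTable,
    on_collision: str = "warn",
    stop_words: frozenset[str] = DEFAULT_STOP_WORDS,
) -> VocabularyTree:
    """Group table rows into a tree of common nodes.

    Rows sharing a normalized prefix share nodes; each row's token becomes a
    node (typically a leaf) holding the row's example value.  Rows whose
    labels collide after normalization but differ in raw text trigger the
    ``on_collision`` policy ("warn" by default so legacy spreadsheets can be
    bulk-imported; "error" to refuse).
    """
    tree = VocabularyTree(stop_words)
    for row in table:
        node = tree._ensure_path(row.path, on_collision=on_collision)
        if row.value and node.example_value is None:
            node.example_value = row.value
    return tree


def to_table(tree: VocabularyTree) -> VocabularyTable:
    """Serialize a tree back to rows, one per leaf.

    Interior nodes are implied by the hierarchy cells of their descendants'
    rows, so ``build_tree(to_table(t))`` reproduces the path set of ``t``.
    """
    rows = [
        TableRow(labels[:-1], labels[-1], node.example_value or "")
        for labels, node in tree.walk()
        if node.is_leaf()
    ]
    return VocabularyTable(rows)


def _split_hierarchy(cells: Sequence[str], row_number: int) -> tuple[str, ...]:
    stripped = [c.strip() for c in cells]
    filled = [c for c in stripped if c]
    # hierarchy cells must be left-aligned: no filled cell after a gap
    first_gap = next((i for i, c in enumerate(stripped) if not c), len(stripped))
    if any(stripped[first_gap:]):
        raise TableFormatError(
            f"row {row_number}: hierarchy cells are not left-aligned "
            f"(a filled cell follows an empty one): {cells!r}"
        )
    return tuple(filled)


def read_table(source: str | Path | io.TextIOBase) -> VocabularyTable:
    """Read a delimited vocabulary table.

    Expects a UTF-8 header row ``level1..levelN,token,value``; comma is the
    canonical delimiter, tab is accepted for ``.tsv`` paths.  Rows with an
    empty token are a format error reported with their row number.
    """
    sep = ","
    if isinstance(source, (str, Path)) and str(source).endswith(".tsv"):
        sep = "\t"
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if "token" not in cols:
        raise TableFormatError(f"no 'token' column in header: {cols!r}")
    level_cols = [c for c in cols if c.lower().startswith("level")]
    has_value = "value" in cols
    rows: list[TableRow] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = rec._asdict() if hasattr(rec, "_asdict") else dict(zip(cols, rec))
        token = str(rec["token"]).strip()
        if not token:
            raise TableFormatError(f"row {i}: empty token")
        hierarchy = _split_hierarchy([str(rec[c]) for c in level_cols], i)
        value = str(rec["value"]).strip() if has_value else ""
        rows.append(TableRow(hierarchy, token, value))
    return VocabularyTable(rows)


def write_table(table: VocabularyTable, dest: str | Path | io.TextIOBase) -> None:
    """Write a table as canonical CSV (ragged hierarchies padded with '')."""
    depth = table.depth
    cols = [f"level{i + 1}" for i in range(depth)] + ["token", "value"]
    records = [
        list(row.hierarchy) + [""] * (depth - len(row.hierarchy)) + [row.token, row.value]
        for row in table
    ]
    pd.DataFrame.from_records(records, columns=cols).to_csv(dest, index=False)
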