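"""The layered store: immutable files, mutable metadata, three linkage tables.

Image (and protocol) files are immutable once registered — any processing
result is a *new* file — while the metadata tables describing them stay
editable and shareable.  The two layers meet in three reference tables, all
joined on the *series name*:

* **series table** — one row per (series, term phrase, value): the metadata
  record of each image series;
* **file table** — series name ↔ image-data filename;
* **protocol table** — series name ↔ free-text protocol filename.

Long free-form descriptions never become metadata values; they live in
separate protocol files linked through the protocol table.

The catalog owns a vocabulary tree and checks every metadata key against it.
Unknown keys are either rejected (``strict`` policy) or appended to the
vocabulary on the fly (``extend`` policy — the local, spontaneous growth of
terms the root-term rules are designed for).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    DuplicateSeriesError,
    ImmutabilityError,
    IntegrityError,
    UnknownFileError,
    UnknownSeriesError,
    UnknownTermError,
)
from .ouri import parse_ouri
from .vocabulary import (
    VocabularyTree,
    add_path,
    build_tree,
    normalize_term,
    parse_phrase,
    read_table,
    to_table,
    write_table,
)

ROLES = ("image", "protocol")

VOCAB_FILE = "vocabulary.csv"
SERIES_FILE = "series.csv"
FILES_FILE = "files.csv"
PROTOCOLS_FILE = "protocols.csv"


@dataclass
class SeriesEntry:
    """One image series: its metadata record and its linked files."""

    series_name: str
    metadata: dict[str, str] = field(default_factory=dict)
    image_files: list[str] = field(default_factory=list)
    protocol_files: list[str] = field(default_factory=list)

    def files(self, role: str) -> list[str]:
        return self.image_files if role == "image" else self.protocol_files


class Catalog:
    """Vocabulary tree + the three linkage tables."""

    def __init__(self, vocabulary: VocabularyTree | None = None) -> None:
        self.vocabulary = vocabulary or VocabularyTree.with_default_roots()
        self._series: dict[str, SeriesEntry] = {}
        self._file_index: dict[str, tuple[str, str]] = {}  # filename -> (series, role)

    # -- registration ------------------------------------------------------

    def register_series(
        self,
        series_name: str,
        metadata: Mapping[str, str],
        policy: str = "strict",
    ) -> SeriesEntry:
        """Add a series row with its term-phrase → value metadata record.

        Every key must resolve in the catalog vocabulary.  Under ``strict``
        an unresolvable key raises :class:`UnknownTermError` naming all
        offending phrases; under ``extend`` the missing paths are appended
        to the vocabulary.
        """
        if policy not in ("strict", "extend"):
            raise ValueError(f"unknown policy {policy!r}")
        if series_name in self._series:
            raise DuplicateSeriesError(
                f"series {series_name!r} is already registered"
            )
        unknown = [k for k in metadata if k not in self.vocabulary]
        if unknown:
            if policy == "strict":
                raise UnknownTermError(
                    "metadata keys do not resolve in the vocabulary: "
                    + ", ".join(repr(k) for k in sorted(unknown))
                )
            for phrase in unknown:
                add_path(self.vocabulary, phrase, on_collision="ignore")
        entry = SeriesEntry(series_name, dict(metadata))
        self._series[series_name] = entry
        return entry

    def register_files(
        self, series_name: str, filenames: Sequence[str], role: str = "image"
    ) -> SeriesEntry:
        """Link OURI filenames to an existing series.

        Filenames must parse as OURIs, and a name already present anywhere
        in the catalog is refused: registered data files are immutable, so
        re-registration can only mean a naming clash or an attempted
        overwrite.
        """
        if role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {role!r}")
        entry = self._series.get(series_name)
        if entry is None:
            raise UnknownSeriesError(f"no series named {series_name!r}")
        for name in filenames:
            parse_ouri(name)  # validates; raises OURIParseError
            if name in self._file_index:
                owner, _ = self._file_index[name]
                raise ImmutabilityError(
                    f"{name!r} is already registered to series {owner!r}; "
                    f"registered files are immutable"
                )
        for name in filenames:
            entry.files(role).append(name)
            self._file_index[name] = (series_name, role)
        return entry

    # -- lookups -----------------------------------------------------------

    @property
    def series_names(self) -> list[str]:
        return list(self._series)

    def series(self, series_name: str) -> SeriesEntry:
        try:
            return self._series[series_name]
        except KeyError:
            raise UnknownSeriesError(f"no series named {series_name!r}") from None

    def __contains__(self, series_name: str) -> bool:
        return series_name in self._series

    def __iter__(self):
        return iter(self._series.values())

    def __len__(self) -> int:
        return len(self._series)

    def series_for_file(self, filename: str) -> str:
        try:
            return self._file_index[filename][0]
        except KeyError:
            raise UnknownFileError(f"no registered file {filename!r}") from None

    def files_for_series(self, series_name: str, role: str | None = None) -> list[str]:
        entry = self.series(series_name)
        if role is None:
            return entry.image_files + entry.protocol_files
        return list(entry.files(role))

    # -- integrity ---------------------------------------------------------

    def validate(self) -> list[str]:
        """Walk all three tables; return a list of problems (empty = sound)."""
        problems: list[str] = []
        for filename, (series_name, role) in self._file_index.items():
            entry = self._series.get(series_name)
            if entry is None:
                problems.append(
                    f"file {filename!r} points at missing series {series_name!r}"
                )
            elif filename not in entry.files(role):
                problems.append(
                    f"file {filename!r} indexed under {series_name!r}/{role} "
                    f"but absent from that series' file list"
                )
        for entry in self._series.values():
            for role in ROLES:
                for filename in entry.files(role):
                    if self._file_index.get(filename) != (entry.series_name, role):
                        problems.append(
                            f"file {filename!r} of series "
                            f"{entry.series_name!r} missing from file index"
                        )
            for phrase in entry.metadata:
                if phrase not in self.vocabulary:
                    problems.append(
                        f"series {entry.series_name!r}: metadata key "
                        f"{phrase!r} does not resolve in the vocabulary"
                    )
        return problems

    def check(self) -> None:
        problems = self.validate()
        if problems:
            raise IntegrityError("; ".join(problems))

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist as four CSV files in canonical order.

        Series and metadata rows are sorted; file rows keep registration
        order within each series (insertion order is part of the record).
        Saving, loading and saving again is byte-identical.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_table(to_table(self.vocabulary), directory / VOCAB_FILE)

        with open(directory / SERIES_FILE, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["series_name", "phrase", "value"])
            for name in sorted(self._series):
                metadata = self._series[name].metadata
                if not metadata:  # keep metadata-less series across reloads
                    w.writerow([name, "", ""])
                for phrase in sorted(metadata):
                    w.writerow([name, phrase, metadata[phrase]])

        for fname, role in ((FILES_FILE, "image"), (PROTOCOLS_FILE, "protocol")):
            with open(directory / fname, "w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(["series_name", "filename"])
                for name in sorted(self._series):
                    for filename in self._series[name].files(role):
                        w.writerow([name, filename])

    @classmethod
    def load(cls, directory: str | Path) -> "Catalog":
        directory = Path(directory)
        vocab = build_tree(read_table(directory / VOCAB_FILE), on_collision="ignore")
        catalog = cls(vocab)
        with open(directory / SERIES_FILE, newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                name = rec["series_name"]
                if name not in catalog._series:
                    catalog._series[name] = SeriesEntry(name)
                if rec["phrase"]:
                    catalog._series[name].metadata[rec["phrase"]] = rec["value"]
        for fname, role in ((FILES_FILE, "image"), (PROTOCOLS_FILE, "protocol")):
            with open(directory / fname, newline="", encoding="utf-8") as fh:
                for rec in csv.DictReader(fh):
                    name, filename = rec["series_name"], rec["filename"]
                    if name not in catalog._series:
                        catalog._series[name] = SeriesEntry(name)
                    catalog._series[name].files(role).append(filename)
                    catalog._file_index[filename] = (name, role)
        return catalog

    # -- normalized views used by the query engine -------------------------

    def normalized_metadata(self, series_name: str) -> dict[tuple[str, ...], str]:
        """Series metadata keyed by normalized label path."""
        entry = self.series(series_name)
        return {
            tuple(normalize_term(l, self.vocabulary.stop_words)
                  for l in parse_phrase(phrase)): value
            for phrase, value in entry.metadata.items()
        }
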