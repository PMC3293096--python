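"""Ontological Unique Resource Identifier (OURI) filenames.

When image data and metadata live in separate layers, the filename is the
only link between a data file and its metadata record, so it must be
unambiguous.  An OURI filename is built from four parts joined by ``_``::

    <content code>_<user region>_<unique id>_s<series number><extension>

* **content code** — one registered letter describing the file kind
  (``I`` image, ``P`` free-text protocol, ``R`` reference/benchmark,
  ``D`` derived data such as segmentation masks; the registry is
  extensible).
* **user region** — free text chosen by the experimentalist (their original
  descriptive filename, folder hints, ...), kept as an intuitive check that
  retrieved data match expectations.  Underscores are escaped to ``-`` so
  the grammar stays unambiguous.
* **unique id** — a site-controlled identifier (uppercase site prefix +
  6-digit counter), giving each federated site local control and making the
  site recognizable.
* **series number** — rendered ``s<n>``; together with the unique id it
  guarantees no two files share a name.

The extension (``.tif``, ``.txt`` ...) rides along verbatim outside the four
parts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import (
    AlreadyNamedError,
    InvalidRegionError,
    OURIParseError,
    UnknownCodeError,
)

#: Default content-code registry: file kinds handled by the catalog.
DEFAULT_CODE_REGISTRY: Mapping[str, str] = {
    "I": "image data",
    "P": "free-text protocol",
    "R": "reference or benchmark data",
    "D": "derived data",
}

PART_DELIMITER = "_"

_UID_RE = re.compile(r"^[A-Z]+[0-9]{6,}$")
_SERIES_RE = re.compile(r"^s([0-9]+)$")
_EXT_RE = re.compile(r"^(?P<stem>.*?)(?P<ext>(\.[A-Za-z0-9]+)+)?$")
_REGION_BAD = re.compile(r"[/\\\x00-\x1f]")


@dataclass(frozen=True)
class OURI:
    """The four parsed parts of an OURI filename, plus its extension."""

    content_code: str
    user_region: str
    unique_id: str
    series_number: int
    extension: str = ""

    @property
    def filename(self) -> str:
        return (
            f"{self.content_code}{PART_DELIMITER}{self.user_region}"
            f"{PART_DELIMITER}{self.unique_id}{PART_DELIMITER}"
            f"s{self.series_number}{self.extension}"
        )


def sanitize_region(text: str) -> str:
    """Escape free text into the user-region alphabet (no delimiter).

    Underscores become dashes; anything that would break a filename
    (path separators, control characters) is refused.
    """
    if _REGION_BAD.search(text):
        raise InvalidRegionError(
            f"user region contains path separators or control characters: {text!r}"
        )
    return text.replace(PART_DELIMITER, "-")


def format_unique_id(site_prefix: str, number: int) -> str:
    """Render a site-controlled unique ID: uppercase prefix + 6-digit counter."""
    prefix = site_prefix.upper()
    if not prefix.isalpha():
        raise InvalidRegionError(f"site prefix must be alphabetic: {site_prefix!r}")
    return f"{prefix}{number:06d}"


def make_ouri(
    content_code: str,
    user_region: str,
    unique_id: str,
    series_number: int,
    extension: str = "",
    registry: Mapping[str, str] = DEFAULT_CODE_REGISTRY,
) -> str:
    """Assemble a filename from the four OURI parts.

    Deterministic; distinct (unique_id, series_number) pairs yield distinct
    filenames.  The user region is sanitized (``_`` escaped to ``-``).
    """
    if content_code not in registry:
        raise UnknownCodeError(
            f"content code {content_code!r} is not registered "
            f"(known: {sorted(registry)})"
        )
    if not _UID_RE.match(unique_id):
        raise OURIParseError(
            f"unique id must be an uppercase site prefix followed by a "
            f"zero-padded counter (≥6 digits): {unique_id!r}"
        )
    if series_number < 0:
        raise OURIParseError(f"series number must be non-negative: {series_number}")
    if extension and not extension.startswith("."):
        extension = "." + extension
    return OURI(
        content_code=content_code,
        user_region=sanitize_region(user_region),
        unique_id=unique_id,
        series_number=series_number,
        extension=extension,
    ).filename


def parse_ouri(
    filename: str, registry: Mapping[str, str] = DEFAULT_CODE_REGISTRY
) -> OURI:
    """Parse a conforming filename back into its four parts.

    The error message names the first grammar rule the filename violates,
    so legacy names (e.g. lacking the unique-ID part) are rejected with a
    diagnosis rather than a generic failure.
    """
    m = _EXT_RE.match(filename)
    stem, extension = m.group("stem"), m.group("ext") or ""
    parts = stem.split(PART_DELIMITER)
    if len(parts) != 4:
        raise OURIParseError(
            f"{filename!r}: expected four {PART_DELIMITER!r}-separated parts "
            f"(content code, user region, unique id, series number), "
            f"got {len(parts)}"
        )
    code, region, uid, series = parts
    if len(code) != 1 or code not in registry:
        raise OURIParseError(
            f"{filename!r}: first part must be a single registered content "
            f"code letter (known: {sorted(registry)}), got {code!r}"
        )
    if not _UID_RE.match(uid):
        raise OURIParseError(
            f"{filename!r}: third part must be a unique id "
            f"(uppercase prefix + ≥6-digit counter), got {uid!r}"
        )
    sm = _SERIES_RE.match(series)
    if not sm:
        raise OURIParseError(
            f"{filename!r}: fourth part must be 's' followed by a series "
            f"number, got {series!r}"
        )
    return OURI(
        content_code=code,
        user_region=region,
        unique_id=uid,
        series_number=int(sm.group(1)),
        extension=extension,
    )


def is_ouri(filename: str, registry: Mapping[str, str] = DEFAULT_CODE_REGISTRY) -> bool:
    try:
        parse_ouri(filename, registry)
        return True
    except OURIParseError:
        return False


def assign_unique_ids(
    filenames: Sequence[str],
    site_prefix: str,
    start_id: int = 1,
    series_number: int = 1,
    registry: Mapping[str, str] = DEFAULT_CODE_REGISTRY,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Rename experimentalist-chosen files into full OURIs.

    Input names must carry a content code and the user's chosen text
    (``<code>_<chosen name><ext>``); each gains a fresh unique id
    (site prefix + dense counter from ``start_id``) and a series number,
    with the chosen text preserved in the user region.  Returns the renamed
    list and an old→new mapping table.  A file already carrying a unique id
    is refused — renaming twice would silently break the metadata link.
    """
    renamed: list[str] = []
    mapping: list[tuple[str, str]] = []
    for offset, old in enumerate(filenames):
        if is_ouri(old, registry):
            raise AlreadyNamedError(
                f"{old!r} already carries a unique id; refusing to rename twice"
            )
        m = _EXT_RE.match(old)
        stem, extension = m.group("stem"), m.group("ext") or ""
        if len(stem) < 2 or stem[1] != PART_DELIMITER:
            raise OURIParseError(
                f"{old!r}: input names must start with a one-letter content "
                f"code followed by {PART_DELIMITER!r}"
            )
        code, chosen = stem[0], stem[2:]
        if code not in registry:
            raise UnknownCodeError(
                f"{old!r}: content code {code!r} is not registered"
            )
        new = make_ouri(
            code,
            sanitize_region(chosen),
            format_unique_id(site_prefix, start_id + offset),
            series_number,
            extension,
            registry,
        )
        renamed.append(new)
        mapping.append((old, new))
    return renamed, mapping
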