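"""Exception hierarchy for cellvocab.

Every error raised by the library derives from :class:`CellVocabError`, so
callers (including the CLI) can catch one type.  Warnings derive from
:class:`CellVocabWarning`.
"""


class CellVocabError(Exception):
    """Base class for all cellvocab errors."""


class CellVocabWarning(UserWarning):
    """Base class for all cellvocab warnings."""


# --- vocabulary -----------------------------------------------------------

class InvalidTermError(CellVocabError):
    """A term label is empty, whitespace-only, or normalizes to nothing."""


class InvalidLabelError(CellVocabError):
    """A label contains the path delimiter and cannot appear in a phrase."""


class UnknownPathError(CellVocabError):
    """A term path does not resolve to a node in the vocabulary tree."""


class DuplicateTermError(CellVocabError):
    """A sibling with the same normalized key already exists.

    Terms must be substantially different from existing terms; labels that
    differ only in case, dashes, underscores, whitespace, parentheses or
    stop words denote the same term.
    """


class SynonymCollisionWarning(CellVocabWarning):
    """Two raw labels normalize to the same key during a bulk import."""


class TableFormatError(CellVocabError):
    """A vocabulary table violates its layout (e.g. a row without a token)."""


# --- ouri -----------------------------------------------------------------

class OURIError(CellVocabError):
    """Base class for file-naming errors."""


class UnknownCodeError(OURIError):
    """Content code is not in the registered code set."""


class InvalidRegionError(OURIError):
    """User-defined region cannot be sanitized into the filename grammar."""


class OURIParseError(OURIError):
    """A filename does not conform to the four-part OURI grammar."""


class AlreadyNamedError(OURIError):
    """A file already carries a unique ID; renaming it again is refused."""


# --- catalog --------------------------------------------------------------

class CatalogError(CellVocabError):
    """Base class for catalog errors."""


class DuplicateSeriesError(CatalogError):
    """A series with this name is already registered."""


class UnknownSeriesError(CatalogError):
    """No series with this name exists in the catalog."""


class UnknownFileError(CatalogError):
    """No registered file with this name exists in the catalog."""


class ImmutabilityError(CatalogError):
    """Attempt to re-register a filename: registered data files are immutable."""


class UnknownTermError(CatalogError):
    """A metadata key does not resolve in the catalog vocabulary."""


class IntegrityError(CatalogError):
    """Referential integrity between the linkage tables is broken."""
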