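"""Exception hierarchy shared across the package.

Grouped so the command-line layer can map failures onto exit codes:
usage problems are left to click, :class:`DataError` subclasses exit
with 3, :class:`DegeneracyError` subclasses with 4.
"""


class LingsyncError(Exception):
    """Base class for all package-specific errors."""


class DataError(LingsyncError):
    """Malformed or inconsistent input data."""


class TranscriptParseError(DataError):
    """A transcript line could not be attributed to a known speaker."""


class TranscriptFormatError(DataError):
    """Raw text contains no recognizable speaker prefixes."""


class DictionaryFormatError(DataError):
    """A .dic category dictionary violates the expected layout."""


class MissingCategoryError(DataError):
    """A summary-variable composition references an unscored category."""


class AssemblyError(DataError):
    """Profiles cannot be assembled into a complete dyad matrix."""


class ConsistencyError(DataError):
    """Report parts computed on different dyads or configurations."""


class DegeneracyError(LingsyncError):
    """A numerical degeneracy (zero variance, deficient rank, ...)."""
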