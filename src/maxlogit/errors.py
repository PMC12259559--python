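"""Exception hierarchy.

All library errors derive from :class:`MaxLogitError` so callers (and the
CLI) can distinguish user/data problems (exit code 2) from genuine bugs
(exit code 1).
"""


class MaxLogitError(Exception):
    """Base class for all maxlogit errors."""


class ValidationError(MaxLogitError):
    """Invalid input data or inconsistent arguments."""


class ParseError(MaxLogitError):
    """A delimited text file could not be parsed."""


class DomainError(MaxLogitError):
    """A value falls outside a transform's mathematical domain."""


class FitError(MaxLogitError):
    """A model fit is impossible on the given data (e.g. constant genes)."""


class FixtureLookupError(MaxLogitError):
    """Unknown bundled fixture name."""
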