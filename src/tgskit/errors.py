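"""Exception hierarchy.

All package errors derive from :class:`TgsError` so callers can catch one
type at pipeline boundaries while tests discriminate on the subclasses.
"""


class TgsError(Exception):
    """Base class for all tgskit errors."""


class FormatError(TgsError):
    """Input file structure is wrong (missing column, bad header, unknown format)."""


class ValidationError(TgsError):
    """A record's content violates the panel or data contract."""


class ConfigurationError(TgsError):
    """A panel / weight / simulation configuration is invalid."""


class UndefinedStatisticError(TgsError):
    """The requested statistic is undefined for the given inputs (e.g. zero variance)."""
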