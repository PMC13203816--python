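"""Exception hierarchy.

All package-specific failures derive from :class:`MacrossError` so callers
(and the CLI) can catch one base class.
"""


class MacrossError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MacrossError):
    """A file does not conform to the expected delimited dialect
    (missing columns, unknown event labels, unparseable values)."""


class DataError(MacrossError):
    """The file parsed but its content violates a data invariant
    (non-uniform sampling, non-monotone times, broken trial structure)."""


class ConfigurationError(MacrossError):
    """Parameters are inconsistent (invalid band, fast >= slow window,
    detection window that cannot be satisfied, ...)."""


class EvaluationError(MacrossError):
    """Outcome classification or metric aggregation received inputs it
    cannot score (no trials, missing movement onset on a GO trial)."""
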