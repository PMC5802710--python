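"""Exception hierarchy for the CBC pipeline.

Every error raised by this package derives from :class:`EpmcbcError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class EpmcbcError(Exception):
    """Base class for all errors raised by epmcbc."""


class SchemaError(EpmcbcError):
    """An input table is missing a required column."""


class ParseError(EpmcbcError):
    """A cell in an input table could not be parsed as a number."""


class ValidationError(EpmcbcError):
    """Data violate a structural invariant (duplicate ids, negative
    values, missing measures, unknown group labels, ...)."""


class ConfigError(EpmcbcError):
    """The analysis configuration is inconsistent or incomplete."""


class AnalysisError(EpmcbcError):
    """A statistical routine refused to run (empty design cell, no
    residual degrees of freedom, degenerate reference proportions, ...)."""


class CutoffWarning(UserWarning):
    """Non-fatal condition while deriving control cutoffs, e.g. a
    measure that is constant across the control group."""
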