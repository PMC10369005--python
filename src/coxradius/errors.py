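"""Exception hierarchy.

Errors are split so callers (and the CLI exit codes) can distinguish bad
configuration, bad data, geometry problems, and numerical non-convergence.
"""


class CoxRadiusError(Exception):
    """Base class for all package errors."""


class ParameterError(CoxRadiusError, ValueError):
    """A configuration value is out of its valid range."""


class GeometryError(CoxRadiusError, ValueError):
    """A mask or volume violates a geometric precondition."""


class SizingError(GeometryError):
    """The simulation grid cannot hold the tumour plus the required margin."""


class DataError(CoxRadiusError, ValueError):
    """Input data is malformed (non-finite values, missing columns, ...)."""


class SchemaError(DataError):
    """A required model term or table column is missing."""


class ConvergenceError(CoxRadiusError, RuntimeError):
    """A fit failed in a way that cannot be reported as a flag."""


class UsageError(CoxRadiusError, ValueError):
    """An operation was called with incompatible arguments."""
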