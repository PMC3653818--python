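"""Exception hierarchy shared across the package.

All errors raised on bad user input derive from :class:`RegistatError`
so callers (and the CLI) can catch one base class.
"""


class RegistatError(ValueError):
    """Base class for all registat errors."""


class SchemaError(RegistatError):
    """A file is missing mandatory columns or has an unusable header."""


class RowValidationError(RegistatError):
    """A data row violates an invariant; message names the row and value."""


class DuplicateKeyError(RegistatError):
    """Two rows share the same (sex, age-group, year, disease) key."""


class CoverageError(RegistatError):
    """A required cell (population, reference rate, life-table entry) is absent."""


class AlignmentError(RegistatError):
    """Requested age bounds do not align with the age-group scheme."""


class ZeroRateError(RegistatError):
    """A rate of zero makes the log-scale model undefined."""


class InsufficientDataError(RegistatError):
    """Too few data points to fit the requested model."""


class FitError(RegistatError):
    """A model failed to converge; carries family and slope type."""


class SchemeMismatchError(RegistatError):
    """Two inputs use different age-group schemes."""
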