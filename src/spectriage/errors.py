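"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`SpectriageError`, so callers can catch package errors without
swallowing genuine bugs.
"""


class SpectriageError(Exception):
    """Base class for all errors raised by spectriage."""


class ConfigurationError(SpectriageError, ValueError):
    """A configuration object is internally inconsistent; the message names the field."""


class FormatError(SpectriageError, ValueError):
    """An on-disk file violates the expected interchange format."""


class SchemaError(FormatError):
    """A tabular file is missing mandatory columns; the message lists them."""


class UsageError(SpectriageError, ValueError):
    """An operation was called with arguments outside its contract."""


class DegenerateInputError(UsageError):
    """Input is syntactically valid but degenerate (e.g. an all-zero spectrum)."""


class DesignError(SpectriageError, ValueError):
    """A cohort or resampling design is infeasible (e.g. a class with <2 patients)."""


class LeakageError(SpectriageError, RuntimeError):
    """A test-set or external patient became reachable during training/tuning."""


class BlindingError(LeakageError):
    """An external cohort shares patient ids with the training cohort."""


class ModelError(SpectriageError, ValueError):
    """A fitted model was applied to incompatible data (e.g. wrong feature dimension)."""


class EvanescenceError(SpectriageError, ValueError):
    """Optics parameters do not satisfy the total-internal-reflection condition."""
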