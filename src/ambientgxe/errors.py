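"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
ModelError -> 4. Everything raised by the package derives from
AmbientGxeError so callers can catch one base class.
"""


class AmbientGxeError(Exception):
    """Base class for all package errors."""


class ConfigError(AmbientGxeError):
    """Invalid configuration (bad ranges, malformed file, failed schema)."""


class DataError(AmbientGxeError):
    """Malformed or inconsistent input data (unknown genotype label, ...)."""


class UndefinedExposureError(DataError):
    """A subject has zero recorded (geocoded) years in the exposure window."""


class ThresholdUndefinedError(DataError):
    """No exposed control exists, so a median threshold cannot be formed."""


class InvalidWindowError(DataError):
    """Exposure window [start_year, index_year - lag] is empty."""


class ModelError(AmbientGxeError):
    """Estimation failure."""


class SeparationError(ModelError):
    """Complete or quasi-complete separation in a logistic fit."""

    def __init__(self, message, term=None):
        super().__init__(message)
        self.term = term


class CollinearityError(ModelError):
    """Singular design matrix."""


class InestimableError(ModelError):
    """A required cell of the genotype x exposure table is empty."""

    def __init__(self, message, cell=None):
        super().__init__(message)
        self.cell = cell


class DegenerateTestError(ModelError):
    """A test statistic is undefined (monomorphic sample, constant input)."""
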