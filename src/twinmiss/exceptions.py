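"""Exception hierarchy for twinmiss."""


class TwinMissError(Exception):
    """Base class for all package errors."""


class DataFormatError(TwinMissError, ValueError):
    """Malformed input file: missing columns, bad schema."""


class TraitValueError(TwinMissError, ValueError):
    """A trait value violates its declared kind or range."""


class SpecError(TwinMissError, ValueError):
    """Invalid simulation or pipeline specification."""


class DegenerateInputError(TwinMissError, ValueError):
    """Input too small or too uniform for the requested statistic."""


class SampleSizeError(TwinMissError, ValueError):
    """Too few pairs for the requested fit."""


class TransformFailureError(TwinMissError, ValueError):
    """No power in the declared grid achieved the target skewness."""

    def __init__(self, message, best_power=None, best_skew=None):
        super().__init__(message)
        self.best_power = best_power
        self.best_skew = best_skew


class OptimizationError(TwinMissError, RuntimeError):
    """Maximum-likelihood optimisation failed to converge."""


class ConfigError(TwinMissError, ValueError):
    """Invalid pipeline configuration."""
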