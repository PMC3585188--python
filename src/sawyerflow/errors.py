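"""Exception types shared across the pipeline."""


class SawyerflowError(Exception):
    """Base class for all package errors."""


class AlignmentError(SawyerflowError):
    """Malformed alignment (length mismatch, bad alphabet, empty input)."""


class PopmapError(SawyerflowError):
    """Individual/population bookkeeping problem (unknown id, missing mapping)."""


class SaturationError(SawyerflowError):
    """K2P log argument fell to <= 0; the distance is undefined at this divergence."""


class InsufficientSampleError(SawyerflowError):
    """A statistic requested for fewer individuals than it is defined on."""


class UndefinedStatisticError(SawyerflowError):
    """The statistic is undefined on this input (e.g. Fst with zero variance)."""


class DegenerateDataError(SawyerflowError):
    """Input carries no usable signal (e.g. all-zero distance matrix)."""


class ConfigError(SawyerflowError):
    """Invalid run or simulation configuration."""
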