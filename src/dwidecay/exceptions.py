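"""Exception types raised across the package."""


class DWIDecayError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DWIDecayError, ValueError):
    """A parameter set or option violates its invariants."""


class UnfittableVoxelError(DWIDecayError, ValueError):
    """A voxel's signal cannot be normalized or fitted (e.g. S0 <= 0, NaN)."""


class UndefinedStatisticError(DWIDecayError, ValueError):
    """A statistic is undefined for the given input (e.g. SNR of identical images)."""
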