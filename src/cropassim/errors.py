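"""Exception hierarchy for the cropassim package."""


class CropAssimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CropAssimError):
    """Invalid parameter table, crop parameter set, or pipeline configuration."""


class IncompleteSeasonError(CropAssimError):
    """Weather forcing ended before the crop reached maturity.

    Carries the partial trajectory so callers can inspect how far the
    simulation got.
    """

    def __init__(self, message, partial_trajectory=None):
        super().__init__(message)
        self.partial_trajectory = partial_trajectory


class OutOfRangeDateError(CropAssimError):
    """A requested date falls outside the simulated trajectory span."""


class UndefinedStatisticError(CropAssimError):
    """An evaluation statistic is undefined for the given series."""


class OptimizationFailureError(CropAssimError):
    """Every optimization start failed to produce a usable simulation."""
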