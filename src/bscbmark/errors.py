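"""Exception hierarchy for bscb-mark."""


class BscbMarkError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(BscbMarkError, ValueError):
    """A phantom/cohort specification violates its invariants."""


class UnidentifiableSchemeError(SpecValidationError):
    """Gradient scheme has too few non-collinear directions to identify a tensor."""


class DegenerateCalibrationError(BscbMarkError):
    """Threshold calibration is impossible (e.g. constant map)."""


class NormalizationError(BscbMarkError):
    """Longitudinal normalization against a non-positive baseline."""


class MissingChannelError(BscbMarkError, KeyError):
    """A required fluorescence channel is absent from the image."""


class StatisticsError(BscbMarkError):
    """A statistical operation cannot be computed from the given data."""


class CollinearityError(StatisticsError):
    """Predictors are (near-)perfectly collinear; names the offenders."""

    def __init__(self, predictors, condition_number):
        self.predictors = list(predictors)
        self.condition_number = condition_number
        super().__init__(
            f"predictor matrix ill-conditioned (cond={condition_number:.3g}); "
            f"offending predictors: {', '.join(self.predictors)}"
        )
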