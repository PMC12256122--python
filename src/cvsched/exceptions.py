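"""Exception hierarchy shared across the package."""


class CvschedError(Exception):
    """Base class for package errors."""


class ParameterError(CvschedError, ValueError):
    """Invalid model or simulator parameters (e.g. non-PSD covariance)."""


class InputError(CvschedError, ValueError):
    """Invalid user input to an operation (bad ages, missing covariates...)."""


class EstimationError(CvschedError, RuntimeError):
    """A statistical fit failed (no events, separation, singular system)."""


class UndefinedMetricError(CvschedError, RuntimeError):
    """A validation metric is undefined on the supplied data."""
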