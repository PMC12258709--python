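"""Exception hierarchy for timescale estimation."""


class TimescalesError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(TimescalesError, ValueError):
    """A series or ACF carries no usable signal (e.g. zero variance)."""


class InvalidLagError(TimescalesError, ValueError):
    """A requested lag count is incompatible with the series length."""


class StationarityError(TimescalesError, ValueError):
    """Autoregressive coefficients fall outside the stationary region."""


class PositiveDefiniteError(TimescalesError, ValueError):
    """A target covariance matrix could not be made positive definite."""
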