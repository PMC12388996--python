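"""Exception hierarchy for liporelax."""


class LiporelaxError(Exception):
    """Base class for all liporelax errors."""


class InvalidParameterError(LiporelaxError, ValueError):
    """A model or generator parameter violates its physical constraint."""


class FitFailureError(LiporelaxError, RuntimeError):
    """Nonlinear least squares did not converge or the data cannot constrain the model."""


class DomainError(LiporelaxError, ValueError):
    """A requested inversion/normalization lies outside the mathematical domain."""


class EmptyInputError(LiporelaxError, ValueError):
    """An operation requiring at least one record received none."""


class UnestimableIC50Error(FitFailureError):
    """Viability data never cross 50% of control, so the half-maximal dose is unbounded."""

    def __init__(self, message: str, nearest_bound_um: float | None = None):
        super().__init__(message)
        self.nearest_bound_um = nearest_bound_um
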