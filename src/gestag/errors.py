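"""Typed exceptions raised across the package.

Every error a caller may want to catch derives from :class:`GestagError`,
so ``except GestagError`` distinguishes model/validation failures from
programming errors.
"""


class GestagError(Exception):
    """Base class for all package-specific errors."""


class WeekRangeError(GestagError, ValueError):
    """Gestational week outside the supported 0–42-week range."""


class DegenerateCurveError(GestagError, ValueError):
    """A fitted physiological curve evaluated to a non-physical value
    (e.g. non-positive GFR), or lacks the required shape (no interior
    maximum for a non-concave quadratic)."""


class PhysioRangeError(GestagError, ValueError):
    """An evaluated physiological quantity left its admissible range
    (fractional plasma mass outside (0, 1], plasma volume <= 0)."""


class UnderdeterminedError(GestagError, ValueError):
    """Too few distinct observation weeks to identify the curve."""


class FitFailureError(GestagError, RuntimeError):
    """Iterative curve fit failed to converge."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class InvalidReabsorptionError(GestagError, ValueError):
    """Reabsorption fraction evaluated outside the open interval (0, 1)."""


class ClearanceVanishesError(GestagError, ZeroDivisionError):
    """1 - r fell below numerical tolerance: renal clearance of the tracer
    vanishes and the steady state diverges."""


class ConvergenceError(GestagError, RuntimeError):
    """Fast-time integration did not reach steady state within the horizon."""


class IdentifiabilityError(GestagError, ValueError):
    """Requested free-parameter set is structurally non-identifiable."""


class SchemaError(GestagError, ValueError):
    """Tabular input violated the expected schema."""


class ZeroVarianceError(GestagError, ValueError):
    """Coefficient of determination undefined: observations have no variance."""
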