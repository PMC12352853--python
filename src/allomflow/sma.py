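"""Standardized major axis regression and scaling-exponent model competition.

Everything operates on log10-transformed axes.  The slope of an SMA line is
``sign(r) * sd(log10 y) / sd(log10 x)`` and its confidence interval follows
the standard F-based construction (Warton et al. 2006, eq. 6):

    B = F(ci_level; 1, n - 2) * (1 - r^2) / (n - 2)
    CI = slope * (sqrt(B + 1) -/+ sqrt(B))

Exponent predictions for the six variable pairs are closed-form functions of
the length-diameter exponent ``alpha``: the constrained flow-similarity model
(CFS) uses alpha = 2 and the elastic-similarity / WBE model uses alpha = 2/3.
Model competition scores each fitted slope by its absolute deviation from the
predicted exponent; :func:`running_rmse` additionally provides the
expanding-window RMSE used when several group fits are scored as a sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import f as f_dist

from allomflow.exceptions import ValidationError

__all__ = [
    "PAIRS",
    "PAIR_LABELS",
    "CFS",
    "WBE",
    "SMAFit",
    "ModelPrediction",
    "ModelEvaluation",
    "sma_fit",
    "predict_exponents",
    "predicted_exponent",
    "evaluate_model",
    "running_rmse",
]

#: The six ordered (y, x) variable pairs, in canonical report order.
PAIRS: tuple[tuple[str, str], ...] = (
    ("surface_area", "volume"),
    ("length", "diameter"),
    ("diameter", "volume"),
    ("length", "volume"),
    ("diameter", "surface_area"),
    ("length", "surface_area"),
)

PAIR_LABELS: Mapping[tuple[str, str], str] = {
    ("surface_area", "volume"): "SA~V",
    ("length", "diameter"): "L~D",
    ("diameter", "volume"): "D~V",
    ("length", "volume"): "L~V",
    ("diameter", "surface_area"): "D~SA",
    ("length", "surface_area"): "L~SA",
}


@dataclass(frozen=True)
class SMAFit:
    """SMA regression result for one variable pair on log10-log10 axes."""

    pair: tuple[str, str]
    group: str
    n: int
    r_squared: float
    slope: float
    slope_ci_low: float
    slope_ci_high: float
    intercept: float
    intercept_ci_low: float
    intercept_ci_high: float


@dataclass(frozen=True)
class ModelPrediction:
    """Exponent set implied by one value of the length-diameter exponent alpha."""

    model_name: str
    alpha: object  # number-like; Fraction inputs propagate exactly
    exponents: Mapping[tuple[str, str], object]


@dataclass(frozen=True)
class ModelEvaluation:
    """One fitted slope scored against one model's predicted exponent."""

    fit: SMAFit
    model_name: str
    predicted: float
    rmse: float


def predicted_exponent(pair: tuple[str, str], alpha):
    """Closed-form predicted log-log slope for ``pair`` given exponent ``alpha``.

    Arithmetic is generic: pass a :class:`fractions.Fraction` to get exact
    rational exponents.
    """
    if not alpha > 0:
        raise ValidationError(f"alpha must be > 0, got {alpha}")
    y, x = pair
    if (y, x) == ("surface_area", "volume"):
        return (alpha + 1) / (alpha + 2)
    if (y, x) == ("length", "diameter"):
        return alpha
    if (y, x) == ("diameter", "volume"):
        return 1 / (alpha + 2)
    if (y, x) == ("length", "volume"):
        return alpha / (alpha + 2)
    if (y, x) == ("diameter", "surface_area"):
        return 1 / (alpha + 1)
    if (y, x) == ("length", "surface_area"):
        return alpha / (alpha + 1)
    raise ValidationError(f"unknown variable pair {pair!r}; expected one of {list(PAIRS)}")


def predict_exponents(alpha, model_name: str = "custom") -> ModelPrediction:
    """Predicted exponents for all six pairs under exponent ``alpha``."""
    exponents = {pair: predicted_exponent(pair, alpha) for pair in PAIRS}
    return ModelPrediction(model_name=model_name, alpha=alpha, exponents=exponents)


#: Constrained flow-similarity prediction (alpha = 2), exact rationals.
CFS = predict_exponents(Fraction(2), "CFS")
#: Elastic-similarity / WBE prediction (alpha = 2/3), exact rationals.
WBE = predict_exponents(Fraction(2, 3), "WBE")


def _validate_positive(name: str, values: np.ndarray) -> None:
    bad = np.flatnonzero(~(np.isfinite(values) & (values > 0)))
    if bad.size:
        raise ValidationError(
            f"{name} must be positive and finite; offending row indices: {bad.tolist()[:20]}"
        )


def sma_fit(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    ci_level: float = 0.95,
    pair: tuple[str, str] = ("length", "diameter"),
    group: str = "all",
) -> SMAFit:
    """Fit a standardized major axis line to log10(x), log10(y).

    The intercept CI is propagated from the slope CI endpoints through the
    sample means (``intercept = mean(log10 y) - slope * mean(log10 x)``); it
    is documented as a propagation, not the exact small-sample interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"x and y must be 1-d arrays of equal length, got {x.shape} and {y.shape}")
    n = x.size
    if n < 3:
        raise ValidationError(f"SMA fit requires n >= 3, got n={n}")
    if not 0 < ci_level < 1:
        raise ValidationError(f"ci_level must lie in (0, 1), got {ci_level}")
    _validate_positive("x", x)
    _validate_positive("y", y)

    lx = np.log10(x)
    ly = np.log10(y)
    sx = lx.std(ddof=1)
    sy = ly.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValidationError("zero variance in log10(x) or log10(y); SMA slope undefined")
    r = float(np.corrcoef(lx, ly)[0, 1])
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    xbar = lx.mean()
    ybar = ly.mean()
    intercept = ybar - slope * xbar

    r2 = min(r * r, 1.0)
    B = float(f_dist.ppf(ci_level, 1, n - 2)) * (1.0 - r2) / (n - 2)
    bounds = sorted((slope * (math.sqrt(B + 1.0) - math.sqrt(B)), slope * (math.sqrt(B + 1.0) + math.sqrt(B))))
    icpt_bounds = sorted((ybar - bounds[0] * xbar, ybar - bounds[1] * xbar))
    return SMAFit(
        pair=pair,
        group=group,
        n=n,
        r_squared=r2,
        slope=slope,
        slope_ci_low=bounds[0],
        slope_ci_high=bounds[1],
        intercept=intercept,
        intercept_ci_low=icpt_bounds[0],
        intercept_ci_high=icpt_bounds[1],
    )


def evaluate_model(fit: SMAFit, prediction: ModelPrediction) -> ModelEvaluation:
    """Score one fit against one model: RMSE of a single slope is |observed - predicted|."""
    if fit.pair not in prediction.exponents:
        raise ValidationError(f"prediction {prediction.model_name!r} has no exponent for pair {fit.pair!r}")
    predicted = float(prediction.exponents[fit.pair])
    return ModelEvaluation(
        fit=fit,
        model_name=prediction.model_name,
        predicted=predicted,
        rmse=abs(fit.slope - predicted),
    )


def running_rmse(deviations: Sequence[float] | np.ndarray) -> np.ndarray:
    """Expanding-window RMSE over an ordered sequence of slope deviations.

    Element ``k`` is ``sqrt(mean(deviations[: k + 1] ** 2))``.  This is the
    convention for scoring a sequence of per-group fits cumulatively: the
    first element reduces to ``|deviation|`` and the last is the RMSE across
    all groups.
    """
    d = np.asarray(deviations, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValidationError("running_rmse requires a non-empty 1-d sequence")
    return np.sqrt(np.cumsum(d * d) / np.arange(1, d.size + 1))
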