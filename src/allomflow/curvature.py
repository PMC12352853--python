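"""Concavity/convexity classification of log-log bivariate relationships.

A second-order polynomial ``a*x**2 + b*x + c`` is least-squares fitted to the
log10-transformed data and the relationship is classified by the sign of the
second derivative ``2a``: concave for ``a < 0``, convex for ``a > 0``.
Ordinary least squares is used (only the sign of ``a`` matters and SMA has no
standard quadratic analogue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from allomflow.exceptions import ValidationError

__all__ = ["EXPECTED_CURVATURE", "CurvatureResult", "classify_curvature", "bootstrap_sign_stability"]

#: Expected curvature per variable pair under the full flow-similarity model.
EXPECTED_CURVATURE: dict[tuple[str, str], str] = {
    ("surface_area", "volume"): "concave",
    ("length", "diameter"): "concave",
    ("diameter", "volume"): "convex",
    ("length", "volume"): "concave",
    ("diameter", "surface_area"): "convex",
    ("length", "surface_area"): "concave",
}


@dataclass(frozen=True)
class CurvatureResult:
    pair: tuple[str, str]
    group: str
    quad_coeff: float
    classification: Optional[str]  # "concave" | "convex" | None when degenerate
    degenerate: bool
    predicted: Optional[str]
    matches_prediction: Optional[bool]


def _check_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"x and y must be 1-d arrays of equal length, got {x.shape} and {y.shape}")
    if x.size < 4:
        raise ValidationError(f"curvature classification requires n >= 4, got n={x.size}")
    bad = np.flatnonzero(~(np.isfinite(x) & (x > 0) & np.isfinite(y) & (y > 0)))
    if bad.size:
        raise ValidationError(f"positive finite data required; offending row indices: {bad.tolist()[:20]}")


def classify_curvature(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    pair: tuple[str, str] = ("length", "diameter"),
    group: str = "all",
    predicted: Optional[str] = None,
) -> CurvatureResult:
    """Classify the log-log relationship of (x, y) by the sign of the fitted quadratic.

    ``predicted`` defaults to the expectation in :data:`EXPECTED_CURVATURE`
    when the pair is one of the six canonical ones.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_inputs(x, y)
    lx = np.log10(x)
    ly = np.log10(y)
    if np.unique(lx).size < 3:
        raise ValidationError("need at least 3 distinct x values to fit a quadratic")
    a = float(np.polyfit(lx, ly, 2)[0])
    if predicted is None and pair in EXPECTED_CURVATURE:
        predicted = EXPECTED_CURVATURE[pair]
    if a == 0.0:
        return CurvatureResult(pair, group, a, None, True, predicted, None)
    classification = "concave" if a < 0 else "convex"
    matches = None if predicted is None else (classification == predicted)
    return CurvatureResult(pair, group, a, classification, False, predicted, matches)


def bootstrap_sign_stability(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Diagnostic only: fraction of bootstrap resamples whose quadratic sign
    agrees with the full-data fit. Not used for the headline classification."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_inputs(x, y)
    lx, ly = np.log10(x), np.log10(y)
    a_full = np.polyfit(lx, ly, 2)[0]
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_boot):
        idx = rng.integers(0, lx.size, lx.size)
        if np.unique(lx[idx]).size < 3:
            continue
        a = np.polyfit(lx[idx], ly[idx], 2)[0]
        agree += int(np.sign(a) == np.sign(a_full))
    return agree / n_boot
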