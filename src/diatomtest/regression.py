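"""Logarithmic accuracy-vs-image-count model and image-budget solver.

Extrapolation accuracy grows roughly logarithmically with the number of
acquired fields, so accuracy is modelled as

    accuracy(n) = a * ln(n) + b

fitted by ordinary least squares.  Inverting the fitted curve gives the
minimum whole number of images needed to reach a target accuracy
(ceiling of exp((target - b) / a)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AccuracyCurve", "fit_log_curve", "predict_accuracy", "images_needed"]


@dataclass(frozen=True)
class AccuracyCurve:
    """Coefficients of accuracy = a*ln(images) + b for one strategy."""

    a: float  # slope on ln(images)
    b: float  # intercept, percent
    strategy: str = ""
    fit_points: tuple[tuple[float, float], ...] = field(default_factory=tuple)


def fit_log_curve(points, strategy: str = "") -> AccuracyCurve:
    """Fit accuracy = a*ln(n_images) + b by unweighted OLS.

    Accuracy inputs above 100 are not clamped; clamping is a reporting
    concern and would bias the fit.
    """
    pts = [(float(n), float(y)) for n, y in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 points to fit the log curve")
    if any(n < 1 for n, _ in pts):
        raise ValueError("all n_images values must be >= 1")
    lnx = np.log([n for n, _ in pts])
    if np.unique(lnx).size < 2:
        raise ValueError("need at least 2 distinct n_images values")
    y = np.array([v for _, v in pts])
    design = np.column_stack([lnx, np.ones_like(lnx)])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    return AccuracyCurve(a=float(a), b=float(b), strategy=strategy,
                         fit_points=tuple(pts))


def predict_accuracy(curve: AccuracyCurve, n_images: float) -> float:
    """Predicted accuracy (percent) at a given image count."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    return curve.a * math.log(n_images) + curve.b


def images_needed(curve: AccuracyCurve, target_pct: float = 95.0) -> int:
    """Smallest whole number of images whose predicted accuracy reaches
    ``target_pct``; 1 if the intercept already meets the target."""
    if target_pct <= curve.b:
        return 1
    if curve.a <= 0:
        raise ValueError(
            f"target {target_pct}% unreachable: curve is non-increasing (a={curve.a})"
        )
    n = math.ceil(math.exp((target_pct - curve.b) / curve.a) - 1e-9)
    n = max(1, n)
    # guard against floating-point edge effects around the ceiling
    while predict_accuracy(curve, n) < target_pct:
        n += 1
    while n > 1 and predict_accuracy(curve, n - 1) >= target_pct:
        n -= 1
    return n
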