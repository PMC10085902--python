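"""Published study values used as worked-example inputs.

These are the printed results of the validation study this package
re-implements: the per-case concentrations, the control-case
tissue-weight/count triples, the empirical accuracy ladders of the two
acquisition strategies, and the published log-regression coefficients.
They serve as fixed inputs for worked examples, fixtures and
verification -- nothing here is computed by this package.
"""

from __future__ import annotations

import pandas as pd

from .regression import AccuracyCurve

__all__ = [
    "study_cases",
    "control_cases",
    "transect_accuracy_ladder",
    "scatter_accuracy_ladder",
    "TRANSECT_CURVE",
    "SCATTER_CURVE",
]

#: published log-regression coefficients: accuracy = a*ln(images) + b
TRANSECT_CURVE = AccuracyCurve(a=6.5832, b=66.32, strategy="transect")
SCATTER_CURVE = AccuracyCurve(a=4.3587, b=77.99, strategy="scatter")

_STUDY_CASES = [
    # case_id, lung diatoms/g, medium diatoms/ml, published L/D, flags
    ("1", 3426.0, 315.0, 10.9, ""),
    ("2", 410.0, 175.0, 2.3, ""),
    ("3", 11928.0, 3336.0, 3.6, ""),
    ("4", 4521.0, 675.0, 6.7, "advanced_decomposition"),
    ("5", 2567.0, 24148.0, 0.1, "debris"),
]

_CONTROL_CASES = {
    # control case -> (tissue masses g, whole-membrane diatom counts)
    "A": ((0.5, 1.1, 1.5), (57, 108, 155)),
    "B": ((1.0, 2.0, 3.0), (207, 444, 640)),
    "C": ((0.4, 0.9, 1.4), (55, 108, 181)),
}

#: empirical mean extrapolation accuracy per image count (pooled dilutions)
_TRANSECT_LADDER = [(10, 79.8), (20, 87.1), (40, 92.2), (80, 95.6)]
_SCATTER_LADDER = [(8, 86.1), (16, 91.0), (32, 93.8), (69, 97.0)]


def study_cases() -> pd.DataFrame:
    """The five validation cases: per-gram lung and per-ml medium diatom
    concentrations with the published one-decimal L/D ratios."""
    return pd.DataFrame(
        _STUDY_CASES,
        columns=["case_id", "lung_per_gram", "medium_per_ml", "published_ld", "flags"],
    )


def control_cases() -> dict[str, tuple[tuple[float, ...], tuple[int, ...]]]:
    """Control drowning cases A-C: replicate lung aliquot masses (g) and
    their whole-membrane diatom counts."""
    return dict(_CONTROL_CASES)


def transect_accuracy_ladder() -> list[tuple[int, float]]:
    """(n_images, mean accuracy %) for quarter/half/full/double transects."""
    return list(_TRANSECT_LADDER)


def scatter_accuracy_ladder() -> list[tuple[int, float]]:
    """(n_images, mean accuracy %) for eighth/quarter/half/full scatter."""
    return list(_SCATTER_LADDER)
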