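"""Forensic L/D diagnostics: concentrations, ratio, classification,
replicability statistics, peripheral-tissue categories and digestion
reagent recommendations.

The L/D ratio is the diatom concentration per gram of lung tissue
divided by the concentration per millilitre of the putative drowning
medium.  Active aspiration concentrates diatoms in the lung, so L/D > 1
supports drowning (reported drowning probabilities of 96% for L/D > 1
and 100% for L/D > 2), while L/D <= 1 is compatible with post-mortal
immersion.  Classification always uses the unrounded ratio; one-decimal
rounding is applied only when reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .synthetic import SyntheticCase

__all__ = [
    "DiagnosticClass",
    "TissueMeasurement",
    "MediumMeasurement",
    "CaseRecord",
    "ReplicabilityReport",
    "DigestionRecommendation",
    "per_gram",
    "per_ml",
    "ld_ratio",
    "round_ld",
    "classify_ld",
    "categorize_peripheral",
    "replicability",
    "recommend_digestion",
    "analyze_case",
    "analyze_synthetic_case",
]


class DiagnosticClass(str, Enum):
    """Diagnostic class from the L/D ratio.

    strong_drowning: L/D > 2 -- lung at least twice as concentrated as
    the medium; drowning_supportive: 1 < L/D <= 2; immersion_compatible:
    L/D <= 1 -- passive infiltration can at most reach the medium's
    concentration.
    """

    STRONG_DROWNING = "strong_drowning"
    DROWNING_SUPPORTIVE = "drowning_supportive"
    IMMERSION_COMPATIBLE = "immersion_compatible"


def per_gram(count: int, mass_g: float) -> float:
    """Diatoms per gram of tissue."""
    if mass_g <= 0:
        raise ValueError("tissue mass must be > 0 g")
    if count < 0:
        raise ValueError("diatom count must be >= 0")
    return count / mass_g


def per_ml(count: int, volume_ml: float) -> float:
    """Diatoms per millilitre of medium."""
    if volume_ml <= 0:
        raise ValueError("medium volume must be > 0 ml")
    if count < 0:
        raise ValueError("diatom count must be >= 0")
    return count / volume_ml


@dataclass(frozen=True)
class TissueMeasurement:
    """One digested tissue aliquot with its whole-membrane diatom count."""

    tissue: str  # lung / liver / kidney
    mass_g: float
    diatom_count: float

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass_g must be > 0")
        if self.diatom_count < 0:
            raise ValueError("diatom_count must be >= 0")

    @property
    def per_gram(self) -> float:
        return self.diatom_count / self.mass_g


@dataclass(frozen=True)
class MediumMeasurement:
    """One drowning-medium aliquot with its diatom count."""

    volume_ml: float
    diatom_count: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")
        if self.diatom_count < 0:
            raise ValueError("diatom_count must be >= 0")

    @property
    def per_ml(self) -> float:
        return self.diatom_count / self.volume_ml


def ld_ratio(lung_per_gram: float, medium_per_ml: float) -> float:
    """L/D ratio: lung concentration (per g) over medium concentration
    (per ml).  Unrounded; use :func:`round_ld` for reporting."""
    if medium_per_ml <= 0:
        raise ValueError(
            "medium concentration must be > 0 diatoms/ml to serve as reference"
        )
    if lung_per_gram < 0:
        raise ValueError("lung concentration must be >= 0")
    return lung_per_gram / medium_per_ml


def round_ld(ld: float) -> float:
    """One-decimal reporting convention for L/D ratios."""
    return round(ld, 1)


def classify_ld(ld: float) -> DiagnosticClass:
    """Classify an (unrounded) L/D ratio; the boundary L/D = 1 falls on
    the immersion-compatible side."""
    if ld < 0:
        raise ValueError("L/D ratio must be >= 0")
    if ld > 2:
        return DiagnosticClass.STRONG_DROWNING
    if ld > 1:
        return DiagnosticClass.DROWNING_SUPPORTIVE
    return DiagnosticClass.IMMERSION_COMPATIBLE


def categorize_peripheral(count: int) -> str:
    """Qualitative peripheral-tissue category: '-' (0 diatoms),
    '+' (1-4), '++' (5-9), '+++' (>= 10)."""
    if count < 0 or int(count) != count:
        raise ValueError("peripheral count must be a non-negative integer")
    count = int(count)
    if count == 0:
        return "-"
    if count <= 4:
        return "+"
    if count <= 9:
        return "++"
    return "+++"


@dataclass(frozen=True)
class ReplicabilityReport:
    """Replicate agreement of per-gram concentrations across aliquots of
    different mass from the same tissue."""

    per_gram_values: tuple[float, ...]
    max_rel_deviation_pct: float
    spearman_r: float
    spearman_p: float
    kruskal_p: float  # NaN when no per-field count groups supplied


def replicability(
    samples: Sequence[TissueMeasurement],
    per_field_counts: Sequence[Sequence[int]] | None = None,
) -> ReplicabilityReport:
    """Replicability of diatoms-per-gram across aliquots of one tissue.

    max_rel_deviation_pct is the range of the per-gram values relative
    to their mean (100*(max-min)/mean).  Spearman's rank correlation is
    computed between aliquot mass and raw count.  When per-field count
    groups are supplied (one group of per-image counts per aliquot) a
    Kruskal-Wallis test across the groups is added.
    """
    if len(samples) < 2:
        raise ValueError("replicability needs at least 2 samples")
    tissues = {s.tissue for s in samples}
    if len(tissues) > 1:
        raise ValueError(f"samples mix tissues: {sorted(tissues)}")
    pg = np.array([s.per_gram for s in samples])
    max_rel = 100.0 * (pg.max() - pg.min()) / pg.mean() if pg.mean() > 0 else 0.0
    masses = [s.mass_g for s in samples]
    counts = [s.diatom_count for s in samples]
    rho, p = stats.spearmanr(masses, counts)
    if per_field_counts is not None:
        if len(per_field_counts) != len(samples):
            raise ValueError("one per-field count group required per sample")
        _, kp = stats.kruskal(*per_field_counts)
    else:
        kp = math.nan
    return ReplicabilityReport(
        per_gram_values=tuple(float(v) for v in pg),
        max_rel_deviation_pct=float(max_rel),
        spearman_r=float(rho),
        spearman_p=float(p),
        kruskal_p=float(kp),
    )


@dataclass(frozen=True)
class DigestionRecommendation:
    """Reagent volumes (4:1 HNO3:H2O2) recommended for a tissue mass."""

    tissue_mass_g: float
    total_volume_ml: float
    hno3_ml: float
    h2o2_ml: float
    warnings: tuple[str, ...] = ()


def recommend_digestion(
    tissue_mass_g: float, volume_ml: float | None = None
) -> DigestionRecommendation:
    """Recommend the nitric acid / hydrogen peroxide batch for a tissue mass.

    Validated rules: <= 0.5 g -> 5 ml (4 + 1); <= 1.0 g -> 10 ml (8 + 2);
    > 1.0 g -> 15 ml (12 + 3).  ``volume_ml`` overrides the recommended
    total volume (must be one of 5/10/15); oversized batches on light
    samples attach a frustule-disintegration warning, since excess
    reagent partially dissolves the silica shells.
    """
    if not 0 < tissue_mass_g <= 2.0:
        raise ValueError(
            f"tissue mass {tissue_mass_g} g outside the validated 0-2 g range; "
            "adjust the sampled tissue mass before digestion"
        )
    if tissue_mass_g <= 0.5:
        total = 5.0
    elif tissue_mass_g <= 1.0:
        total = 10.0
    else:
        total = 15.0
    if volume_ml is not None:
        if volume_ml not in (5.0, 10.0, 15.0):
            raise ValueError("total volume must be one of 5, 10 or 15 ml")
        total = float(volume_ml)
    warnings = []
    if total >= 10.0 and tissue_mass_g <= 0.5:
        warnings.append(
            f"{total:.0f} ml reagent on {tissue_mass_g} g tissue risks diatom "
            "frustule disintegration"
        )
    elif total >= 15.0 and tissue_mass_g <= 1.0:
        warnings.append(
            f"15 ml reagent on {tissue_mass_g} g tissue risks diatom "
            "frustule disintegration"
        )
    if total == 5.0 and tissue_mass_g > 0.5:
        warnings.append(
            f"5 ml reagent digests {tissue_mass_g} g tissue only partially"
        )
    if total == 10.0 and tissue_mass_g > 1.0:
        warnings.append(
            f"10 ml reagent leaves tissue residues at {tissue_mass_g} g"
        )
    return DigestionRecommendation(
        tissue_mass_g=float(tissue_mass_g),
        total_volume_ml=total,
        hno3_ml=total * 0.8,
        h2o2_ml=total * 0.2,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class CaseRecord:
    """One analysed case: concentrations, L/D ratio, diagnostic class,
    peripheral-tissue categories and caveats."""

    case_id: str
    lung_per_gram: float
    medium_per_ml: float
    ld: float
    diagnostic_class: DiagnosticClass
    peripheral: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    @property
    def ld_reported(self) -> float:
        return round_ld(self.ld)


DEBRIS_CAVEAT = (
    "drowning medium contained plenty of debris; medium concentration may "
    "overstate the diatom content of the aspirated water"
)


def analyze_case(
    case_id: str,
    lung: TissueMeasurement,
    medium: MediumMeasurement,
    peripheral_counts: Mapping[str, int] | None = None,
    flags: Sequence[str] = (),
) -> CaseRecord:
    """Compose concentrations, L/D ratio, classification and peripheral
    categories into one case record.  A ``debris`` flag attaches the
    medium-reliability caveat."""
    if lung.tissue != "lung":
        raise ValueError(f"L/D numerator must be lung tissue, got {lung.tissue!r}")
    ld = ld_ratio(lung.per_gram, medium.per_ml)
    peripheral = {
        t: categorize_peripheral(c) for t, c in (peripheral_counts or {}).items()
    }
    out_flags = list(flags)
    if "debris" in out_flags:
        out_flags.append(DEBRIS_CAVEAT)
    return CaseRecord(
        case_id=str(case_id),
        lung_per_gram=lung.per_gram,
        medium_per_ml=medium.per_ml,
        ld=ld,
        diagnostic_class=classify_ld(ld),
        peripheral=peripheral,
        flags=tuple(out_flags),
    )


def analyze_synthetic_case(case: SyntheticCase, case_id: str = "synthetic") -> CaseRecord:
    """Analyse a simulated case by pooling its aliquots (total count over
    total mass/volume), the same estimator applied to replicate digests."""
    mass = sum(m for m, _ in case.tissue_samples)
    t_count = sum(c for _, c in case.tissue_samples)
    vol = sum(v for v, _ in case.medium_samples)
    m_count = sum(c for _, c in case.medium_samples)
    lung = TissueMeasurement(tissue="lung", mass_g=mass, diatom_count=t_count)
    medium = MediumMeasurement(volume_ml=vol, diatom_count=m_count)
    return analyze_case(case_id, lung, medium)
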