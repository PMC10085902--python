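"""Synthetic diatom deposition patterns and synthetic forensic cases.

Real membranes are not published, so every downstream stage is exercised
on simulated data.  Two point processes model diatom deposition on the
membrane disc:

* ``homogeneous`` -- complete spatial randomness (uniform Poisson), the
  null model of even deposition;
* ``clustered`` -- a Neyman-Scott process (Poisson parents uniform on
  the disc, Poisson-distributed offspring displaced by an isotropic
  Gaussian), emulating the clusters and layers in which diatoms settle
  on real filters.

Synthetic forensic cases draw Poisson counts for tissue aliquots of
known mass and medium aliquots of known volume around a controllable
true L/D ratio.

All randomness flows through one ``numpy.random.Generator`` seeded per
call; identical (parameters, seed) give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import MembraneSpec

__all__ = ["PointPattern", "SyntheticCase", "simulate_membrane", "simulate_case"]


@dataclass(frozen=True)
class PointPattern:
    """Diatom coordinates on the membrane disc plus bookkeeping.

    Coordinates are an (N, 2) float array of (x_mm, y_mm) relative to the
    membrane centre; every point lies within ``spec.radius_mm`` of the
    origin and ``true_total`` equals the number of points.
    """

    spec: MembraneSpec
    coordinates: np.ndarray
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "coordinates", coords)
        if coords.size:
            r = np.hypot(coords[:, 0], coords[:, 1])
            if np.any(r > self.spec.radius_mm * (1 + 1e-12)):
                raise ValueError("point pattern contains points outside the membrane disc")

    @property
    def true_total(self) -> int:
        return int(self.coordinates.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coordinates, columns=["x_mm", "y_mm"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: MembraneSpec) -> "PointPattern":
        df = pd.read_csv(path)
        return cls(spec=spec, coordinates=df[["x_mm", "y_mm"]].to_numpy())


@dataclass(frozen=True)
class SyntheticCase:
    """A simulated forensic case: known concentrations, Poisson counts.

    ``tissue_samples`` holds (mass_g, observed_count) pairs and
    ``medium_samples`` (volume_ml, observed_count) pairs, mirroring the
    tissue-weight/count structure of replicate digestions.
    """

    true_lung_conc: float  # diatoms per g
    true_medium_conc: float  # diatoms per ml
    tissue_samples: tuple[tuple[float, int], ...]
    medium_samples: tuple[tuple[float, int], ...]

    @property
    def true_ld(self) -> float:
        if self.true_medium_conc <= 0:
            return math.nan
        return self.true_lung_conc / self.true_medium_conc

    def to_frame(self) -> pd.DataFrame:
        rows = [("tissue", m, c) for m, c in self.tissue_samples]
        rows += [("medium", v, c) for v, c in self.medium_samples]
        return pd.DataFrame(rows, columns=["sample_kind", "size", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * math.pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_membrane(
    spec: MembraneSpec,
    process: str = "homogeneous",
    intensity: float = 10.0,
    cluster_rate: float = 0.5,
    cluster_size_mean: float = 20.0,
    cluster_sd_mm: float = 0.3,
    seed: int | None = None,
) -> PointPattern:
    """Simulate diatom deposition on the membrane disc.

    Parameters
    ----------
    process
        ``"homogeneous"`` (uniform Poisson at ``intensity`` points/mm^2)
        or ``"clustered"`` (Neyman-Scott: parents at ``cluster_rate``
        clusters/mm^2, Poisson(``cluster_size_mean``) offspring per
        parent displaced by an isotropic Gaussian of sd ``cluster_sd_mm``;
        offspring landing outside the disc are discarded).  For the
        clustered process the realised mean intensity is
        ``cluster_rate * cluster_size_mean`` (minus edge loss) and the
        ``intensity`` argument is not used.
    seed
        Seed for the per-call ``numpy.random.default_rng``; no global
        random state is touched.
    """
    if process not in ("homogeneous", "clustered"):
        raise ValueError(f"unknown process {process!r}")
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    rng = np.random.default_rng(seed)
    radius = spec.radius_mm

    if process == "homogeneous":
        n = rng.poisson(intensity * spec.area_mm2)
        coords = _uniform_disc(rng, n, radius)
    else:
        if cluster_rate <= 0 or cluster_size_mean <= 0 or cluster_sd_mm <= 0:
            raise ValueError(
                "clustered process requires cluster_rate, cluster_size_mean "
                "and cluster_sd_mm all > 0"
            )
        n_parents = rng.poisson(cluster_rate * spec.area_mm2)
        parents = _uniform_disc(rng, n_parents, radius)
        sizes = rng.poisson(cluster_size_mean, n_parents)
        total = int(sizes.sum())
        if total:
            offsets = rng.normal(0.0, cluster_sd_mm, size=(total, 2))
            coords = np.repeat(parents, sizes, axis=0) + offsets
            keep = np.hypot(coords[:, 0], coords[:, 1]) <= radius
            coords = coords[keep]
        else:
            coords = np.empty((0, 2))

    params = {
        "process": process,
        "intensity": intensity,
        "cluster_rate": cluster_rate,
        "cluster_size_mean": cluster_size_mean,
        "cluster_sd_mm": cluster_sd_mm,
        "seed": seed,
    }
    return PointPattern(spec=spec, coordinates=coords, generator_params=params)


def simulate_case(
    true_lung_conc: float,
    true_medium_conc: float,
    tissue_masses: Sequence[float],
    medium_volumes: Sequence[float],
    seed: int | None = None,
) -> SyntheticCase:
    """Simulate a forensic case with Poisson counting noise.

    Each tissue aliquot of mass m grams yields a count drawn
    Poisson(m * true_lung_conc); each medium aliquot of volume v ml a
    count drawn Poisson(v * true_medium_conc).
    """
    if true_lung_conc < 0 or true_medium_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if len(tissue_masses) == 0 or len(medium_volumes) == 0:
        raise ValueError("tissue_masses and medium_volumes must be non-empty")
    if any(m <= 0 for m in tissue_masses) or any(v <= 0 for v in medium_volumes):
        raise ValueError("all masses and volumes must be > 0")
    rng = np.random.default_rng(seed)
    tissue = tuple(
        (float(m), int(rng.poisson(m * true_lung_conc))) for m in tissue_masses
    )
    medium = tuple(
        (float(v), int(rng.poisson(v * true_medium_conc))) for v in medium_volumes
    )
    return SyntheticCase(
        true_lung_conc=float(true_lung_conc),
        true_medium_conc=float(true_medium_conc),
        tissue_samples=tissue,
        medium_samples=medium,
    )
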