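"""Field-of-view acquisition geometry on a circular filter membrane.

A digested sample is filtered onto a circular PVDF membrane (default
diameter 10 mm) which is then imaged in square SEM fields of view at
1000x magnification.  A full transect of 40 contiguous fields across one
diameter fixes the field width at 0.25 mm.  Two families of acquisition
plans are provided:

* **transect** -- contiguous fields along a diameter (quarter / half /
  full / double, i.e. 10 / 20 / 40 / 80 images); the double transect is
  two orthogonal full transects.
* **scatter** -- near-equidistant fields spread over the whole disc
  (eighth / quarter / half / full, i.e. 8 / 16 / 32 / 69 images), laid
  out on a deterministic sunflower (Vogel spiral) lattice.

Coordinates are continuous millimetres with the origin at the membrane
centre.  Plans are pure functions of (spec, strategy, level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad

__all__ = [
    "MembraneSpec",
    "FieldOfView",
    "AcquisitionPlan",
    "TRANSECT_LEVELS",
    "SCATTER_LEVELS",
    "make_transect_plan",
    "make_scatter_plan",
    "make_grid_plan",
    "sunflower_plan",
    "clipped_area",
]

#: image counts per level, as published for the 10 mm / 40-field membrane
TRANSECT_LEVELS: dict[str, int] = {"quarter": 10, "half": 20, "full": 40, "double": 80}
SCATTER_LEVELS: dict[str, int] = {"eighth": 8, "quarter": 16, "half": 32, "full": 69}

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class MembraneSpec:
    """Geometry of the filter membrane and its SEM field tiling.

    Parameters
    ----------
    diameter_mm
        Membrane diameter; the published protocol uses 10 mm.
    fields_per_diameter
        Number of contiguous fields spanning one diameter in a full
        transect (40 in the published protocol); this fixes the field
        width at ``diameter_mm / fields_per_diameter``.
    """

    diameter_mm: float = 10.0
    fields_per_diameter: int = 40

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be positive, got {self.diameter_mm}")
        if self.fields_per_diameter < 2:
            raise ValueError(
                f"fields_per_diameter must be >= 2, got {self.fields_per_diameter}"
            )

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def field_width_mm(self) -> float:
        return self.diameter_mm / self.fields_per_diameter

    @property
    def area_mm2(self) -> float:
        """Total membrane area (pi * r^2)."""
        return math.pi * self.radius_mm**2


@dataclass(frozen=True)
class FieldOfView:
    """One square SEM field of view.

    ``clipped_area_mm2`` is the area of the square's intersection with
    the membrane disc; fields at the rim extend past the membrane edge
    and contribute only their clipped area to extrapolation.
    """

    index: int
    center: tuple[float, float]
    width_mm: float
    clipped_area_mm2: float

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership: [lo, hi) on both axes.

        Half-open on the max edges so a point on a boundary shared by
        two contiguous transect fields is counted exactly once.
        """
        h = self.width_mm / 2.0
        cx, cy = self.center
        return (cx - h <= x < cx + h) and (cy - h <= y < cy + h)


@dataclass(frozen=True)
class AcquisitionPlan:
    """An ordered set of fields of view with strategy/level metadata."""

    strategy: str
    level: str
    spec: MembraneSpec
    fields: tuple[FieldOfView, ...]

    @property
    def n_images(self) -> int:
        return len(self.fields)

    @property
    def sampled_area_mm2(self) -> float:
        return sum(f.clipped_area_mm2 for f in self.fields)

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.fields], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [f.index for f in self.fields],
                "x_mm": [f.center[0] for f in self.fields],
                "y_mm": [f.center[1] for f in self.fields],
                "width_mm": [f.width_mm for f in self.fields],
                "clipped_area_mm2": [f.clipped_area_mm2 for f in self.fields],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _disc_rect_area(r: float, x1: float, x2: float, y1: float, y2: float) -> float:
    """Area of the intersection of the disc x^2 + y^2 <= r^2 with
    the axis-aligned rectangle [x1, x2] x [y1, y2].

    Fast analytic paths for fully-interior and disjoint rectangles;
    otherwise adaptive quadrature of the chord-height function with
    breakpoints at the arc/edge crossings (relative error << 1e-6).
    """
    if x1 >= x2 or y1 >= y2:
        return 0.0
    # farthest rectangle corner from the origin
    fx = max(abs(x1), abs(x2))
    fy = max(abs(y1), abs(y2))
    if fx * fx + fy * fy <= r * r:
        return (x2 - x1) * (y2 - y1)
    # nearest point of the rectangle to the origin
    nx = x1 if x1 > 0 else (x2 if x2 < 0 else 0.0)
    ny = y1 if y1 > 0 else (y2 if y2 < 0 else 0.0)
    if nx * nx + ny * ny >= r * r:
        return 0.0

    xa, xb = max(x1, -r), min(x2, r)
    if xa >= xb:
        return 0.0

    def chord(x: float) -> float:
        yc = math.sqrt(max(0.0, r * r - x * x))
        return max(0.0, min(y2, yc) - max(y1, -yc))

    pts = []
    for yy in (y1, y2):
        if abs(yy) < r:
            xc = math.sqrt(r * r - yy * yy)
            for cand in (-xc, xc):
                if xa < cand < xb:
                    pts.append(cand)
    val, _ = quad(chord, xa, xb, points=sorted(pts) or None, limit=200,
                  epsabs=1e-12, epsrel=1e-10)
    return val


def clipped_area(center: tuple[float, float], width_mm: float,
                 spec: MembraneSpec) -> float:
    """Area (mm^2) of a square field's intersection with the membrane disc."""
    cx, cy = center
    h = width_mm / 2.0
    return _disc_rect_area(spec.radius_mm, cx - h, cx + h, cy - h, cy + h)


def _make_field(index: int, center: tuple[float, float], spec: MembraneSpec) -> FieldOfView:
    w = spec.field_width_mm
    return FieldOfView(index=index, center=center, width_mm=w,
                       clipped_area_mm2=clipped_area(center, w, spec))


def _diameter_centers(spec: MembraneSpec) -> np.ndarray:
    """1-D centers of the n contiguous fields spanning one diameter."""
    n = spec.fields_per_diameter
    w = spec.field_width_mm
    return -spec.radius_mm + (np.arange(n) + 0.5) * w


def make_transect_plan(spec: MembraneSpec, level: str) -> AcquisitionPlan:
    """Build a transectial acquisition plan along the membrane diameter.

    ``full`` covers one diameter contiguously (40 fields by default);
    ``half`` and ``quarter`` are the central 20 and 10 fields of that
    diameter; ``double`` adds the full transect of the perpendicular
    diameter (80 fields -- the two central fields of each arm overlap
    geometrically near the origin but both acquisitions are kept, as in
    the published image counts).
    """
    if level not in TRANSECT_LEVELS:
        raise ValueError(
            f"invalid transect level {level!r}; expected one of {sorted(TRANSECT_LEVELS)}"
        )
    n = spec.fields_per_diameter
    if n % 4 != 0:
        raise ValueError("fields_per_diameter must be divisible by 4 for transect levels")
    xs = _diameter_centers(spec)
    if level == "quarter":
        sel = xs[3 * n // 8: 5 * n // 8]
        centers = [(x, 0.0) for x in sel]
    elif level == "half":
        sel = xs[n // 4: 3 * n // 4]
        centers = [(x, 0.0) for x in sel]
    elif level == "full":
        centers = [(x, 0.0) for x in xs]
    else:  # double: two orthogonal full transects
        centers = [(x, 0.0) for x in xs] + [(0.0, y) for y in xs]
    fields = tuple(_make_field(i, c, spec) for i, c in enumerate(centers))
    return AcquisitionPlan(strategy="transect", level=level, spec=spec, fields=fields)


def sunflower_plan(spec: MembraneSpec, n_images: int,
                   level: str = "custom") -> AcquisitionPlan:
    """Deterministic sunflower (Vogel spiral) scatter layout of ``n_images``
    fields, scaled so field centres stay at least one field width inside
    the membrane rim."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    r_max = spec.radius_mm - spec.field_width_mm
    if r_max <= 0:
        raise ValueError("field width too large for scatter layout on this membrane")
    k = np.arange(n_images)
    rad = r_max * np.sqrt((k + 0.5) / n_images)
    theta = k * GOLDEN_ANGLE
    centers = [(float(r * math.cos(t)), float(r * math.sin(t)))
               for r, t in zip(rad, theta)]
    fields = tuple(_make_field(i, c, spec) for i, c in enumerate(centers))
    return AcquisitionPlan(strategy="scatter", level=level, spec=spec, fields=fields)


def make_scatter_plan(spec: MembraneSpec, level: str) -> AcquisitionPlan:
    """Build a scatter acquisition plan at a published level
    (eighth/quarter/half/full = 8/16/32/69 images)."""
    if level not in SCATTER_LEVELS:
        raise ValueError(
            f"invalid scatter level {level!r}; expected one of {sorted(SCATTER_LEVELS)}"
        )
    return sunflower_plan(spec, SCATTER_LEVELS[level], level=level)


def make_grid_plan(spec: MembraneSpec) -> AcquisitionPlan:
    """Full-coverage plan: every field of the square tiling whose square
    intersects the disc.  Used as the exhaustive reference; its clipped
    areas sum to the membrane area."""
    xs = _diameter_centers(spec)
    fields = []
    idx = 0
    for y in xs:
        for x in xs:
            f = _make_field(idx, (float(x), float(y)), spec)
            if f.clipped_area_mm2 > 0.0:
                fields.append(FieldOfView(idx, f.center, f.width_mm, f.clipped_area_mm2))
                idx += 1
    # reindex contiguously
    fields = [FieldOfView(i, f.center, f.width_mm, f.clipped_area_mm2)
              for i, f in enumerate(fields)]
    return AcquisitionPlan(strategy="grid", level="coverage", spec=spec,
                           fields=tuple(fields))
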