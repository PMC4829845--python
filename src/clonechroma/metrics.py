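"""The four clonal-color metrics.

A clone — the set of cells descended from one founder — occupies a region of
chromaticity space.  Four quantities summarise how useful its color is as a
clonal identifier:

* **chromatic mode** — the grid element with the highest adjusted cell count
  (n_max); the clone's color center.
* **chromatic spread** — the connected region around the mode enclosed by an
  isosurface drawn at a stated fraction f of n_max (default fractions 50%,
  25%, 10%, 5%, 2%, 1%); the clone's color footprint at that density level.
* **relative clonal brightness** — the fraction of the clone's cells whose
  total fluorescence exceeds b* multiples of an autofluorescence reference
  unit (1 xAF); quantifies how little autofluorescence contaminates the
  color code.  Ideal value 1.
* **chromatic stability** — the extra spread area accumulated per additional
  timepoint, relative to the smallest single-timepoint spread; quantifies
  color drift over the course of an experiment.  Ideal value 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .colorspace import (
    ChromaticityGrid,
    ColorEvents,
    bin_events,
    solid_angle_column,
)

__all__ = [
    "DEFAULT_FRACTIONS",
    "ModeResult",
    "SpreadContour",
    "CloneColorProfile",
    "AFReference",
    "StabilityReport",
    "chromatic_mode",
    "chromatic_spread",
    "clone_profile",
    "xaf_unit",
    "cell_xaf",
    "relative_clonal_brightness",
    "chromatic_stability",
]

DEFAULT_FRACTIONS = (0.50, 0.25, 0.10, 0.05, 0.02, 0.01)

_DEG2_PER_SR = (180.0 / np.pi) ** 2


@dataclass(frozen=True)
class ModeResult:
    """Arg-max element of a grid's adjusted counts."""

    element: tuple[int, int]  # (i_theta, j_phi)
    n_max: float
    theta: float  # element-center coordinates, degrees
    phi: float
    tied: bool = False


def chromatic_mode(grid: ChromaticityGrid, tie_break: str = "lexicographic") -> ModeResult:
    """Locate the chromatic mode: the element with the highest adjusted count.

    Ties are resolved deterministically: ``lexicographic`` (default) returns
    the tied element with the smallest (theta index, phi index);
    ``centroid`` returns the element nearest the centroid of the tied set.
    The result is flagged ``tied`` either way.
    """
    if not np.any(grid.counts > 0):
        raise ValueError("grid has no nonzero elements; cannot locate a mode")
    n_max = float(grid.counts.max())
    tied_idx = np.argwhere(grid.counts == n_max)
    tied = len(tied_idx) > 1
    if tie_break == "centroid" and tied:
        center = tied_idx.mean(axis=0)
        d2 = ((tied_idx - center) ** 2).sum(axis=1)
        i, j = tied_idx[int(np.argmin(d2))]
    elif tie_break in ("lexicographic", "centroid"):
        i, j = tied_idx[0]  # argwhere is already in lexicographic order
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return ModeResult(
        element=(int(i), int(j)),
        n_max=n_max,
        theta=float(grid.theta_centers[i]),
        phi=float(grid.phi_centers[j]),
        tied=bool(tied),
    )


@dataclass
class SpreadContour:
    """Chromatic spread at one isosurface fraction.

    ``mask`` is the boolean grid of elements in the mode-containing
    4-connected component of {adjusted count ≥ fraction·n_max}.  Areas are
    reported both as solid angle (``area_sr``, also in deg² of solid angle)
    and as planar (theta, phi) area (``area_planar_deg2`` = n elements ×
    resolution²).  ``enclosed_fraction`` is the fraction of the clone's
    defined-chromaticity cells whose coordinates fall inside the contour.
    ``has_islands`` flags super-threshold elements outside the mode's
    component (excluded from the spread).
    """

    fraction: float
    mask: np.ndarray
    area_sr: float
    area_deg2: float
    area_planar_deg2: float
    enclosed_fraction: float | None = None
    has_islands: bool = False
    resolution_deg: float = 0.2

    @property
    def n_elements(self) -> int:
        return int(self.mask.sum())

    def elements(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in np.argwhere(self.mask)}

    def overlaps(self, other: "SpreadContour") -> bool:
        return bool(np.any(self.mask & other.mask))


_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def chromatic_spread(
    grid: ChromaticityGrid,
    mode: ModeResult,
    fraction: float,
    events: ColorEvents | None = None,
) -> SpreadContour:
    """Chromatic spread: the mode's connected component above fraction·n_max.

    The isosurface at level f·n_max is projected onto the grid as the set of
    elements whose adjusted count reaches the level; the spread keeps only
    the 4-connected component containing the mode, so a spread is always one
    region around the clone's color center.  If ``events`` is given, the
    fraction of cells whose chromaticity lies inside the contour is computed
    from the raw coordinates.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    level = fraction * mode.n_max
    above = grid.counts >= level
    labels, _ = ndimage.label(above, structure=_FOUR_CONNECTED)
    mode_label = labels[mode.element]
    if mode_label == 0:  # numerically possible only if mode count < level
        raise ValueError("mode element falls below its own isosurface level")
    mask = labels == mode_label
    has_islands = bool(np.any(above & ~mask))
    omega = solid_angle_column(grid.resolution_deg)
    area_sr = float((mask * omega[np.newaxis, :]).sum())
    enclosed = None
    if events is not None:
        ok = events.defined
        if ok.sum():
            i, j = grid.element_of(events.theta[ok], events.phi[ok])
            enclosed = float(mask[i, j].mean())
        else:
            enclosed = 0.0
    return SpreadContour(
        fraction=float(fraction),
        mask=mask,
        area_sr=area_sr,
        area_deg2=area_sr * _DEG2_PER_SR,
        area_planar_deg2=float(mask.sum()) * grid.resolution_deg**2,
        enclosed_fraction=enclosed,
        has_islands=has_islands,
        resolution_deg=grid.resolution_deg,
    )


@dataclass
class CloneColorProfile:
    """A clone's color characterisation: histogram, mode, spreads, brightness."""

    clone_id: str
    events: ColorEvents
    grid: ChromaticityGrid
    mode: ModeResult
    spreads: dict[float, SpreadContour] = field(default_factory=dict)
    relative_brightness: float | None = None
    timepoint: float | str | None = None

    @property
    def n_max(self) -> float:
        return self.mode.n_max

    def spread(self, fraction: float) -> SpreadContour:
        try:
            return self.spreads[fraction]
        except KeyError:
            c = chromatic_spread(self.grid, self.mode, fraction, self.events)
            self.spreads[fraction] = c
            return c

    def summary(self) -> dict:
        return {
            "clone_id": self.clone_id,
            "n_events": self.events.n,
            "mode_theta": self.mode.theta,
            "mode_phi": self.mode.phi,
            "n_max": self.mode.n_max,
            "mode_tied": self.mode.tied,
            "relative_brightness": self.relative_brightness,
            "timepoint": self.timepoint,
            "spreads": {
                f: {
                    "area_sr": c.area_sr,
                    "area_deg2": c.area_deg2,
                    "enclosed_fraction": c.enclosed_fraction,
                    "has_islands": c.has_islands,
                }
                for f, c in sorted(self.spreads.items(), reverse=True)
            },
        }


def clone_profile(
    clone_id: str,
    events: ColorEvents,
    resolution_deg: float = 0.2,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    ref: "AFReference | None" = None,
    b_star: float = 20.0,
    timepoint=None,
    tie_break: str = "lexicographic",
) -> CloneColorProfile:
    """Characterise one clone: grid, mode, spreads and (optionally) brightness."""
    grid = bin_events(events, resolution_deg)
    mode = chromatic_mode(grid, tie_break=tie_break)
    profile = CloneColorProfile(
        clone_id=clone_id,
        events=events,
        grid=grid,
        mode=mode,
        timepoint=timepoint,
    )
    for f in fractions:
        profile.spreads[f] = chromatic_spread(grid, mode, f, events)
    if ref is not None:
        profile.relative_brightness = relative_clonal_brightness(events, ref, b_star)
    return profile


# ---------------------------------------------------------------------------
# Autofluorescence reference and brightness
# ---------------------------------------------------------------------------


@dataclass
class AFReference:
    """Autofluorescence reference defining the 1 xAF brightness unit.

    Autofluorescence behaves like a clonal color, with its own chromatic
    mode and spread.  The unit value ``v_af`` is a high quantile (default
    99th percentile) of the value distribution of untransduced cells whose
    chromaticity lies inside the AF population's 2% isosurface spread, so
    that for a cell at b = value/v_af multiples of 1 xAF, autofluorescence
    is expected to contribute < 1/b of total fluorescence.
    """

    grid: ChromaticityGrid
    mode: ModeResult
    spread_2pct: SpreadContour
    v_af: float
    quantile: float = 0.99
    n_inside: int = 0


def xaf_unit(
    af_events: ColorEvents,
    resolution_deg: float = 0.2,
    quantile: float = 0.99,
    min_inside: int = 50,
) -> AFReference:
    """Define 1 xAF from an untransduced (autofluorescence-only) population."""
    if af_events.n == 0:
        raise ValueError("empty autofluorescence input")
    grid = bin_events(af_events, resolution_deg)
    mode = chromatic_mode(grid)
    spread = chromatic_spread(grid, mode, 0.02, af_events)
    ok = af_events.defined
    i, j = grid.element_of(af_events.theta[ok], af_events.phi[ok])
    inside = spread.mask[i, j]
    n_inside = int(inside.sum())
    if n_inside < min_inside:
        raise ValueError(
            f"only {n_inside} AF events inside the 2% spread "
            f"(need ≥ {min_inside}); AF reference unreliable"
        )
    v_af = float(np.quantile(af_events.value[ok][inside], quantile))
    if v_af <= 0:
        raise ValueError("AF value quantile is non-positive")
    return AFReference(
        grid=grid,
        mode=mode,
        spread_2pct=spread,
        v_af=v_af,
        quantile=quantile,
        n_inside=n_inside,
    )


def cell_xaf(value, ref: AFReference):
    """Per-cell relative brightness b = value / v_af (multiples of 1 xAF).

    Accepts a scalar value, an array of values, or a :class:`ColorEvents`.
    For a cell at b xAF the autofluorescence contribution to total
    fluorescence is expected to be below 1/b.
    """
    if isinstance(value, ColorEvents):
        value = value.value
    return np.asarray(value, dtype=float) / ref.v_af


def relative_clonal_brightness(
    events: ColorEvents, ref: AFReference, b_star: float = 20.0
) -> float:
    """Fraction of a clone's cells at or above b* multiples of 1 xAF."""
    if b_star <= 0:
        raise ValueError("b_star must be positive")
    if events.n == 0:
        raise ValueError("empty clone")
    b = cell_xaf(events, ref)
    return float((b >= b_star).mean())


# ---------------------------------------------------------------------------
# Chromatic stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Per-clone chromatic stability across timepoints.

    stability = (area(union of timepoint contours) − min_t area_t)
                / (min_t area_t · (T − 1))

    Zero when all timepoint contours coincide; unitless and normalised by
    the smallest single-timepoint spread so clones of different footprint
    sizes are comparable.
    """

    clone_id: str
    fraction: float
    timepoints: list
    areas_sr: list[float]
    union_area_sr: float
    stability: float


def chromatic_stability(
    profiles: Sequence[CloneColorProfile], fraction: float = 0.02
) -> StabilityReport:
    """Chromatic stability from ≥2 per-timepoint profiles of one clone.

    Each profile's spread contour at ``fraction`` is taken on its own grid;
    the union of contour element sets measures the total chromaticity area
    the clone visited.  All profiles must share one grid resolution.
    """
    if len(profiles) < 2:
        raise ValueError("chromatic stability requires at least two timepoints")
    res = profiles[0].grid.resolution_deg
    if any(p.grid.resolution_deg != res for p in profiles):
        raise ValueError("all timepoint profiles must share one grid resolution")
    ids = {p.clone_id for p in profiles}
    if len(ids) > 1:
        raise ValueError(f"profiles mix clones: {sorted(ids)}")
    contours = [p.spread(fraction) for p in profiles]
    omega = solid_angle_column(res)
    areas = [c.area_sr for c in contours]
    union_mask = np.zeros_like(contours[0].mask)
    for c in contours:
        union_mask |= c.mask
    union_area = float((union_mask * omega[np.newaxis, :]).sum())
    a_min = min(areas)
    t = len(profiles)
    stability = (union_area - a_min) / (a_min * (t - 1))
    return StabilityReport(
        clone_id=profiles[0].clone_id,
        fraction=float(fraction),
        timepoints=[p.timepoint for p in profiles],
        areas_sr=areas,
        union_area_sr=union_area,
        stability=float(stability),
    )
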