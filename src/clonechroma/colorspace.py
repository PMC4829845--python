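"""Spherical chromaticity color space for RGB-marked cells.

A cell's fluorescence is a point (R, G, B) in the first octant of 3-D
intensity space.  Converting to spherical coordinates separates *what color*
the cell is from *how bright* it is:

* ``value``  — the Euclidean norm sqrt(R²+G²+B²), total fluorescence;
* ``theta``  — azimuth, measured in the R–G plane from the R axis toward G;
* ``phi``    — elevation, measured from the R–G plane toward the B axis.

Both angles are reported in degrees and live in [0°, 90°] for non-negative
intensities, so chromaticity is a point on the surface of the first octant
of the unit sphere.  Cells with the same R:G:B ratio share one chromaticity
coordinate regardless of brightness.  Pure-R, pure-G and pure-B cells sit at
the corners (0°, 0°), (90°, 0°) and the phi = 90° pole respectively.

Chromaticity distributions are summarised on a fixed-resolution (theta, phi)
lattice, the :class:`ChromaticityGrid`.  Because equal (theta, phi) cells do
not subtend equal solid angles on the sphere, raw per-element event counts
are converted to *adjusted counts* — surface-density estimates normalised by
each element's solid angle and rescaled by the mean element solid angle —
so a population that is uniform per unit sphere area shows a flat histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CellColor",
    "ColorEvents",
    "ChromaticityGrid",
    "rgb_to_spherical",
    "spherical_to_rgb",
    "bin_events",
    "OCTANT_SOLID_ANGLE_SR",
    "SCALE_MAX_CYTOMETER",
    "SCALE_MAX_MICROSCOPE",
]

#: Solid angle of one octant of the unit sphere (4π/8), steradian.
OCTANT_SOLID_ANGLE_SR = np.pi / 2.0

#: Detector ceilings: 16-bit microscope scale and the cytometer intensity scale.
SCALE_MAX_MICROSCOPE = 65535.0
SCALE_MAX_CYTOMETER = 1.0e5

NEGATIVE_POLICIES = ("clamp", "drop", "error")


@dataclass(frozen=True)
class CellColor:
    """A single event's RGB intensities with derived spherical coordinates.

    ``defined`` is False when value == 0, in which case chromaticity is
    undefined and ``theta``/``phi`` are NaN.  Such events are never silently
    dropped downstream; they are counted and flagged.
    """

    r: float
    g: float
    b: float
    value: float
    theta: float
    phi: float
    defined: bool = True


def rgb_to_spherical(r, g, b):
    """Convert RGB intensities to (theta, phi, value) in degrees.

    Accepts scalars or arrays (broadcast elementwise).  ``theta`` is the
    azimuth from the R axis toward G; ``phi`` the elevation toward B.  For
    a zero vector both angles are NaN.  At the pure-blue pole (phi = 90°)
    theta is degenerate and reported as 0 by convention.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(g)) and np.all(np.isfinite(b))):
        bad = np.flatnonzero(~(np.isfinite(r) & np.isfinite(g) & np.isfinite(b)))
        raise ValueError(f"non-finite intensities at event indices {bad[:10].tolist()}")
    rg = np.hypot(r, g)
    value = np.hypot(rg, b)
    with np.errstate(invalid="ignore"):
        theta = np.degrees(np.arctan2(g, r))
        phi = np.degrees(np.arctan2(b, rg))
    zero = value == 0
    theta = np.where(zero, np.nan, theta)
    phi = np.where(zero, np.nan, phi)
    # pure-blue pole: azimuth undefined, fix the convention value 0
    pole = (~zero) & (rg == 0)
    theta = np.where(pole, 0.0, theta)
    if np.ndim(value) == 0:
        return float(theta), float(phi), float(value)
    return theta, phi, value


def spherical_to_rgb(theta, phi, value):
    """Inverse of :func:`rgb_to_spherical` (degrees in, intensities out)."""
    theta = np.radians(np.asarray(theta, dtype=float))
    phi = np.radians(np.asarray(phi, dtype=float))
    value = np.asarray(value, dtype=float)
    r = value * np.cos(phi) * np.cos(theta)
    g = value * np.cos(phi) * np.sin(theta)
    b = value * np.sin(phi)
    if np.ndim(value) == 0:
        return float(r), float(g), float(b)
    return r, g, b


@dataclass
class ColorEvents:
    """A vectorised collection of cell-color events.

    The canonical in-memory container for per-cell fluorescence: parallel
    arrays of raw intensities plus the derived spherical coordinates.
    ``theta``/``phi`` are NaN where ``value`` is 0 (undefined chromaticity).
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    value: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    saturated: np.ndarray
    scale_max: float = SCALE_MAX_CYTOMETER
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_rgb(
        cls,
        r,
        g,
        b,
        *,
        scale_max: float = SCALE_MAX_CYTOMETER,
        negative_policy: str = "clamp",
        meta: Mapping | None = None,
    ) -> "ColorEvents":
        """Build events from raw intensity arrays.

        Baseline-subtracted cytometer exports can contain negative
        intensities; ``negative_policy`` is one of ``clamp`` (set to 0,
        default — preserves event counts for composition analysis),
        ``drop`` (remove the event) or ``error``.
        """
        r = np.atleast_1d(np.asarray(r, dtype=float)).copy()
        g = np.atleast_1d(np.asarray(g, dtype=float)).copy()
        b = np.atleast_1d(np.asarray(b, dtype=float)).copy()
        if not (r.shape == g.shape == b.shape):
            raise ValueError("r, g, b must have identical shapes")
        if negative_policy not in NEGATIVE_POLICIES:
            raise ValueError(f"negative_policy must be one of {NEGATIVE_POLICIES}")
        neg = (r < 0) | (g < 0) | (b < 0)
        n_negative = int(neg.sum())
        if n_negative:
            if negative_policy == "error":
                raise ValueError(
                    f"{n_negative} events with negative intensities "
                    f"(first at index {int(np.flatnonzero(neg)[0])})"
                )
            if negative_policy == "drop":
                keep = ~neg
                r, g, b = r[keep], g[keep], b[keep]
            else:  # clamp
                r = np.maximum(r, 0.0)
                g = np.maximum(g, 0.0)
                b = np.maximum(b, 0.0)
        saturated = (r >= scale_max) | (g >= scale_max) | (b >= scale_max)
        theta, phi, value = rgb_to_spherical(r, g, b)
        theta = np.atleast_1d(theta)
        phi = np.atleast_1d(phi)
        value = np.atleast_1d(value)
        md = dict(meta or {})
        md.setdefault("n_negative", n_negative)
        md.setdefault("negative_policy", negative_policy)
        return cls(r, g, b, value, theta, phi, saturated, float(scale_max), md)

    @classmethod
    def from_spherical(cls, theta, phi, value, **kwargs) -> "ColorEvents":
        r, g, b = spherical_to_rgb(theta, phi, value)
        return cls.from_rgb(r, g, b, **kwargs)

    def __len__(self) -> int:
        return self.r.size

    @property
    def n(self) -> int:
        return self.r.size

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask: events with value > 0 (chromaticity defined)."""
        return self.value > 0

    @property
    def n_zero_value(self) -> int:
        return int((~self.defined).sum())

    @property
    def saturation_fraction(self) -> float:
        return float(self.saturated.mean()) if self.n else 0.0

    def subset(self, index) -> "ColorEvents":
        return ColorEvents(
            self.r[index],
            self.g[index],
            self.b[index],
            self.value[index],
            self.theta[index],
            self.phi[index],
            self.saturated[index],
            self.scale_max,
            dict(self.meta),
        )

    def cellcolors(self) -> list[CellColor]:
        """Materialise scalar :class:`CellColor` records (small inputs only)."""
        out = []
        for i in range(self.n):
            d = bool(self.value[i] > 0)
            out.append(
                CellColor(
                    float(self.r[i]),
                    float(self.g[i]),
                    float(self.b[i]),
                    float(self.value[i]),
                    float(self.theta[i]) if d else float("nan"),
                    float(self.phi[i]) if d else float("nan"),
                    defined=d,
                )
            )
        return out

    @staticmethod
    def concatenate(parts: Iterable["ColorEvents"]) -> "ColorEvents":
        parts = list(parts)
        if not parts:
            raise ValueError("no event collections to concatenate")
        scale = parts[0].scale_max
        if any(p.scale_max != scale for p in parts):
            raise ValueError("cannot concatenate events with different scale_max")
        return ColorEvents(
            np.concatenate([p.r for p in parts]),
            np.concatenate([p.g for p in parts]),
            np.concatenate([p.b for p in parts]),
            np.concatenate([p.value for p in parts]),
            np.concatenate([p.theta for p in parts]),
            np.concatenate([p.phi for p in parts]),
            np.concatenate([p.saturated for p in parts]),
            scale,
        )


def _n_bins(resolution_deg: float) -> int:
    n = 90.0 / resolution_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"resolution_deg={resolution_deg} does not divide 90° evenly"
        )
    return int(round(n))


@dataclass
class ChromaticityGrid:
    """Fixed-resolution (theta, phi) lattice over the first octant.

    ``raw_counts[i, j]`` is the integer number of events binned to theta bin
    i, phi bin j (half-open bins [lo, hi), last bin closed at 90°).
    ``counts`` holds the adjusted cell count:

        counts = raw_counts / ω · ω̄

    where ω is the element's solid angle and ω̄ the mean element solid angle
    over the octant, making ``counts`` a surface-density estimate.
    """

    resolution_deg: float
    raw_counts: np.ndarray
    counts: np.ndarray
    n_events: int
    n_zero_value: int = 0
    n_saturated: int = 0
    scale_max: float = SCALE_MAX_CYTOMETER

    @property
    def n_theta(self) -> int:
        return self.raw_counts.shape[0]

    @property
    def n_phi(self) -> int:
        return self.raw_counts.shape[1]

    # --- geometry -------------------------------------------------------

    @property
    def theta_edges(self) -> np.ndarray:
        return np.linspace(0.0, 90.0, self.n_theta + 1)

    @property
    def phi_edges(self) -> np.ndarray:
        return np.linspace(0.0, 90.0, self.n_phi + 1)

    @property
    def theta_centers(self) -> np.ndarray:
        e = self.theta_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def phi_centers(self) -> np.ndarray:
        e = self.phi_edges
        return 0.5 * (e[:-1] + e[1:])

    def solid_angles(self) -> np.ndarray:
        """Per-element solid angle ω[i, j] in steradian, shape (n_theta, n_phi)."""
        return solid_angle_column(self.resolution_deg)[np.newaxis, :].repeat(
            self.n_theta, axis=0
        )

    @property
    def mean_solid_angle(self) -> float:
        return OCTANT_SOLID_ANGLE_SR / (self.n_theta * self.n_phi)

    def element_of(self, theta, phi):
        """Grid indices (i_theta, j_phi) for chromaticity coordinates.

        NaN inputs (undefined chromaticity) yield index -1 in both axes.
        """
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        res = self.resolution_deg
        with np.errstate(invalid="ignore"):
            i = np.floor(theta / res).astype(int)
            j = np.floor(phi / res).astype(int)
        # final bin closed at 90°
        i = np.clip(i, 0, self.n_theta - 1)
        j = np.clip(j, 0, self.n_phi - 1)
        bad = ~(np.isfinite(theta) & np.isfinite(phi))
        i = np.where(bad, -1, i)
        j = np.where(bad, -1, j)
        return i, j

    # --- serialization --------------------------------------------------

    def to_dataframe(self):
        """Dense long-format table (theta_lo, phi_lo, raw_count, adjusted_count)."""
        import pandas as pd

        ti, pj = np.meshgrid(
            np.arange(self.n_theta), np.arange(self.n_phi), indexing="ij"
        )
        return pd.DataFrame(
            {
                "theta_lo": ti.ravel() * self.resolution_deg,
                "phi_lo": pj.ravel() * self.resolution_deg,
                "raw_count": self.raw_counts.ravel(),
                "adjusted_count": self.counts.ravel(),
            }
        )


def solid_angle_column(resolution_deg: float) -> np.ndarray:
    """Solid angle (sr) of each phi row of elements at a given resolution.

    For an element spanning [θ1, θ2] × [φ1, φ2] (φ = elevation),
    ω = (θ2 − θ1)·(sin φ2 − sin φ1) with angles in radians; it depends only
    on the φ row.
    """
    n = _n_bins(resolution_deg)
    edges = np.radians(np.linspace(0.0, 90.0, n + 1))
    dtheta = np.radians(resolution_deg)
    return dtheta * np.diff(np.sin(edges))


def bin_events(events: ColorEvents, resolution_deg: float = 0.2) -> ChromaticityGrid:
    """Bin events onto a chromaticity grid with solid-angle-adjusted counts.

    Every defined-chromaticity event lands in exactly one element; zero-value
    events are tallied in ``n_zero_value``, never silently discarded.
    """
    n = _n_bins(resolution_deg)
    if events.n == 0:
        raise ValueError("cannot bin an empty event collection")
    ok = events.defined
    i, j = _bin_indices(events.theta[ok], events.phi[ok], resolution_deg, n)
    raw = np.zeros((n, n), dtype=np.int64)
    np.add.at(raw, (i, j), 1)
    omega = solid_angle_column(resolution_deg)
    mean_omega = OCTANT_SOLID_ANGLE_SR / (n * n)
    counts = raw / omega[np.newaxis, :] * mean_omega
    grid = ChromaticityGrid(
        resolution_deg=float(resolution_deg),
        raw_counts=raw,
        counts=counts,
        n_events=int(events.n),
        n_zero_value=int(events.n_zero_value),
        n_saturated=int(events.saturated.sum()),
        scale_max=events.scale_max,
    )
    if events.saturation_fraction > 0.01:
        warnings.warn(
            f"{100 * events.saturation_fraction:.2f}% of events saturate the "
            f"detector scale ({events.scale_max:g}); chromaticity of clipped "
            "events is distorted",
            stacklevel=2,
        )
    return grid


def _bin_indices(theta: np.ndarray, phi: np.ndarray, res: float, n: int):
    i = np.minimum(np.floor(theta / res).astype(int), n - 1)
    j = np.minimum(np.floor(phi / res).astype(int), n - 1)
    i = np.clip(i, 0, n - 1)
    j = np.clip(j, 0, n - 1)
    return i, j
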