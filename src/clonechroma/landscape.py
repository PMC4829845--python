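"""Chromatic landscape: the matching template for clonal assignment.

The landscape superimposes every participant clone's chromatic mode
("peak") and chromatic spread ("altitude" in adjusted cell count) on one
chromaticity grid.  Each grid element is then resolved to a single label:

* covered by exactly one clone's spread → that clone;
* covered by none → ``UNASSIGNED`` (out-of-bounds chromaticity);
* covered by several → per policy.  Under ``strict`` the element is
  ``UNASSIGNED`` (a cell there cannot be exclusively assigned).  Under
  ``majority(p)`` the overlapping clones' adjusted counts at the element
  give their relative occupation probabilities; the element goes to the
  top-occupancy clone iff its occupation probability ≥ p (ties →
  ``UNASSIGNED``).  The occupation probability is also the probability the
  assignment is correct, which is what the spillover matrix tallies.

Assigning a labelled reference pool back to its own landscape yields the
row-stochastic spillover matrix M_s (true clone × assigned clone ∪
UNASSIGNED); its off-diagonal clone mass is the per-clone assignment
error.  Compositions of unknown samples are per-clone assigned fractions;
optionally they can be corrected by inverting M_s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .colorspace import ChromaticityGrid, ColorEvents, bin_events, spherical_to_rgb
from .metrics import ModeResult, chromatic_mode, chromatic_spread, clone_profile

__all__ = [
    "UNASSIGNED",
    "ChromaticLandscape",
    "SpilloverMatrix",
    "ClonalComposition",
    "DriftReport",
    "build_landscape",
    "assign",
    "spillover",
    "composition",
    "drift_correct",
    "track",
]

#: Label for cells with out-of-bounds chromaticity or unresolvable elements.
UNASSIGNED = "Unassigned"


@dataclass
class ChromaticLandscape:
    """Per-element clone occupancy and the resolved assignment map."""

    resolution_deg: float
    clone_ids: list[str]
    count_grids: dict[str, np.ndarray]
    spread_masks: dict[str, np.ndarray]
    modes: dict[str, ModeResult]
    assignment: np.ndarray  # int map, clone index or -1 (UNASSIGNED)
    landscape_fraction: float
    policy: str
    majority_threshold: float

    @property
    def n_bins(self) -> int:
        return self.assignment.shape[0]

    def n_overlap_elements(self) -> int:
        cover = np.zeros_like(self.assignment)
        for m in self.spread_masks.values():
            cover += m
        return int((cover > 1).sum())

    def label_of_element(self, i: int, j: int) -> str:
        k = self.assignment[i, j]
        return UNASSIGNED if k < 0 else self.clone_ids[k]


def _resolve_assignment(
    clone_ids: Sequence[str],
    count_grids: Mapping[str, np.ndarray],
    spread_masks: Mapping[str, np.ndarray],
    policy: str,
    majority_threshold: float,
) -> np.ndarray:
    occ = np.stack(
        [np.where(spread_masks[c], count_grids[c], 0.0) for c in clone_ids]
    )  # (k, n, n)
    covered = np.stack([spread_masks[c] for c in clone_ids])
    n_cover = covered.sum(axis=0)
    top = occ.argmax(axis=0)
    top_val = occ.max(axis=0)
    total = occ.sum(axis=0)
    # is the top value strictly unique among covering clones?
    tied = (occ == top_val[np.newaxis]).sum(axis=0) > 1

    assignment = np.full(n_cover.shape, -1, dtype=np.int32)
    single = n_cover == 1
    assignment[single] = top[single]
    multi = n_cover > 1
    if policy == "strict":
        pass  # multi-clone elements stay UNASSIGNED
    elif policy == "majority":
        with np.errstate(invalid="ignore", divide="ignore"):
            prob = np.where(total > 0, top_val / total, 0.0)
        win = multi & ~tied & (prob >= majority_threshold)
        assignment[win] = top[win]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return assignment


def build_landscape(
    events: ColorEvents,
    labels: np.ndarray,
    resolution_deg: float = 0.2,
    landscape_fraction: float = 0.01,
    policy: str = "majority",
    majority_threshold: float = 0.5,
    smooth_sigma_deg: float = 0.5,
) -> ChromaticLandscape:
    """Build the landscape from a labelled (digitally pooled) reference.

    Each clone's grid and spread at ``landscape_fraction`` (default the 1%
    isosurface, the widest standard contour) define its footprint; the
    per-element assignment map is resolved per the module rules.  Clones
    should be equally represented (use ``digital_pool``); unequal counts
    bias occupation probabilities and are warned about.

    ``smooth_sigma_deg`` is the Gaussian density-estimation bandwidth
    applied to each clone's adjusted-count histogram before isosurface
    extraction.  A low-percentage isosurface of a *raw* finite-count
    histogram on a fine grid is dominated by empty elements (the connected
    component fragments and the footprint misses genuine clone territory);
    a modest bandwidth — default 0.5°, a few grid elements — makes the
    footprint an estimate of the underlying density's level set.  Set 0 to
    disable (appropriate for analytic or very dense histograms).
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != events.n:
        raise ValueError("labels must align with events")
    clone_ids = sorted(set(labels.tolist()))
    counts = {c: int((labels == c).sum()) for c in clone_ids}
    if any(v == 0 for v in counts.values()):
        raise ValueError("every clone must contribute at least one cell")
    if len(set(counts.values())) > 1:
        warnings.warn(
            "clones are unequally represented in the reference pool; "
            "occupation probabilities will be weighted accordingly",
            stacklevel=2,
        )
    count_grids, spread_masks, modes = {}, {}, {}
    for c in clone_ids:
        ev = events.subset(labels == c)
        grid = bin_events(ev, resolution_deg)
        if smooth_sigma_deg > 0:
            grid.counts = ndimage.gaussian_filter(
                grid.counts, sigma=smooth_sigma_deg / resolution_deg
            )
        mode = chromatic_mode(grid)
        contour = chromatic_spread(grid, mode, landscape_fraction)
        count_grids[c] = grid.counts
        spread_masks[c] = contour.mask
        modes[c] = mode
    assignment = _resolve_assignment(
        clone_ids, count_grids, spread_masks, policy, majority_threshold
    )
    return ChromaticLandscape(
        resolution_deg=float(resolution_deg),
        clone_ids=clone_ids,
        count_grids=count_grids,
        spread_masks=spread_masks,
        modes=modes,
        assignment=assignment,
        landscape_fraction=float(landscape_fraction),
        policy=policy,
        majority_threshold=float(majority_threshold),
    )


def assign(events: ColorEvents, landscape: ChromaticLandscape) -> np.ndarray:
    """Assign each cell to a clone (or UNASSIGNED) via its grid element.

    Total: every event receives exactly one label; zero-value events are
    UNASSIGNED.
    """
    n = landscape.n_bins
    res = landscape.resolution_deg
    out = np.full(events.n, UNASSIGNED, dtype=object)
    ok = events.defined
    if ok.any():
        i = np.minimum((events.theta[ok] / res).astype(int), n - 1)
        j = np.minimum((events.phi[ok] / res).astype(int), n - 1)
        idx = landscape.assignment[i, j]
        lut = np.array(landscape.clone_ids + [UNASSIGNED], dtype=object)
        out[ok] = lut[np.where(idx < 0, len(landscape.clone_ids), idx)]
    return out


@dataclass
class SpilloverMatrix:
    """Row-stochastic true-clone × (assigned clone ∪ UNASSIGNED) table.

    ``matrix[i, j]`` is the probability a cell of true clone i is assigned
    to clone j; the final column is UNASSIGNED.  The per-clone assignment
    error is the row mass on *wrong clone* columns (UNASSIGNED is tallied
    separately, as an abstention rather than an error).
    """

    clone_ids: list[str]
    matrix: np.ndarray  # (k, k+1)

    @property
    def columns(self) -> list[str]:
        return self.clone_ids + [UNASSIGNED]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.clone_ids, columns=self.columns)

    @property
    def per_clone_error(self) -> np.ndarray:
        k = len(self.clone_ids)
        off = self.matrix[:, :k].copy()
        np.fill_diagonal(off, 0.0)
        return off.sum(axis=1)

    @property
    def per_clone_unassigned(self) -> np.ndarray:
        return self.matrix[:, -1]

    @property
    def per_clone_correct(self) -> np.ndarray:
        return np.diag(self.matrix[:, : len(self.clone_ids)])

    @property
    def error_range(self) -> tuple[float, float]:
        e = self.per_clone_error
        return float(e.min()), float(e.max())

    def correct(self, observed: np.ndarray) -> np.ndarray:
        """Invert the forward model observed = M_sᵀ·true.

        ``observed`` holds the assigned fractions per clone column plus
        UNASSIGNED (length k+1, summing to ≤1).  Returns non-negative true
        clone fractions, renormalised to sum to 1 (non-negative least
        squares, so spillover-inflated clones are deflated and vice versa).
        """
        observed = np.asarray(observed, dtype=float)
        if observed.shape != (len(self.clone_ids) + 1,):
            raise ValueError("observed must have one entry per clone plus "
                             "UNASSIGNED")
        x, _ = optimize.nnls(self.matrix.T, observed)
        if x.sum() > 0:
            x = x / x.sum()
        return x


def spillover(
    landscape: ChromaticLandscape,
    events: ColorEvents,
    true_labels: np.ndarray,
) -> SpilloverMatrix:
    """Empirical spillover matrix from a labelled reference population."""
    true_labels = np.asarray(true_labels, dtype=object)
    present = sorted(set(true_labels.tolist()))
    missing = [c for c in present if c not in landscape.clone_ids]
    if missing:
        raise ValueError(f"true clones absent from landscape: {missing}")
    assigned = assign(events, landscape)
    k = len(landscape.clone_ids)
    col = {c: j for j, c in enumerate(landscape.clone_ids)}
    col[UNASSIGNED] = k
    matrix = np.zeros((k, k + 1))
    for i, c in enumerate(landscape.clone_ids):
        rows = true_labels == c
        n_i = int(rows.sum())
        if n_i == 0:
            raise ValueError(f"no reference cells for clone {c}")
        for lab in assigned[rows]:
            matrix[i, col[lab]] += 1
        matrix[i] /= n_i
    return SpilloverMatrix(clone_ids=list(landscape.clone_ids), matrix=matrix)


@dataclass
class ClonalComposition:
    """Clonal frequencies (%) of one sample; conserved to 100%."""

    sample_id: str | None
    timepoint: float | str | None
    frequencies: dict[str, float]  # percent per clone
    unassigned: float  # percent
    n_cells: int
    corrected_frequencies: dict[str, float] | None = None

    def total(self) -> float:
        return sum(self.frequencies.values()) + self.unassigned

    def to_series(self) -> pd.Series:
        s = pd.Series(self.frequencies)
        s[UNASSIGNED] = self.unassigned
        return s


def composition(
    events: ColorEvents,
    landscape: ChromaticLandscape,
    spillover_matrix: SpilloverMatrix | None = None,
    sample_id: str | None = None,
    timepoint=None,
) -> ClonalComposition:
    """Clonal composition of one sample via landscape assignment.

    With a spillover matrix, additionally reports corrected frequencies by
    solving observed = M_sᵀ·true with non-negative least squares and
    renormalising — an optional refinement on top of the raw assigned
    fractions.
    """
    if events.n == 0:
        raise ValueError("empty sample")
    assigned = assign(events, landscape)
    n = events.n
    freqs = {
        c: 100.0 * float((assigned == c).sum()) / n for c in landscape.clone_ids
    }
    unassigned = 100.0 * float((assigned == UNASSIGNED).sum()) / n
    corrected = None
    if spillover_matrix is not None:
        if spillover_matrix.clone_ids != landscape.clone_ids:
            raise ValueError("spillover matrix clones do not match landscape")
        observed = np.array(
            [freqs[c] / 100.0 for c in landscape.clone_ids] + [unassigned / 100.0]
        )
        x = spillover_matrix.correct(observed)
        corrected = {
            c: 100.0 * float(v) for c, v in zip(landscape.clone_ids, x)
        }
    return ClonalComposition(
        sample_id=sample_id,
        timepoint=timepoint,
        frequencies=freqs,
        unassigned=unassigned,
        n_cells=n,
        corrected_frequencies=corrected,
    )


# ---------------------------------------------------------------------------
# Chromatic drift correction
# ---------------------------------------------------------------------------


@dataclass
class DriftReport:
    """Affine chromaticity correction fitted from peak/mode matching."""

    matrix: np.ndarray  # 2×2
    offset: np.ndarray  # (2,)
    n_matched: int
    n_peaks: int
    residual_deg: float
    identity: bool
    matched_modes: list[str] = field(default_factory=list)

    def apply(self, theta: np.ndarray, phi: np.ndarray):
        pts = np.column_stack([theta, phi]) @ self.matrix.T + self.offset
        return pts[:, 0], pts[:, 1]

    @property
    def mean_shift_deg(self) -> tuple[float, float]:
        """Mean (theta, phi) displacement over the matched anchor points."""
        return (float(self.offset[0]), float(self.offset[1]))


def _find_peaks(
    grid: ChromaticityGrid, smooth_sigma_deg: float, n_peaks: int, rel_floor: float = 0.05
) -> np.ndarray:
    """Strongest local maxima of the smoothed histogram, as (theta, phi) deg."""
    sigma = max(smooth_sigma_deg / grid.resolution_deg, 1.0)
    sm = ndimage.gaussian_filter(grid.counts, sigma=sigma)
    size = max(int(round(2.0 / grid.resolution_deg)), 3)
    local_max = (sm == ndimage.maximum_filter(sm, size=size)) & (
        sm > rel_floor * sm.max()
    )
    ij = np.argwhere(local_max)
    if len(ij) == 0:
        return np.empty((0, 2))
    heights = sm[local_max]
    order = np.argsort(heights)[::-1][:n_peaks]
    ij = ij[order]
    tc, pc = grid.theta_centers, grid.phi_centers
    return np.column_stack([tc[ij[:, 0]], pc[ij[:, 1]]])


def drift_correct(
    events: ColorEvents,
    landscape: ChromaticLandscape,
    smooth_sigma_deg: float = 1.0,
    match_radius_deg: float = 5.0,
    min_matches: int = 3,
) -> tuple[ColorEvents, DriftReport]:
    """Correct slow chromatic drift before assignment.

    The sample's chromaticity histogram is smoothed and its strongest local
    density peaks are paired with the nearest landscape clone modes (within
    ``match_radius_deg``, greedily by distance, one-to-one).  An affine map
    on (theta, phi) is least-squares fitted from matched peaks to modes and
    applied to every cell's chromaticity; values are unchanged.  With fewer
    than ``min_matches`` pairs the identity is returned with a warning.
    Spurious sample peaks that match no mode are simply left out of the fit.
    """
    if len(landscape.clone_ids) < 3:
        raise ValueError("drift correction needs a landscape of ≥3 clone modes")
    grid = bin_events(events, landscape.resolution_deg)
    peaks = _find_peaks(grid, smooth_sigma_deg, n_peaks=3 * len(landscape.clone_ids))
    mode_xy = {
        c: np.array([m.theta, m.phi]) for c, m in landscape.modes.items()
    }
    # greedy one-to-one nearest matching, closest pairs first
    pairs = []
    for c, xy in mode_xy.items():
        if len(peaks) == 0:
            break
        d = np.hypot(peaks[:, 0] - xy[0], peaks[:, 1] - xy[1])
        k = int(np.argmin(d))
        if d[k] <= match_radius_deg:
            pairs.append((d[k], c, k))
    pairs.sort()
    used_peaks: set[int] = set()
    matched_src, matched_dst, matched_ids = [], [], []
    for _, c, k in pairs:
        if k in used_peaks:
            continue
        used_peaks.add(k)
        matched_src.append(peaks[k])
        matched_dst.append(mode_xy[c])
        matched_ids.append(c)

    if len(matched_src) < min_matches:
        warnings.warn(
            f"only {len(matched_src)} peak/mode matches (need {min_matches}); "
            "drift correction falls back to identity",
            stacklevel=2,
        )
        report = DriftReport(
            matrix=np.eye(2),
            offset=np.zeros(2),
            n_matched=len(matched_src),
            n_peaks=len(peaks),
            residual_deg=float("nan"),
            identity=True,
            matched_modes=matched_ids,
        )
        return events, report

    src = np.asarray(matched_src)
    dst = np.asarray(matched_dst)
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    matrix = coef[:2].T
    offset = coef[2]
    fitted = design @ coef
    residual = float(np.sqrt(np.mean(np.sum((fitted - dst) ** 2, axis=1))))
    report = DriftReport(
        matrix=matrix,
        offset=offset,
        n_matched=len(src),
        n_peaks=len(peaks),
        residual_deg=residual,
        identity=False,
        matched_modes=matched_ids,
    )

    theta = events.theta.copy()
    phi = events.phi.copy()
    ok = events.defined
    t2, p2 = report.apply(theta[ok], phi[ok])
    theta[ok] = np.clip(t2, 0.0, 90.0)
    phi[ok] = np.clip(p2, 0.0, 90.0)
    r, g, b = spherical_to_rgb(theta, phi, events.value)
    corrected = ColorEvents(
        r=np.where(ok, r, events.r),
        g=np.where(ok, g, events.g),
        b=np.where(ok, b, events.b),
        value=events.value.copy(),
        theta=theta,
        phi=phi,
        saturated=events.saturated.copy(),
        scale_max=events.scale_max,
        meta={**events.meta, "drift_corrected": True},
    )
    return corrected, report


def track(
    samples: Sequence[tuple[float, ColorEvents]],
    landscape: ChromaticLandscape,
    spillover_matrix: SpilloverMatrix | None = None,
    drift_correction: bool = False,
) -> tuple[list[ClonalComposition], pd.DataFrame]:
    """Clonal-composition time series with replicate mean ± SD.

    ``samples`` is a list of (timepoint, events); several entries at the
    same timepoint are replicates.  Returns the per-sample compositions and
    a tidy table (timepoint, clone, mean_pct, sd_pct, n_samples); SD is NaN
    for a single replicate (flagged by n_samples = 1).
    """
    if not samples:
        raise ValueError("no samples to track")
    comps: list[ClonalComposition] = []
    for k, (t, events) in enumerate(samples):
        ev = events
        if drift_correction:
            ev, _ = drift_correct(ev, landscape)
        comps.append(
            composition(ev, landscape, spillover_matrix,
                        sample_id=f"sample{k}", timepoint=t)
        )
    rows = []
    labels = landscape.clone_ids + [UNASSIGNED]
    timepoints = sorted({c.timepoint for c in comps})
    for t in timepoints:
        group = [c for c in comps if c.timepoint == t]
        for lab in labels:
            vals = np.array(
                [c.frequencies.get(lab, c.unassigned if lab == UNASSIGNED else 0.0)
                 for c in group]
            )
            rows.append(
                {
                    "timepoint": t,
                    "clone_id": lab,
                    "mean_pct": float(vals.mean()),
                    "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "n_samples": len(vals),
                }
            )
    return comps, pd.DataFrame(rows)
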