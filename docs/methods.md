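# Methods

## The problem

In combinatorial fluorescent-protein clonal marking (Brainbow/LeGO-style
RGB marking), every clone inherits a characteristic ratio of red, green and
blue fluorescence from its founder cell.  Tracking clones in a pooled
population then reduces to a color-matching problem: given a cell's
(R, G, B) intensities, which clone did it come from?  `clonechroma`
implements a deterministic, validated answer: clones are characterised by
four color metrics, mutually distinguishable clones are selected for
pooling, and cells are assigned through a *chromatic landscape* whose
error is quantified by a spillover matrix.

## Color space

A cell's fluorescence vector (R, G, B) with non-negative components lives
in the first octant of 3-D intensity space.  We convert to spherical
coordinates:

* value `v = sqrt(R² + G² + B²)` — total brightness;
* azimuth `Θ = atan2(G, R)` — measured from the R axis toward G;
* elevation `Φ = atan2(B, sqrt(R² + G²))` — from the R–G plane toward B.

Both angles are in degrees, in [0°, 90°].  The pair (Θ, Φ) is the cell's
**chromaticity**: invariant under uniform scaling of all three channels,
so it captures the R:G:B ratio and discards brightness.  Pure-R/G/B cells
sit at (0, 0), (90, 0) and the Φ = 90° pole; at the pole the azimuth is
degenerate and reported as 0 by convention.  A zero vector has no defined
chromaticity; such events are flagged and counted, never silently dropped,
because composition analysis must conserve event counts.

Chromaticity distributions are histogrammed on a fixed (Θ, Φ) lattice
(default 0.2° × 0.2°, i.e. 450 × 450 elements).  Bins are half-open
[lo, hi) with the final bin closed at 90°, so binning is total and
deterministic.  Because an element spanning [Θ₁, Θ₂] × [Φ₁, Φ₂] subtends a
solid angle ω = (Θ₂−Θ₁)(sin Φ₂ − sin Φ₁) that shrinks toward the pole, raw
counts are converted to **adjusted counts** `n_adj = n_raw / ω · ω̄`, with
ω̄ the mean element solid angle over the octant.  Adjusted counts are a
surface-density estimate: a population uniform per unit sphere area yields
a flat histogram (verified by a χ² test against the analytic solid-angle
density in the test suite).  The normalisation constant ω̄ is a package
convention chosen so adjusted and raw counts agree in overall magnitude.

Negative intensities (baseline-subtracted cytometer output) are clamped to
zero by default; `drop` and `error` policies are available.  Clamping is
the default because it preserves event counts.  Events at the detector
ceiling (65535 for 16-bit microscopy, 1e5 for the cytometer scale) are
retained but flagged, and the saturation fraction is reported: clipping
distorts chromaticity (e.g. cells with R ≈ G clipped in both channels
collapse onto the exact Θ = 45° line), so a high saturation fraction is a
data-quality warning, not a silent correction.

## The four clonal-color metrics

**Chromatic mode** — the grid element with the highest adjusted count,
`n_max`.  Ties are broken lexicographically by (Θ index, Φ index) and
flagged; a centroid-of-ties alternative is available.

**Chromatic spread** — for a fraction f of n_max (standard fractions 50,
25, 10, 5, 2, 1%), the 4-connected component of
{elements with adjusted count ≥ f·n_max} containing the mode.  Restricting
to the mode's component makes a spread one region around the clone's color
center; disconnected super-threshold islands are excluded and flagged.
Area is reported as solid angle (steradian and deg² of solid angle) and as
planar (Θ, Φ) area; spherical area is the default since the grid lives on
a sphere surface, but the planar area is what a level-set of a planar
density integrates to, so both are exposed.  The fraction of the clone's
cells whose chromaticity falls inside each contour is computed from the
raw event coordinates.  On an analytic isotropic Gaussian density the
extracted contour area matches the closed-form level-set area
π σ² (−2 ln f) to within the boundary-discretisation band.

**Relative clonal brightness** — autofluorescence (AF) behaves like a
clonal color with its own mode, spread and value.  One brightness unit,
1 xAF, is defined from an untransduced reference population: the package
takes the 99th percentile of the value distribution of AF cells inside the
AF population's 2% spread.  With that definition, a cell at
`b = v / v_AF` multiples of 1 xAF has an expected AF contribution to total
fluorescence below 1/b for ≥99% of AF-like cells; the quantile is
configurable since any high quantile satisfies the same logic with a
different safety margin.  The clone-level metric is the fraction of cells
with b ≥ b\* (default b\* = 20, i.e. AF < 5% of signal); ideal value 1.

**Chromatic stability** — for T ≥ 2 timepoints, each with its own spread
contour at a configured fraction (default 2%, the fraction that also
anchors the AF reference),

    stability = (area(∪ₜ contourₜ) − minₜ areaₜ) / (minₜ areaₜ · (T − 1)).

This is the extra area covered per additional timepoint, normalised by the
smallest single-timepoint spread: zero when the color never moves,
unit-free and insensitive to the clone's own footprint size, so clones of
different spread widths are comparable.  Uniform scaling of all cell
values leaves it unchanged (chromaticity-only metric).

## Pool design

Triage admits clones with relative clonal brightness ≥ 0.975 at b\* = 20
(read as: at least 97.5% of the clone's cells exceed b\*; the alternative
reading — top 2.5% of clones — is inconsistent with lowering the cutoff to
admit more clones, and is not used) and with chromatic stability that is
not a cohort outlier.  The outlier rule is a Tukey fence (> Q3 + 1.5·IQR
rejected; needs ≥4 clones) by default, with a z-score (> 3σ) alternative
for small cohorts.

Two clones are **compatible** when their chromatic modes fall in different
grid elements and their 50% spreads share no element.  Compatibility is an
undirected graph; a pool of mutually distinguishable clones is a clique.
Selection runs a greedy max-degree heuristic, falling back to an exact
maximum-clique search (networkx) when the greedy result misses the target
and the admitted cohort has ≤ 25 clones; the test suite checks exactness
against brute-force subset enumeration on random 10–12-node graphs.

Digital pooling concatenates an equal-size subsample (without replacement,
seeded) of each selected clone's events, keeping true-clone labels.

## Chromatic landscape and assignment

The landscape superimposes each participant clone's mode and spread at the
*landscape fraction* — default the 1% isosurface, the widest standard
contour — on one grid.  Each element resolves to a single label:

* inside exactly one clone's spread → that clone;
* inside none → `Unassigned` (out-of-bounds chromaticity);
* inside several → policy-dependent.  `strict`: `Unassigned` (the cell
  cannot be exclusively assigned).  `majority(p)` (default p = 0.5): the
  overlapping clones' adjusted counts at the element are their relative
  occupation probabilities; the element goes to the top clone iff its
  probability ≥ p, ties → `Unassigned`.

Assignment of a cell is a constant-time lookup of its grid element; it is
total (every cell gets exactly one label, zero-value cells are
`Unassigned`).

Because a low-percentage isosurface of a raw finite-count histogram on a
fine grid is dominated by empty elements (at 10⁴ cells on the 0.2° grid a
wide clone's 1% component fragments and misses genuine clone territory),
`build_landscape` smooths each clone's adjusted-count histogram with a
Gaussian kernel before isosurface extraction (default bandwidth 0.5°, a
few grid elements — small against typical clone spreads of several
degrees).  The footprint is then an estimate of the underlying density's
level set rather than of the noise.  Metrics-level spreads are *not*
smoothed; the bandwidth only affects the assignment template.

**Spillover matrix** `M_s`: re-assigning a labelled reference pool to its
own landscape gives a row-stochastic k × (k+1) table — row = true clone,
columns = assigned clones plus `Unassigned`.  The per-clone assignment
*error* is the row mass on wrong-clone columns; `Unassigned` is an
abstention, tallied separately.  The reported error range is the min/max
of that per-clone error.

**Composition**: per-clone assigned percentages plus `Unassigned`,
conserved to 100%.  Optionally the forward model `observed = M_sᵀ · true`
is inverted by non-negative least squares with renormalisation to produce
corrected frequencies — an extension of the matrix's accuracy-reporting
role, clearly labelled in outputs.  Composition works equally when the
landscape is incomplete (unknown cells simply accumulate in `Unassigned`).

**Drift correction**: slow chromatic drift is corrected before assignment
by matching the sample histogram's strongest smoothed density peaks to the
landscape's clone modes (nearest, one-to-one, within 5° by default) and
least-squares fitting an affine map on (Θ, Φ), applied to every cell's
chromaticity; values are untouched.  An affine map was chosen over
elastic/thin-plate registration because with ≤ ~15 anchor peaks a 6-degree-
of-freedom fit is robust and deterministic; fewer than 3 matches falls
back to the identity with a warning, and unmatched (spurious) peaks are
excluded from the fit.  The correction is idempotent to within one grid
element.  Collinear anchor sets leave the fit under-determined in the
transverse direction; landscapes whose modes span the plane condition it
well.

**Tracking** assigns replicate samples per timepoint and reports per-clone
mean ± SD trajectories (sample SD, NaN for a single replicate).

## Synthetic data generator

No public per-cell cytometry data accompanies the tracking framework, so
the generator produces populations with the statistical structure the
analysis assumes — it is the test bed for every other module:

* **Copy numbers**: per construct, Poisson(MOI), so the 3FP⁺ fraction is
  (1 − e^(−MOI))³ — the mechanism by which MOI controls color diversity.
* **Clone events**: channel intensity
  `I_c = copies_c · brightness_c · s · ε_c · drift_c^t + AF_c`, with
  `s ~ lognormal(0, σ_cell)` shared across channels (a cell-cycle-like
  size/expression factor that moves value but cancels in chromaticity) and
  `ε_c ~ lognormal(0, σ_channel)` independent per channel (the noise that
  actually spreads chromaticity).  Defaults σ_cell = 0.5, σ_channel = 0.15.
* **Autofluorescence**: a lognormal value (default mean 150 a.u. on the
  1e5 cytometer scale, σ = 0.4) along a characteristic chromaticity
  (Θ = 40°, Φ = 25°) with 3° angular jitter, added to every cell — dim
  cells are pulled toward the AF mode, as in real data.
* **Drift**: multiplicative per-channel factor per unit time; unequal
  factors shift chromaticity (instability), a single factor < 1 emulates
  FP silencing toward autofluorescence.
* **Detector**: intensities clip at the scale ceiling and clipped events
  are flagged.
* **Pools**: clone frequencies evolve by exponential competition
  `f_i(t) ∝ f_i e^{g_i t}`; realised counts are multinomial; labels are
  retained for ground-truth checks.

The default 15-clone panel places clone chromaticities on a 3 × 5 (Θ, Φ)
lattice (Θ ∈ {12°, 45°, 78°}, Φ ∈ {8°, 26°, 44°, 62°, 80°}) at total value
2.5e4 a.u.  That spacing puts the panel in the regime the framework is
designed for: 50% spreads disjoint (so the pool satisfies the
distinguishability criterion) while 1% landscape contours touch (so
assignment error is nonzero and the spillover matrix is informative).  The
amplitude keeps essentially every cell above b\* = 20 xAF for the default
AF while making channel saturation negligible (≈0.2%).

What the generator does **not** emulate: spectral overlap between
detection channels (the three fluorescent proteins are treated as
spectrally separated, matching instruments set up without compensation),
integration-site effects, mechanistic cell-cycle structure (only its
common-factor signature), FP maturation kinetics and pH sensitivity, and
instrument-specific nonlinearity.  Passing tests therefore demonstrate the
*analysis chain* is correct under the stated statistical model, not that
any particular instrument's data meets that model.

## Numerical choices and problem sizes

* All randomness flows from a single seed through `numpy`'s Generator;
  per-stage streams are passed explicitly, so every pipeline output is
  bit-reproducible for a given configuration.
* Numeric outputs are written with 9 significant digits for cross-run
  diffing.
* The validation scenario in `scripts/acceptance.py` uses 15 clones ×
  10⁴ cells on the 0.2° grid — enough cells that per-clone assignment
  fractions have Monte-Carlo standard errors ≈ 0.3 percentage points.
  Unit tests use coarser grids (0.5°–3°) and 10³–10⁴ cells, which exercise
  identical code paths.
* Degenerate inputs: empty event sets, zero-value cells, empty grids,
  single-timepoint stability, sub-minimal AF populations and cohorts below
  the IQR-rule minimum all raise explicit errors (or flags where the event
  must be preserved).

## Known limitations

* The adjusted-count, xAF-quantile, stability-denominator and multi-clone
  assignment rules each admit more than one reasonable convention; the
  package freezes one (documented above) and exposes the alternatives it
  implements via configuration.  Results are comparable only across runs
  sharing one convention.
* Mode and spread estimates are histogram-based; for very small samples
  (≲10³ cells) on fine grids they are noisy, and the landscape bandwidth
  becomes the dominant smoothing scale.
* The affine drift model corrects global chromaticity shifts only;
  clone-specific (differential) drift is detected by the stability metric
  and handled by triage, not by correction.
* Assignment is color-only by design; no spatial or morphological
  information is used.
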