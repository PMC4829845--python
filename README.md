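# clonechroma

Quantitative RGB chromaticity analysis for fluorescent multi-clonal
tracking.

When a cell population is marked by combinatorial expression of three
fluorescent proteins (Brainbow-style germline constructs, LeGO lentiviral
RGB marking), each clone inherits a characteristic red:green:blue
fluorescence ratio from its founder.  `clonechroma` turns that ratio into
a rigorous clonal identifier for researchers running flow-cytometry-based
clonal tracking experiments: it tells you which clones are usable, which
can be pooled together, and — for every cell of a pooled sample — which
clone it came from, with a quantified error.

## The model

Per-cell intensities (R, G, B) are converted to spherical coordinates:
value `v = √(R²+G²+B²)` (brightness) and **chromaticity** — azimuth
`Θ = atan2(G, R)` and elevation `Φ = atan2(B, √(R²+G²))`, both in
[0°, 90°] — which is invariant to brightness and captures only the R:G:B
ratio.  Chromaticity histograms live on a fixed (Θ, Φ) grid (default 0.2°)
with counts normalised per unit solid angle.

Four metrics characterise a clone's color:

| metric | definition | ideal |
|---|---|---|
| chromatic mode | grid element with the highest adjusted count `n_max` | — |
| chromatic spread | mode-connected region above `f · n_max` (f = 50…1%) | small |
| relative clonal brightness | fraction of cells above `b*` multiples of the autofluorescence unit (1 xAF), default `b* = 20` | 1 |
| chromatic stability | extra spread area per timepoint ÷ smallest single-timepoint spread | 0 |

Clones that are bright (≥ 97.5% of cells above b\*) and stable (not a
cohort outlier) are candidates; clones with distinct modes and disjoint
50% spreads are mutually distinguishable, and a maximal compatible subset
(a clique in the compatibility graph) is pooled.  The pooled reference
defines a **chromatic landscape** — every clone's mode and 1%-isosurface
footprint on one grid, with per-element assignment rules (majority
occupation probability by default; unresolvable or out-of-bounds elements
are `Unassigned`).  Re-assigning the labelled reference yields the
row-stochastic **spillover matrix** `M_s`, whose off-diagonal mass bounds
the per-clone assignment error; samples over time are assigned against the
landscape, after optional affine drift correction, to produce clonal
composition trajectories.

A synthetic-data module generates populations with the statistical
structure the analysis assumes (Poisson copy numbers vs MOI, lognormal
cell-scale and channel noise, additive autofluorescence, detector
ceilings, temporal drift), so the whole chain is testable end-to-end.
See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

```python
import numpy as np
import clonechroma as cc

rng = np.random.default_rng(0)

# six synthetic clones plus an autofluorescence reference
specs = cc.reference_panel(n_clones=6)
af = cc.AFSpec()
clones = {s.clone_id: cc.simulate_clone(s, af, 5000, seed=rng) for s in specs}
af_events = cc.simulate_af(af, 10_000, seed=rng)

# brightness metric against the 1 xAF autofluorescence unit
ref = cc.xaf_unit(af_events, resolution_deg=1.0)
print(f"1 xAF = {ref.v_af:.0f} a.u.")
for cid, ev in clones.items():
    prof = cc.clone_profile(cid, ev, 1.0, ref=ref, b_star=20)
    c50 = prof.spreads[0.50]
    print(f"{cid}: mode (Θ={prof.mode.theta:.1f}°, Φ={prof.mode.phi:.1f}°), "
          f"50% spread {c50.area_deg2:.1f} deg² "
          f"(encloses {100*c50.enclosed_fraction:.1f}% of cells), "
          f"brightness {prof.relative_brightness:.3f}")

# landscape, spillover matrix and composition of the pooled reference
pooled, labels = cc.digital_pool(clones, 5000, seed=rng)
scape = cc.build_landscape(pooled, labels, 0.2, landscape_fraction=0.01)
ms = cc.spillover(scape, pooled, labels)
lo, hi = ms.error_range
print(f"spillover error range [{100*lo:.2f}%, {100*hi:.2f}%]")
comp = cc.composition(pooled, scape)
print({c: round(v, 2) for c, v in comp.frequencies.items()},
      "unassigned", round(comp.unassigned, 2))
```

Output:

```
1 xAF = 384 a.u.
C01: mode (Θ=10.5°, Φ=7.5°), 50% spread 13.9 deg² (encloses 46.7% of cells), brightness 0.991
C02: mode (Θ=41.5°, Φ=8.5°), 50% spread 35.6 deg² (encloses 48.6% of cells), brightness 0.989
C03: mode (Θ=78.5°, Φ=8.5°), 50% spread 16.8 deg² (encloses 54.2% of cells), brightness 0.987
C04: mode (Θ=12.5°, Φ=25.5°), 50% spread 34.1 deg² (encloses 44.4% of cells), brightness 0.990
C05: mode (Θ=45.5°, Φ=24.5°), 50% spread 70.5 deg² (encloses 40.2% of cells), brightness 0.993
C06: mode (Θ=78.5°, Φ=23.5°), 50% spread 28.8 deg² (encloses 39.9% of cells), brightness 0.992
spillover error range [0.00%, 0.02%]
{'C01': 16.54, 'C02': 16.63, 'C03': 16.56, 'C04': 16.57, 'C05': 16.6, 'C06': 16.59} unassigned 0.51
```

Reading it: every clone keeps >98% of its cells above 20 xAF
(autofluorescence contributes <5% of their signal); the six modes are well
separated and each 50% contour encloses roughly half the clone's cells, as
a half-maximum contour of a unimodal distribution should.  Pooling the six
clones at equal counts and re-assigning them against their own landscape
misassigns at most 0.02% of any clone's cells, and the recovered
composition is six frequencies of ≈16.6% (= 100/6) with 0.5% of cells
unassigned.

The same stages are available from the shell:

```sh
clonechroma simulate scenario.yaml --out run/        # full pipeline
clonechroma hist events.csv --resolution 0.2 --out grid.csv --plot hist.png
clonechroma metrics clone.fcs --af af.fcs --bstar 20
clonechroma design-pool profiles.csv --af af.fcs --target 15 --out design/
clonechroma build-landscape pool.csv --fraction 1 --policy majority:0.5 \
    --out L.json --ms Ms.csv
clonechroma assign sample.fcs --landscape L.json --ms Ms.csv --drift-correct \
    --out composition.csv
clonechroma track samples.tsv --landscape L.json --out timeseries.csv
```

Events load from 3-column CSV (`r,g,b` header) or FCS 2.0/3.0/3.1 files
(channels selected by `$PnN`/`$PnS` name).

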