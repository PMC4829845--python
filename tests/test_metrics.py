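"""Chromatic mode, spread, xAF brightness and stability."""

import numpy as np
import pytest

import clonechroma as cc
from clonechroma.colorspace import (
    OCTANT_SOLID_ANGLE_SR,
    ChromaticityGrid,
    solid_angle_column,
)
from clonechroma.metrics import chromatic_mode, chromatic_spread

from conftest import point_mass_events


def analytic_grid(counts, resolution_deg):
    """Grid with prescribed adjusted counts (no sampling)."""
    n = counts.shape[0]
    return ChromaticityGrid(
        resolution_deg=resolution_deg,
        raw_counts=np.zeros_like(counts, dtype=np.int64),
        counts=np.asarray(counts, dtype=float),
        n_events=0,
    )


class TestChromaticMode:
    def test_single_nonzero_element(self):
        counts = np.zeros((30, 30))
        counts[4, 7] = 3.5
        mode = chromatic_mode(analytic_grid(counts, 3.0))
        assert mode.element == (4, 7)
        assert mode.n_max == 3.5
        assert not mode.tied

    def test_tie_breaks_lexicographically_and_flags(self):
        counts = np.zeros((30, 30))
        counts[10, 20] = counts[5, 25] = 2.0
        mode = chromatic_mode(analytic_grid(counts, 3.0))
        assert mode.element == (5, 25)
        assert mode.tied

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError, match="mode"):
            chromatic_mode(analytic_grid(np.zeros((30, 30)), 3.0))

    def test_mode_matches_generator_chromaticity(self):
        # unimodal lognormal clone: mode within one grid element of the
        # closed-form chromaticity of the mean-ratio triplet
        mean_rgb = (400.0, 900.0, 250.0)
        spec = cc.SyntheticCloneSpec("m", (1, 1, 1), mean_rgb,
                                     cell_scale_sigma=0.4,
                                     channel_noise_sigma=0.10)
        events = cc.simulate_clone(spec, None, 10_000, seed=11)
        grid = cc.bin_events(events, 1.0)
        mode = chromatic_mode(grid)
        theta_true, phi_true, _ = cc.rgb_to_spherical(*mean_rgb)
        i_true, j_true = grid.element_of(theta_true, phi_true)
        assert abs(mode.element[0] - i_true) <= 1
        assert abs(mode.element[1] - j_true) <= 1


class TestChromaticSpread:
    def test_point_mass_spread_is_one_element(self):
        events = point_mass_events(30, 40, n=50)
        prof = cc.clone_profile("pm", events, 1.0, fractions=(0.5, 0.01))
        for f in (0.5, 0.01):
            contour = prof.spreads[f]
            assert contour.n_elements == 1
            assert contour.enclosed_fraction == 1.0
            j = prof.mode.element[1]
            assert contour.area_sr == pytest.approx(solid_angle_column(1.0)[j])

    def test_nesting_and_monotonicity_over_fractions(self, noisy_pair):
        _, events = noisy_pair
        prof = cc.clone_profile("A", events["A"], 1.0)
        fr = sorted(prof.spreads)  # ascending fractions
        for f_lo, f_hi in zip(fr, fr[1:]):
            lo, hi = prof.spreads[f_lo], prof.spreads[f_hi]
            # contour at the higher fraction nests inside the lower one
            assert np.all(lo.mask[hi.mask])
            assert lo.area_sr >= hi.area_sr
            assert lo.enclosed_fraction >= hi.enclosed_fraction

    @pytest.mark.parametrize("fraction", [0.5, 0.1, 0.02])
    def test_gaussian_level_set_area(self, fraction):
        # isotropic planar Gaussian density: analytic level-set area is
        # pi * sigma^2 * (-2 ln f)
        res, sigma = 0.2, 2.0
        n = int(90 / res)
        centers = (np.arange(n) + 0.5) * res
        th, ph = np.meshgrid(centers, centers, indexing="ij")
        counts = np.exp(-((th - 45.0) ** 2 + (ph - 10.0) ** 2) / (2 * sigma**2))
        grid = analytic_grid(counts, res)
        mode = chromatic_mode(grid)
        contour = chromatic_spread(grid, mode, fraction)
        analytic = np.pi * sigma**2 * (-2.0 * np.log(fraction))
        boundary_band = 2 * np.pi * sigma * np.sqrt(-2 * np.log(fraction)) * res
        assert abs(contour.area_planar_deg2 - analytic) <= boundary_band

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.exponential(1.0, (20, 20))
        counts[rng.random((20, 20)) < 0.5] = 0.0
        grid = analytic_grid(counts, 4.5)
        mode = chromatic_mode(grid)
        contour = chromatic_spread(grid, mode, 0.3)
        assert contour.elements() == _flood_fill(counts, mode.element,
                                                 0.3 * mode.n_max)

    def test_fraction_bounds(self):
        grid = analytic_grid(np.ones((20, 20)), 4.5)
        mode = chromatic_mode(grid)
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                chromatic_spread(grid, mode, bad)


def _flood_fill(counts, start, level):
    """Exhaustive 4-connected region growing above a density level."""
    seen, stack = set(), [start]
    while stack:
        i, j = stack.pop()
        if (i, j) in seen or not (0 <= i < counts.shape[0]) \
                or not (0 <= j < counts.shape[1]) or counts[i, j] < level:
            continue
        seen.add((i, j))
        stack += [(i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)]
    return seen


class TestXafBrightness:
    def test_constant_af_population_defines_its_value_as_unit(self):
        events = point_mass_events(40, 25, n=2000, value=10.0)
        ref = cc.xaf_unit(events, 1.0)
        assert ref.v_af == pytest.approx(10.0)

    def test_lognormal_af_quantile_matches_closed_form(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(np.log(10.0), 0.3, 10_000)
        events = cc.ColorEvents.from_spherical(
            np.full(values.size, 40.0), np.full(values.size, 25.0), values
        )
        ref = cc.xaf_unit(events, 1.0)
        z99 = 2.3263478740408408
        assert ref.v_af == pytest.approx(np.exp(np.log(10.0) + z99 * 0.3),
                                         rel=0.05)

    def test_empty_and_sparse_af_inputs_error(self):
        with pytest.raises(ValueError, match="empty"):
            cc.xaf_unit(cc.ColorEvents.from_rgb([], [], []), 1.0)
        with pytest.raises(ValueError, match="inside"):
            cc.xaf_unit(point_mass_events(40, 25, n=10), 1.0)

    def test_cell_xaf_scaling(self, af_reference):
        v = af_reference.v_af
        b = cc.cell_xaf(np.array([v, 20 * v, 0.0]), af_reference)
        assert b == pytest.approx([1.0, 20.0, 0.0])

    def test_relative_brightness_split_population(self, af_reference):
        v = af_reference.v_af
        half = np.r_[np.full(500, 40 * v), np.full(500, 5 * v)]
        events = cc.ColorEvents.from_spherical(
            np.full(1000, 30.0), np.full(1000, 30.0), half
        )
        assert cc.relative_clonal_brightness(events, af_reference, 20) == 0.5
        assert cc.relative_clonal_brightness(events, af_reference, 4) == 1.0
        assert cc.relative_clonal_brightness(events, af_reference, 50) == 0.0

    def test_relative_brightness_non_increasing_in_bstar(self, af_reference,
                                                         noisy_pair):
        _, events = noisy_pair
        vals = [cc.relative_clonal_brightness(events["A"], af_reference, b)
                for b in (1, 5, 20, 80)]
        assert vals == sorted(vals, reverse=True)


class TestChromaticStability:
    def _profiles_with_shift(self, delta, timepoints=(0, 1, 2), res=0.5):
        rng = np.random.default_rng(99)
        base_theta = 40 + rng.normal(0, 2.0, 4000)
        base_phi = 30 + rng.normal(0, 2.0, 4000)
        profs = []
        for t in timepoints:
            ev = cc.ColorEvents.from_spherical(
                np.clip(base_theta + delta * t, 0, 90),
                np.clip(base_phi, 0, 90),
                np.full(4000, 1000.0),
            )
            profs.append(cc.clone_profile("drift", ev, res, fractions=(0.02,),
                                          timepoint=t))
        return profs

    def test_identical_contours_give_zero(self):
        profs = self._profiles_with_shift(0.0)
        report = cc.chromatic_stability(profs, 0.02)
        assert report.stability == 0.0

    def test_disjoint_equal_area_contours_give_one(self):
        # two timepoints, same phi row: equal solid angle, disjoint
        p1 = cc.clone_profile("x", point_mass_events(20, 30), 1.0,
                              fractions=(0.02,), timepoint=0)
        p2 = cc.clone_profile("x", point_mass_events(70, 30), 1.0,
                              fractions=(0.02,), timepoint=1)
        report = cc.chromatic_stability([p1, p2], 0.02)
        assert report.stability == pytest.approx(1.0)

    def test_stability_increases_with_drift_magnitude(self):
        scores = [cc.chromatic_stability(self._profiles_with_shift(d), 0.02).stability
                  for d in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_single_timepoint_is_an_error(self):
        p = cc.clone_profile("x", point_mass_events(20, 30), 1.0, timepoint=0)
        with pytest.raises(ValueError, match="two timepoints"):
            cc.chromatic_stability([p])

    def test_invariant_under_uniform_value_scaling(self):
        profs = self._profiles_with_shift(1.0)
        scaled = []
        for p in profs:
            ev = cc.ColorEvents.from_rgb(p.events.r * 7, p.events.g * 7,
                                         p.events.b * 7)
            scaled.append(cc.clone_profile("drift", ev, 0.5, fractions=(0.02,),
                                           timepoint=p.timepoint))
        s1 = cc.chromatic_stability(profs, 0.02).stability
        s2 = cc.chromatic_stability(scaled, 0.02).stability
        assert s1 == pytest.approx(s2, rel=1e-12)
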