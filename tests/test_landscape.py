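"""Chromatic landscape: assignment, spillover, composition, drift, tracking."""

import numpy as np
import pytest

import clonechroma as cc
from clonechroma.landscape import UNASSIGNED

from conftest import point_mass_events


def _pool(events_by_clone, n_per_clone, seed=0):
    return cc.digital_pool(events_by_clone, n_per_clone, seed=seed)


@pytest.fixture(scope="module")
def disjoint_landscape():
    events = {
        "A": point_mass_events(10, 10, n=200),
        "B": point_mass_events(60, 10, n=200),
        "C": point_mass_events(40, 70, n=200),
    }
    pooled, labels = _pool(events, 200)
    scape = cc.build_landscape(pooled, labels, 1.0, 0.01, smooth_sigma_deg=0)
    return scape, pooled, labels


@pytest.fixture(scope="module")
def overlap_pair_landscape():
    """Two clones sharing grid elements with engineered unequal density."""
    a = cc.ColorEvents.concatenate([
        point_mass_events(30.5, 30.5, n=900),
        point_mass_events(31.5, 30.5, n=100),   # shared element, A minority
    ])
    b = cc.ColorEvents.concatenate([
        point_mass_events(32.5, 30.5, n=700),
        point_mass_events(31.5, 30.5, n=300),   # shared element, B majority
    ])
    pooled, labels = _pool({"A": a, "B": b}, 1000)
    scape = cc.build_landscape(pooled, labels, 1.0, 0.01,
                               policy="majority", majority_threshold=0.5,
                               smooth_sigma_deg=0)
    return scape, pooled, labels


class TestBuildLandscape:
    def test_disjoint_clones_map_to_themselves(self, disjoint_landscape):
        scape, _, _ = disjoint_landscape
        assert scape.n_overlap_elements() == 0
        for c, mask in scape.spread_masks.items():
            idx = scape.clone_ids.index(c)
            assert np.all(scape.assignment[mask] == idx)

    def test_identical_clones_strict_policy_all_unassigned(self):
        events = {"A": point_mass_events(30, 30, n=100),
                  "B": point_mass_events(30, 30, n=100)}
        pooled, labels = _pool(events, 100)
        scape = cc.build_landscape(pooled, labels, 1.0, 0.01, policy="strict",
                                   smooth_sigma_deg=0)
        covered = np.zeros_like(scape.assignment, dtype=bool)
        for m in scape.spread_masks.values():
            covered |= m
        assert np.all(scape.assignment[covered] == -1)

    def test_overlap_border_matches_pairwise_intersection_oracle(self):
        rng = np.random.default_rng(8)
        specs = [
            cc.SyntheticCloneSpec(f"n{k}", (1, 1, 1),
                                  tuple(cc.spherical_to_rgb(t, 30, 2.0e4)),
                                  cell_scale_sigma=0.3, channel_noise_sigma=0.15)
            for k, t in enumerate((20.0, 45.0, 70.0))
        ]
        events = {s.clone_id: cc.simulate_clone(s, None, 5000, seed=rng)
                  for s in specs}
        pooled, labels = _pool(events, 5000)
        scape = cc.build_landscape(pooled, labels, 1.0, 0.01, policy="strict")
        masks = [scape.spread_masks[c] for c in scape.clone_ids]
        oracle_multi = np.zeros_like(masks[0])
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                oracle_multi |= masks[i] & masks[j]
        assert oracle_multi.any()  # 1% contours do touch
        # strict policy: exactly the multi-clone elements are unassigned
        covered = np.zeros_like(masks[0])
        for m in masks:
            covered |= m
        unassigned_covered = covered & (scape.assignment == -1)
        assert np.array_equal(unassigned_covered, oracle_multi)

    def test_zero_cell_clone_is_an_error(self, disjoint_landscape):
        _, pooled, labels = disjoint_landscape
        with pytest.raises(ValueError, match="align"):
            cc.build_landscape(pooled, labels[:-5], 1.0)


class TestAssign:
    def test_cell_at_mode_assigned_to_its_clone(self, disjoint_landscape):
        scape, _, _ = disjoint_landscape
        cell = point_mass_events(10, 10, n=1)
        assert cc.assign(cell, scape)[0] == "A"

    def test_out_of_bounds_chromaticity_unassigned(self, disjoint_landscape):
        scape, _, _ = disjoint_landscape
        far = point_mass_events(85, 40, n=1)
        zero = cc.ColorEvents.from_rgb([0], [0], [0])
        assert cc.assign(far, scape)[0] == UNASSIGNED
        assert cc.assign(zero, scape)[0] == UNASSIGNED

    def test_assignment_is_total(self, overlap_pair_landscape):
        scape, pooled, _ = overlap_pair_landscape
        labels = cc.assign(pooled, scape)
        assert len(labels) == pooled.n
        assert set(labels) <= set(scape.clone_ids) | {UNASSIGNED}

    def test_matches_element_lookup_oracle(self, overlap_pair_landscape):
        scape, pooled, _ = overlap_pair_landscape
        got = cc.assign(pooled, scape)
        res, n = scape.resolution_deg, scape.n_bins
        lut = {(i, j): scape.label_of_element(i, j)
               for i in range(n) for j in range(n)}
        for k in range(pooled.n):
            if pooled.value[k] == 0:
                assert got[k] == UNASSIGNED
                continue
            i = min(int(pooled.theta[k] / res), n - 1)
            j = min(int(pooled.phi[k] / res), n - 1)
            assert got[k] == lut[(i, j)]


class TestSpillover:
    def test_perfect_separation_gives_identity_and_zero_error(
            self, disjoint_landscape):
        scape, pooled, labels = disjoint_landscape
        ms = cc.spillover(scape, pooled, labels)
        assert np.allclose(ms.matrix[:, :3], np.eye(3))
        assert ms.error_range == (0.0, 0.0)
        assert np.allclose(ms.per_clone_unassigned, 0.0)

    def test_rows_are_stochastic(self, overlap_pair_landscape):
        scape, pooled, labels = overlap_pair_landscape
        ms = cc.spillover(scape, pooled, labels)
        assert np.allclose(ms.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((ms.matrix >= 0) & (ms.matrix <= 1))

    def test_engineered_overlap_matches_occupancy_oracle(
            self, overlap_pair_landscape):
        scape, pooled, labels = overlap_pair_landscape
        ms = cc.spillover(scape, pooled, labels)
        # shared element (31, 30): B majority (300 vs 100) -> element is B's;
        # A loses exactly its 100/1000 cells there, B loses nothing
        i, j = 31, 30
        assert scape.label_of_element(i, j) == "B"
        a_row = ms.clone_ids.index("A")
        b_row = ms.clone_ids.index("B")
        assert ms.matrix[a_row, b_row] == pytest.approx(0.1)
        assert ms.matrix[b_row, a_row] == 0.0
        assert ms.error_range == (pytest.approx(0.0), pytest.approx(0.1))

    def test_unknown_true_clone_is_an_error(self, disjoint_landscape):
        scape, pooled, labels = disjoint_landscape
        bad = labels.copy()
        bad[0] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            cc.spillover(scape, pooled, bad)


class TestComposition:
    def test_equal_pool_recovers_equal_frequencies(self, disjoint_landscape):
        scape, pooled, _ = disjoint_landscape
        comp = cc.composition(pooled, scape)
        for c in scape.clone_ids:
            assert comp.frequencies[c] == pytest.approx(100.0 / 3)
        assert comp.total() == pytest.approx(100.0, abs=1e-6)

    def test_all_unassigned_sample(self, disjoint_landscape):
        scape, _, _ = disjoint_landscape
        comp = cc.composition(point_mass_events(85, 45, n=50), scape)
        assert comp.unassigned == 100.0
        assert all(v == 0.0 for v in comp.frequencies.values())

    def test_conservation_on_arbitrary_sample(self, overlap_pair_landscape):
        scape, pooled, _ = overlap_pair_landscape
        comp = cc.composition(pooled, scape)
        assert comp.total() == pytest.approx(100.0, abs=1e-6)

    def test_spillover_correction_recovers_true_frequencies(self):
        # three overlapping clones; forward-sample at (50, 30, 20)% and
        # invert the empirical spillover matrix
        rng = np.random.default_rng(21)
        specs = [
            cc.SyntheticCloneSpec(f"v{k}", (1, 1, 1),
                                  tuple(cc.spherical_to_rgb(t, 30, 2.0e4)),
                                  cell_scale_sigma=0.3, channel_noise_sigma=0.3)
            for k, t in enumerate((28.0, 45.0, 62.0))
        ]
        ref = {s.clone_id: cc.simulate_clone(s, None, 8000, seed=rng)
               for s in specs}
        pooled, labels = _pool(ref, 8000, seed=3)
        scape = cc.build_landscape(pooled, labels, 1.0, 0.01)
        ms = cc.spillover(scape, pooled, labels)
        assert ms.error_range[1] > 0.01  # overlap is material
        true = (0.5, 0.3, 0.2)
        sim = cc.simulate_pool(specs, true, 30_000, seed=7)
        sample, _ = sim[0.0]
        comp = cc.composition(sample, scape, ms)
        for c, t in zip([s.clone_id for s in specs], true):
            assert comp.corrected_frequencies[c] == pytest.approx(
                100 * t, abs=1.0)

    def test_empty_sample_is_an_error(self, disjoint_landscape):
        scape, _, _ = disjoint_landscape
        with pytest.raises(ValueError, match="empty"):
            cc.composition(cc.ColorEvents.from_rgb([], [], []), scape)


@pytest.fixture(scope="module")
def noisy_landscape():
    """Five separated noisy clones on a 0.5° grid, for drift and tracking."""
    rng = np.random.default_rng(31)
    specs = [
        cc.SyntheticCloneSpec(f"t{k}", (1, 1, 1),
                              tuple(cc.spherical_to_rgb(t, p, 2.0e4)),
                              cell_scale_sigma=0.3, channel_noise_sigma=0.08)
        for k, (t, p) in enumerate([(12, 15), (45, 15), (78, 15),
                                    (25, 55), (65, 55)])
    ]
    events = {s.clone_id: cc.simulate_clone(s, None, 4000, seed=rng)
              for s in specs}
    pooled, labels = _pool(events, 4000)
    scape = cc.build_landscape(pooled, labels, 0.5, 0.01)
    return specs, scape, pooled


class TestDriftCorrect:
    def test_zero_drift_yields_near_identity(self, noisy_landscape):
        _, scape, pooled = noisy_landscape
        corrected, report = cc.drift_correct(pooled, scape)
        assert not report.identity
        assert report.n_matched >= 3
        assert np.max(np.abs(corrected.theta - pooled.theta)) < 1.0
        assert np.allclose(report.matrix, np.eye(2), atol=0.05)

    def test_known_theta_shift_recovered(self, noisy_landscape):
        _, scape, pooled = noisy_landscape
        shifted = cc.ColorEvents.from_spherical(
            np.clip(pooled.theta + 1.0, 0, 90), pooled.phi, pooled.value)
        corrected, report = cc.drift_correct(shifted, scape)
        mean_shift = np.mean(corrected.theta - shifted.theta)
        assert mean_shift == pytest.approx(-1.0, abs=0.2)

    def test_idempotence_within_grid_resolution(self, noisy_landscape):
        _, scape, pooled = noisy_landscape
        once, _ = cc.drift_correct(pooled, scape)
        twice, _ = cc.drift_correct(once, scape)
        assert np.max(np.abs(twice.theta - once.theta)) < scape.resolution_deg
        assert np.max(np.abs(twice.phi - once.phi)) < scape.resolution_deg

    def test_too_few_peaks_falls_back_to_identity(self, noisy_landscape):
        _, scape, _ = noisy_landscape
        lone = point_mass_events(12, 15, n=1000)
        with pytest.warns(UserWarning, match="identity"):
            corrected, report = cc.drift_correct(lone, scape)
        assert report.identity
        assert np.array_equal(corrected.theta, lone.theta)

    def test_values_unchanged(self, noisy_landscape):
        _, scape, pooled = noisy_landscape
        corrected, _ = cc.drift_correct(pooled, scape)
        assert np.allclose(corrected.value, pooled.value)


class TestPolicies:
    def test_strict_abstains_at_least_as_often_as_majority(self):
        rng = np.random.default_rng(13)
        specs = [
            cc.SyntheticCloneSpec(f"p{k}", (1, 1, 1),
                                  tuple(cc.spherical_to_rgb(t, 30, 2.0e4)),
                                  cell_scale_sigma=0.3, channel_noise_sigma=0.25)
            for k, t in enumerate((35.0, 50.0))
        ]
        events = {s.clone_id: cc.simulate_clone(s, None, 4000, seed=rng)
                  for s in specs}
        pooled, labels = _pool(events, 4000)
        strict = cc.build_landscape(pooled, labels, 1.0, 0.01, policy="strict")
        major = cc.build_landscape(pooled, labels, 1.0, 0.01, policy="majority")
        u_strict = (cc.assign(pooled, strict) == UNASSIGNED).mean()
        u_major = (cc.assign(pooled, major) == UNASSIGNED).mean()
        assert u_strict >= u_major
        # strict only ever assigns elements covered by exactly one spread
        cover = np.zeros_like(strict.assignment)
        for m in strict.spread_masks.values():
            cover += m
        assert np.all(cover[strict.assignment >= 0] == 1)


class TestTrack:
    def test_single_sample_sd_flagged(self, noisy_landscape):
        _, scape, pooled = noisy_landscape
        comps, series = cc.track([(0.0, pooled)], scape)
        assert len(comps) == 1
        assert (series["n_samples"] == 1).all()
        assert series["sd_pct"].isna().all()

    def test_identical_replicates_have_zero_sd(self, noisy_landscape):
        _, scape, pooled = noisy_landscape
        comps, series = cc.track([(0.0, pooled)] * 6, scape)
        assert len(comps) == 6
        assert np.allclose(series["sd_pct"], 0.0)

    def test_growth_trajectories_match_exponential_competition(
            self, noisy_landscape):
        specs, scape, _ = noisy_landscape
        growth = [0.25, 0.10, 0.0, -0.10, -0.25]
        f0 = [0.2] * 5
        timepoints = [0.0, 2.0, 4.0, 6.0]
        sim = cc.simulate_pool(specs, f0, 20_000, growth_rates=growth,
                               timepoints=timepoints, seed=71)
        samples = [(t, ev) for t, (ev, _l) in sorted(sim.items())]
        _, series = cc.track(samples, scape)
        for t in timepoints:
            analytic = cc.competition_frequencies(f0, growth, t)
            for s, f_true in zip(specs, analytic):
                got = series[(series.timepoint == t)
                             & (series.clone_id == s.clone_id)].mean_pct.item()
                assert got == pytest.approx(100 * f_true, abs=2.0)

    def test_empty_sample_list_is_an_error(self, noisy_landscape):
        _, scape, _ = noisy_landscape
        with pytest.raises(ValueError, match="no samples"):
            cc.track([], scape)
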