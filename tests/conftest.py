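"""Shared fixtures: small synthetic populations and reference objects.

All fixtures are generated programmatically with fixed seeds; coarse grid
resolutions (0.5°–3°) keep the suite fast while exercising the same code
paths as the default 0.2° grid.
"""

import numpy as np
import pytest

import clonechroma as cc


@pytest.fixture(scope="session")
def af_spec():
    return cc.AFSpec()


@pytest.fixture(scope="session")
def af_reference(af_spec):
    events = cc.simulate_af(af_spec, 10_000, seed=123)
    return cc.xaf_unit(events, resolution_deg=1.0)


def point_mass_events(theta, phi, n=100, value=1000.0):
    """Deterministic events all at one chromaticity coordinate."""
    return cc.ColorEvents.from_spherical(
        np.full(n, float(theta)), np.full(n, float(phi)), np.full(n, value)
    )


@pytest.fixture(scope="session")
def corner_profiles():
    """Five well-separated point-mass clones on a 1° grid."""
    coords = [(5, 5), (85, 5), (45, 85), (45, 45), (10, 60)]
    return {
        f"K{k}": cc.clone_profile(f"K{k}", point_mass_events(t, p), 1.0)
        for k, (t, p) in enumerate(coords)
    }


@pytest.fixture(scope="session")
def noisy_pair():
    """Two overlapping lognormal clones on a 1° grid (fixed seed)."""
    rng = np.random.default_rng(42)
    specs = [
        cc.SyntheticCloneSpec("A", (1, 1, 1), tuple(cc.spherical_to_rgb(35, 30, 2.0e4)),
                              cell_scale_sigma=0.3, channel_noise_sigma=0.25),
        cc.SyntheticCloneSpec("B", (1, 1, 1), tuple(cc.spherical_to_rgb(50, 30, 2.0e4)),
                              cell_scale_sigma=0.3, channel_noise_sigma=0.25),
    ]
    events = {s.clone_id: cc.simulate_clone(s, None, 6000, seed=rng) for s in specs}
    return specs, events
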