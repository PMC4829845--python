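"""End-to-end pipeline: triage → pool design → landscape → assignment → tracking.

The pipeline mirrors the three-step tracking strategy: (1) establish a
consistent color space over a diversely color-coded population, (2) triage
individual clones by relative clonal brightness and chromatic stability,
(3) select a chromatically distinguishable subset, pool it, build the
chromatic landscape and follow clonal composition over time with a known
spillover matrix.

Inputs are either measured per-clone event files or a synthetic *scenario*
(see :mod:`clonechroma.synthdata`); every artifact is written alongside a
manifest recording the inputs, configuration hash and package version so a
run can be reproduced byte for byte.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .io import landscape_to_json, spillover_to_csv, write_events_csv
from .landscape import build_landscape, spillover, track
from .metrics import chromatic_stability, clone_profile, xaf_unit
from .pooldesign import digital_pool, select_subset, triage
from .synthdata import (
    AFSpec,
    SyntheticCloneSpec,
    reference_panel,
    simulate_af,
    simulate_clone,
    simulate_pool,
)

__all__ = ["run_pipeline", "scenario_specs"]


def scenario_specs(scenario: dict) -> tuple[list[SyntheticCloneSpec], AFSpec]:
    """Clone specs + AF spec from a scenario mapping (YAML/JSON-friendly)."""
    af = AFSpec(**scenario.get("af", {}))
    if "panel" in scenario:
        specs = reference_panel(**scenario["panel"])
    elif "clones" in scenario:
        specs = []
        for c in scenario["clones"]:
            c = dict(c)
            c["copies"] = tuple(c["copies"])
            c["brightness"] = tuple(c["brightness"])
            if "drift" in c:
                c["drift"] = tuple(c["drift"])
            specs.append(SyntheticCloneSpec(**c))
    else:
        raise ValueError("scenario needs a 'panel' or a 'clones' entry")
    return specs, af


def run_pipeline(config: RunConfig, scenario: dict, out_dir=None) -> dict:
    """Run the full synthetic-scenario pipeline and write all artifacts.

    Stages (each aborts with its name on error): simulate → profile/triage
    → subset selection → digital pooling → landscape + spillover → tracking.
    Returns a report dict with the in-memory results and written paths.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"stages": [], "outputs": {}}

    def stage(name):
        report["stages"].append(name)

    try:
        stage("simulate")
        specs, af_spec = scenario_specs(scenario)
        n_ref = int(scenario.get("n_cells_per_clone", 5000))
        ref_timepoints = list(scenario.get("reference_timepoints", [0.0, 1.0, 2.0]))
        af_events = simulate_af(af_spec, int(scenario.get("n_af_cells", 10_000)),
                                seed=rng, scale_max=config.scale_max)
        clone_events = {
            s.clone_id: {
                t: simulate_clone(s, af_spec, n_ref, timepoint=t, seed=rng,
                                  scale_max=config.scale_max)
                for t in ref_timepoints
            }
            for s in specs
        }

        stage("profile")
        ref = xaf_unit(af_events, config.resolution_deg)
        profiles, stability_reports = {}, {}
        for cid, by_t in clone_events.items():
            per_t = [
                clone_profile(cid, ev, config.resolution_deg, config.fractions,
                              ref=ref, b_star=config.b_star, timepoint=t)
                for t, ev in by_t.items()
            ]
            profiles[cid] = per_t[0]
            stability_reports[cid] = chromatic_stability(
                per_t, config.stability_fraction
            )

        stage("triage")
        pool = triage(profiles, stability_reports,
                      brightness_cutoff=config.brightness_cutoff,
                      stability_rule=config.stability_rule)
        manifest_df = pool.manifest()
        manifest_path = out / "pool_manifest.csv"
        manifest_df.to_csv(manifest_path, index=False, float_format="%.9g")
        report["outputs"]["pool_manifest"] = str(manifest_path)

        stage("select")
        target_n = int(scenario.get("target_n", len(pool.admitted)))
        selected = select_subset(pool, target_n)
        cells_per_clone = int(scenario.get("cells_per_clone_pool", n_ref))
        design_path = out / "pool_design.json"
        design_path.write_text(json.dumps({
            "selected_clones": selected,
            "cells_per_clone": cells_per_clone,
            "seed": config.seed,
        }, indent=2))
        report["outputs"]["pool_design"] = str(design_path)

        stage("pool")
        t0 = ref_timepoints[0]
        pooled, labels = digital_pool(
            {c: clone_events[c][t0] for c in selected},
            cells_per_clone, seed=rng,
        )

        stage("landscape")
        scape = build_landscape(
            pooled, labels, config.resolution_deg,
            config.landscape_fraction, config.policy, config.majority_threshold,
        )
        ms = spillover(scape, pooled, labels)
        scape_path = out / "landscape.json"
        ms_path = out / "spillover.csv"
        landscape_to_json(scape, scape_path)
        spillover_to_csv(ms, ms_path)
        report["outputs"]["landscape"] = str(scape_path)
        report["outputs"]["spillover"] = str(ms_path)

        stage("track")
        track_cfg = scenario.get("track", {})
        k = len(selected)
        sel_specs = [s for s in specs if s.clone_id in selected]
        sel_idx = [i for i, s in enumerate(specs) if s.clone_id in selected]
        freqs = track_cfg.get("frequencies")
        if freqs is None:
            freqs = [1.0 / k] * k
        elif len(freqs) == len(specs) and k < len(specs):
            # scenario lists one entry per candidate clone; keep the selected
            sub = np.array([freqs[i] for i in sel_idx], dtype=float)
            freqs = (sub / sub.sum()).tolist()
        growth = track_cfg.get("growth_rates")
        if growth is not None and len(growth) == len(specs) and k < len(specs):
            growth = [growth[i] for i in sel_idx]
        t_track = list(track_cfg.get("timepoints", [0.0]))
        n_track = int(track_cfg.get("n_cells", 10 * k))
        n_rep = int(track_cfg.get("n_replicates", 1))
        samples = []
        for _ in range(n_rep):
            sim = simulate_pool(sel_specs, freqs, n_track, growth_rates=growth,
                                timepoints=t_track, af=af_spec, seed=rng,
                                scale_max=config.scale_max)
            samples.extend((t, ev) for t, (ev, _lab) in sorted(sim.items()))
        comps, series = track(samples, scape, ms)
        comp_rows = []
        for c in comps:
            row = {"sample_id": c.sample_id, "timepoint": c.timepoint,
                   "n_cells": c.n_cells, "unassigned_pct": c.unassigned}
            row.update({f"{cid}_pct": v for cid, v in c.frequencies.items()})
            comp_rows.append(row)
        comp_path = out / "composition.csv"
        series_path = out / "track_timeseries.csv"
        pd.DataFrame(comp_rows).to_csv(comp_path, index=False, float_format="%.9g")
        series.to_csv(series_path, index=False, float_format="%.9g")
        report["outputs"]["composition"] = str(comp_path)
        report["outputs"]["track_timeseries"] = str(series_path)

        af_path = out / "af_events.csv"
        write_events_csv(af_events, af_path)
        report["outputs"]["af_events"] = str(af_path)

        stage("manifest")
        run_manifest = {
            "package": "clonechroma",
            "version": __version__,
            "python": platform.python_version(),
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "scenario": scenario,
            "n_admitted": len(pool.admitted),
            "n_selected": len(selected),
            "spillover_error_range_pct": [100 * e for e in ms.error_range],
        }
        (out / "manifest.json").write_text(json.dumps(run_manifest, indent=2))
        report["outputs"]["manifest"] = str(out / "manifest.json")
    except Exception as err:
        failed = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage '{failed}': {err}") from err

    report.update(
        pool=pool, selected=selected, landscape=scape, spillover=ms,
        compositions=comps, timeseries=series, af_reference=ref,
    )
    return report
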