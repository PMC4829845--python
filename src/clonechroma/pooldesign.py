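"""Candidate-clone triage and selection of mutually distinguishable pools.

Building a clonally trackable population proceeds in two steps.  First,
clones unsuited to long-term tracking are *triaged* out: a clone must be
bright enough that autofluorescence cannot distort its color (relative
clonal brightness ≥ cutoff, default 0.975 at b* = 20) and its color must be
stable over time (chromatic stability not an outlier within the cohort).
Second, among the admitted candidates, a maximal subset of *mutually
distinguishable* clones is selected for physical pooling: two clones are
compatible when their chromatic modes fall in different grid elements and
their 50% isosurface chromatic spreads do not overlap.  Compatibility is a
graph; a pool is a clique.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .colorspace import ColorEvents
from .metrics import CloneColorProfile, StabilityReport

__all__ = [
    "CandidatePool",
    "triage",
    "compatibility",
    "compatibility_graph",
    "select_subset",
    "digital_pool",
]


@dataclass
class CandidatePool:
    """Triage outcome: admitted clones plus per-clone rejection reasons."""

    profiles: dict[str, CloneColorProfile]
    stability_reports: dict[str, StabilityReport]
    admitted: list[str]
    rejection_reasons: dict[str, list[str]]
    brightness_cutoff: float
    stability_rule: str
    stability_threshold: float

    def manifest(self):
        import pandas as pd

        rows = []
        for cid, prof in self.profiles.items():
            rows.append(
                {
                    "clone_id": cid,
                    "admitted": cid in self.admitted,
                    "relative_brightness": prof.relative_brightness,
                    "stability": self.stability_reports[cid].stability,
                    "reasons": ";".join(self.rejection_reasons.get(cid, [])),
                }
            )
        return pd.DataFrame(rows)


def triage(
    profiles: Mapping[str, CloneColorProfile],
    stability_reports: Mapping[str, StabilityReport],
    brightness_cutoff: float = 0.975,
    stability_rule: str = "iqr",
    zscore_limit: float = 3.0,
) -> CandidatePool:
    """Admit clones that are bright and chromatically stable.

    ``dim``: relative clonal brightness below ``brightness_cutoff`` (the
    default 0.975 requires ≥97.5% of a clone's cells above b*).
    ``unstable``: chromatic stability an outlier within the cohort — above
    the Tukey fence Q3 + 1.5·IQR (``stability_rule="iqr"``, default) or more
    than ``zscore_limit`` cohort standard deviations above the mean
    (``stability_rule="zscore"``).
    """
    if set(profiles) != set(stability_reports):
        raise ValueError("profiles and stability_reports must be keyed identically")
    ids = sorted(profiles)
    stabilities = np.array([stability_reports[c].stability for c in ids])
    if stability_rule == "iqr":
        if len(ids) < 4:
            raise ValueError(
                "IQR outlier rule needs a cohort of at least 4 clones"
            )
        q1, q3 = np.percentile(stabilities, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
    elif stability_rule == "zscore":
        fence = stabilities.mean() + zscore_limit * stabilities.std(ddof=1)
    else:
        raise ValueError(f"unknown stability_rule {stability_rule!r}")

    admitted, reasons = [], {}
    for cid, stab in zip(ids, stabilities):
        prof = profiles[cid]
        if prof.relative_brightness is None:
            raise ValueError(
                f"clone {cid} has no relative_brightness; profile it against "
                "an AF reference first"
            )
        why = []
        if prof.relative_brightness < brightness_cutoff:
            why.append("dim")
        if stab > fence:
            why.append("unstable")
        if why:
            reasons[cid] = why
        else:
            admitted.append(cid)
    return CandidatePool(
        profiles=dict(profiles),
        stability_reports=dict(stability_reports),
        admitted=admitted,
        rejection_reasons=reasons,
        brightness_cutoff=brightness_cutoff,
        stability_rule=stability_rule,
        stability_threshold=float(fence),
    )


def compatibility(a: CloneColorProfile, b: CloneColorProfile) -> bool:
    """True when two clones are mutually distinguishable: different chromatic
    mode elements AND disjoint 50% isosurface spreads."""
    if a.grid.resolution_deg != b.grid.resolution_deg:
        raise ValueError(
            "profiles were built at different grid resolutions "
            f"({a.grid.resolution_deg}° vs {b.grid.resolution_deg}°)"
        )
    if a.mode.element == b.mode.element:
        return False
    return not a.spread(0.50).overlaps(b.spread(0.50))


def compatibility_graph(profiles: Mapping[str, CloneColorProfile]) -> nx.Graph:
    """Undirected graph with an edge for every distinguishable clone pair."""
    g = nx.Graph()
    g.add_nodes_from(profiles)
    for a, b in itertools.combinations(profiles, 2):
        if compatibility(profiles[a], profiles[b]):
            g.add_edge(a, b)
    return g


def select_subset(
    pool: CandidatePool | Mapping[str, CloneColorProfile],
    target_n: int,
    exact_limit: int = 25,
) -> list[str]:
    """Select a mutually compatible clone subset (a clique) of size ≥ target_n.

    A greedy max-degree heuristic runs first; if it falls short and the
    admitted cohort is small (≤ ``exact_limit``), an exact maximum-clique
    search is used.  If no clique of the target size exists, the largest
    clique found is returned with a warning.  Deterministic for a given
    input ordering.
    """
    if isinstance(pool, CandidatePool):
        profiles = {c: pool.profiles[c] for c in pool.admitted}
    else:
        profiles = dict(pool)
    if not profiles:
        raise ValueError("no admitted clones to select from")
    graph = compatibility_graph(profiles)
    order = {c: k for k, c in enumerate(profiles)}
    best = select_clique(graph, order, target_n, exact_limit)
    if len(best) < target_n:
        warnings.warn(
            f"no mutually compatible subset of size {target_n}; "
            f"returning the largest found ({len(best)} clones)",
            stacklevel=2,
        )
    return best


def select_clique(
    graph: nx.Graph,
    order: Mapping[str, int] | None = None,
    target_n: int = 0,
    exact_limit: int = 25,
) -> list:
    """Clique search on an arbitrary compatibility graph.

    Greedy max-degree first; exact maximum-clique fallback when the greedy
    result misses ``target_n`` and the graph is small enough.
    """
    if order is None:
        order = {c: k for k, c in enumerate(graph.nodes)}
    best = _greedy_clique(graph, order)
    if len(best) < target_n and graph.number_of_nodes() <= exact_limit:
        exact, _ = nx.max_weight_clique(graph, weight=None)
        if len(exact) > len(best):
            best = sorted(exact, key=order.__getitem__)
    return best


def _greedy_clique(graph: nx.Graph, order: Mapping[str, int]) -> list[str]:
    # repeatedly take the highest-degree node among remaining candidates,
    # ties broken by input order
    candidates = set(graph.nodes)
    clique: list[str] = []
    while candidates:
        pick = max(
            candidates,
            key=lambda c: (sum(1 for x in candidates if graph.has_edge(c, x)),
                           -order[c]),
        )
        clique.append(pick)
        candidates = {c for c in candidates if graph.has_edge(pick, c)}
    return sorted(clique, key=order.__getitem__)


def digital_pool(
    profiles: Mapping[str, CloneColorProfile] | Mapping[str, ColorEvents],
    cells_per_clone: int,
    seed=None,
    clone_ids: Sequence[str] | None = None,
) -> tuple[ColorEvents, np.ndarray]:
    """Pool clones *in silico* at equal representation.

    Subsamples ``cells_per_clone`` events without replacement from each
    clone (with replacement, flagged by a warning, if a clone has fewer).
    Returns the concatenated events and an aligned object array of
    true-clone labels, the input for landscape construction and for
    spillover estimation.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = list(clone_ids) if clone_ids is not None else list(profiles)
    parts, labels = [], []
    for cid in ids:
        obj = profiles[cid]
        events = obj.events if isinstance(obj, CloneColorProfile) else obj
        if events.n >= cells_per_clone:
            idx = rng.choice(events.n, size=cells_per_clone, replace=False)
        else:
            warnings.warn(
                f"clone {cid}: only {events.n} events for "
                f"{cells_per_clone} requested; resampling with replacement",
                stacklevel=2,
            )
            idx = rng.choice(events.n, size=cells_per_clone, replace=True)
        parts.append(events.subset(np.sort(idx)))
        labels.extend([cid] * cells_per_clone)
    return ColorEvents.concatenate(parts), np.array(labels, dtype=object)
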