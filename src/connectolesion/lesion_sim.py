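"""Computational lesion model on weighted Watts-Strogatz networks.

A focal subcortical lesion predominantly transects long white-matter
tracts.  This module emulates that mechanism on the canonical small-world
generator: weighted ring lattices (n = 41 nodes, matching one hemisphere;
mean degree k = 10; rewiring probability P = 0.25) are 'lesioned' by
deleting a proportion q of their long-range connections, and the intact
and lesioned arms are compared on null-normalised global efficiency and
clustering plus modularity — the same normalisation as the empirical
analysis (degree-, strength- and weight-preserving random networks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import NullEnsembleSpec, modularity, normalized_global_metrics

__all__ = [
    "WSConfig",
    "LesionSimConfig",
    "WSNetwork",
    "ws_generate",
    "lesion_long_range",
    "run_experiment",
]


@dataclass(frozen=True)
class WSConfig:
    """Watts-Strogatz generator parameters.

    ``weight_scheme='distance_decay'`` weights a lattice edge of ring
    offset d by 1/d; a rewired shortcut keeps the weight of the lattice
    slot it replaced.  ``uniform`` gives unit weights.
    """

    n_nodes: int = 41
    k: int = 10  # desired mean degree (even)
    rewire_p: float = 0.25
    weight_scheme: str = "distance_decay"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 != 0 or not 0 < self.k < self.n_nodes:
            raise ValueError("k must be even and 0 < k < n_nodes")
        if not 0 <= self.rewire_p <= 1:
            raise ValueError("rewire_p must lie in [0, 1]")
        if self.weight_scheme not in ("uniform", "distance_decay"):
            raise ValueError("weight_scheme must be 'uniform' or 'distance_decay'")


@dataclass(frozen=True)
class LesionSimConfig:
    """Long-range lesioning experiment parameters.

    Long-range edges are those whose endpoints are more than
    ``long_range_cutoff`` apart on the ring (default k/2, i.e. beyond the
    lattice neighbourhood, which captures rewired shortcuts and nothing
    of the intact lattice); a fraction ``q`` of them is deleted.
    """

    n_intact: int = 21
    n_lesioned: int = 17
    removal_q: float = 0.5
    long_range_cutoff: int | None = None  # default: k // 2
    n_nulls: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.removal_q <= 1:
            raise ValueError("removal_q must lie in [0, 1]")


@dataclass
class WSNetwork:
    """A weighted Watts-Strogatz realization with its ring geometry."""

    weights: np.ndarray = field(repr=False)
    ring_distance: np.ndarray = field(repr=False)  # realized ring distance per pair
    config: WSConfig

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)


def _ring_dist(i: np.ndarray | int, j: np.ndarray | int, n: int):
    d = np.abs(np.asarray(i) - np.asarray(j))
    return np.minimum(d, n - d)


def ws_generate(cfg: WSConfig) -> WSNetwork:
    """One weighted Watts-Strogatz realization.

    Ring lattice with k/2 neighbours per side; each lattice edge (i, i+d)
    is rewired with probability ``rewire_p`` to (i, j) with j uniform over
    nodes that avoid self-loops and duplicate edges.  Rewiring moves
    edges, never deletes them, so the edge count is exactly n*k/2.
    """
    rng = np.random.default_rng(cfg.seed)
    n, half_k = cfg.n_nodes, cfg.k // 2
    edges: dict[tuple[int, int], float] = {}

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    slot_weight = {
        d: (1.0 / d if cfg.weight_scheme == "distance_decay" else 1.0)
        for d in range(1, half_k + 1)
    }
    for d in range(1, half_k + 1):
        for i in range(n):
            edges[key(i, (i + d) % n)] = slot_weight[d]
    # rewire pass: lattice slot order, as in the original construction
    for d in range(1, half_k + 1):
        for i in range(n):
            old = key(i, (i + d) % n)
            if old not in edges:
                continue  # already moved by an earlier rewiring step
            if rng.random() < cfg.rewire_p:
                for _ in range(100):
                    j = int(rng.integers(n))
                    new = key(i, j)
                    if j != i and new not in edges:
                        w = edges.pop(old)
                        edges[new] = w
                        break

    w = np.zeros((n, n))
    for (a, b), wt in edges.items():
        w[a, b] = w[b, a] = wt
    idx = np.arange(n)
    ring = _ring_dist(idx[:, None], idx[None, :], n)
    return WSNetwork(weights=w, ring_distance=ring, config=cfg)


def lesion_long_range(
    net: WSNetwork, cfg: LesionSimConfig, seed: int = 0
) -> WSNetwork:
    """Delete round(q * count) long-range edges uniformly at random.

    An edge is long-range when the realized ring distance of its
    endpoints exceeds the cutoff (default k/2); short-range edges are
    never touched.
    """
    cutoff = cfg.long_range_cutoff if cfg.long_range_cutoff is not None else net.config.k // 2
    w = net.weights.copy()
    iu = np.triu_indices(w.shape[0], k=1)
    present = w[iu] > 0
    longr = present & (net.ring_distance[iu] > cutoff)
    candidates = np.flatnonzero(longr)
    if len(candidates) == 0:
        warnings.warn("no long-range edges to lesion; returning a copy")
        return WSNetwork(weights=w, ring_distance=net.ring_distance, config=net.config)
    n_remove = int(np.floor(cfg.removal_q * len(candidates) + 0.5))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_remove, replace=False)
    rows, cols = iu[0][chosen], iu[1][chosen]
    w[rows, cols] = 0.0
    w[cols, rows] = 0.0
    return WSNetwork(weights=w, ring_distance=net.ring_distance, config=net.config)


def run_experiment(
    ws: WSConfig = WSConfig(),
    lesion: LesionSimConfig = LesionSimConfig(),
    seed: int = 0,
    modularity_restarts: int = 10,
) -> dict:
    """Generate intact and lesioned arms and compare their global
    graph parameters.

    Returns a dict with a per-realization table (columns: realization,
    arm, efficiency_norm, clustering_norm, modularity) and Welch t-test
    group comparisons per metric.
    """
    rows = []
    n_total = lesion.n_intact + lesion.n_lesioned
    for r in range(n_total):
        arm = "intact" if r < lesion.n_intact else "lesioned"
        net = ws_generate(
            WSConfig(
                n_nodes=ws.n_nodes,
                k=ws.k,
                rewire_p=ws.rewire_p,
                weight_scheme=ws.weight_scheme,
                seed=seed * 100000 + r,
            )
        )
        if arm == "lesioned":
            net = lesion_long_range(net, lesion, seed=seed * 100000 + 50000 + r)
        spec = NullEnsembleSpec(n_nulls=lesion.n_nulls, seed=seed * 100000 + r)
        nm = normalized_global_metrics(net.weights, spec)
        qmod, _ = modularity(
            net.weights, n_restarts=modularity_restarts, seed=seed * 100000 + r
        )
        rows.append(
            {
                "realization": r,
                "arm": arm,
                "efficiency_norm": nm["efficiency_norm"],
                "clustering_norm": nm["clustering_norm"],
                "modularity": qmod,
            }
        )
    table = pd.DataFrame(rows)
    tests = {}
    for metric in ("efficiency_norm", "clustering_norm", "modularity"):
        a = table.loc[table["arm"] == "lesioned", metric]
        b = table.loc[table["arm"] == "intact", metric]
        t = sps.ttest_ind(a, b, equal_var=False)
        tests[metric] = {
            "lesioned_mean": float(a.mean()),
            "intact_mean": float(b.mean()),
            "difference": float(a.mean() - b.mean()),
            "t": float(t.statistic),
            "p": float(t.pvalue),
        }
    return {"table": table, "tests": tests}
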