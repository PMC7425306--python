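"""Global and local graph parameters for weighted brain networks.

Conventions follow the Brain Connectivity Toolbox:

* **q50** — median of the nonzero upper-triangle edge weights (median
  connectivity strength).
* **Global efficiency** — mean over ordered node pairs of the inverse
  weighted shortest-path distance, with edge lengths 1/weight; pairs in
  different components contribute 0.
* **Clustering** — mean Onnela weighted clustering coefficient, with
  weights scaled by the network-wide maximum; nodes of degree < 2
  contribute 0.
* **Modularity** — weighted Newman-Girvan Q maximised by Louvain with
  seeded restarts.

Raw efficiency and clustering confound topology with overall connection
strength, so they are normalised against an ensemble of random null
networks that preserve the degree sequence exactly (Maslov-Sneppen double
edge swaps), the edge-weight multiset exactly (a permutation of the
original weights), and the node-strength sequence approximately
(greedy rank-matched weight placement).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import Connectome, apply_mask, density_mask

__all__ = [
    "GlobalMetrics",
    "NullEnsembleSpec",
    "DensitySweep",
    "q50",
    "node_strength",
    "global_efficiency",
    "clustering",
    "modularity",
    "null_ensemble",
    "normalize",
    "normalized_global_metrics",
    "compute_all",
]


def _weights_of(c: Connectome | np.ndarray) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------

def q50(c: Connectome | np.ndarray) -> float:
    """Median connectivity strength: median over nonzero unordered edges."""
    w = _weights_of(c)
    iu = np.triu_indices(w.shape[0], k=1)
    vals = w[iu]
    vals = vals[vals > 0]
    if len(vals) == 0:
        raise ValueError("q50 undefined on an empty network")
    return float(np.median(vals))


def node_strength(c: Connectome | np.ndarray) -> np.ndarray:
    """Sum of edge weights incident to each node."""
    w = _weights_of(c)
    return w.sum(axis=1)


def global_efficiency(c: Connectome | np.ndarray) -> float:
    """Mean inverse weighted shortest-path length over ordered node pairs."""
    w = _weights_of(c)
    n = w.shape[0]
    if n < 2:
        return 0.0
    rows, cols = np.nonzero(np.triu(w, k=1))
    if len(rows) == 0:
        return 0.0
    lengths = 1.0 / w[rows, cols]
    graph = csr_matrix((lengths, (rows, cols)), shape=(n, n))
    d = shortest_path(graph, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def clustering(c: Connectome | np.ndarray) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are scaled by the network maximum; per node,
    ``c_i = sum_{j,k} (w_ij w_ik w_jk)^(1/3) / (k_i (k_i - 1))`` where the
    sum runs over ordered neighbour pairs.  Nodes with fewer than two
    neighbours contribute 0 to the mean.
    """
    w = _weights_of(c)
    n = w.shape[0]
    if n == 0:
        return 0.0
    wmax = w.max()
    if wmax == 0:
        return 0.0
    what = np.cbrt(w / wmax)
    cyc = np.diag(what @ what @ what)  # 2x number of weighted triangles per node
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    coef = np.zeros(n)
    mask = denom > 0
    coef[mask] = cyc[mask] / denom[mask]
    return float(coef.mean())


def _with_igraph_seed(seed: int | None):
    if seed is not None:
        ig.set_random_number_generator(random.Random(seed))


def _to_igraph(w: np.ndarray) -> tuple[ig.Graph, np.ndarray]:
    rows, cols = np.nonzero(np.triu(w, k=1))
    g = ig.Graph(n=w.shape[0], edges=list(zip(rows.tolist(), cols.tolist())))
    return g, w[rows, cols]


def _q_of(w: np.ndarray, membership: np.ndarray, gamma: float) -> float:
    """Weighted Newman-Girvan quality of a partition."""
    w2 = w.sum()
    q = 0.0
    for comm in np.unique(membership):
        idx = membership == comm
        e = w[np.ix_(idx, idx)].sum() / w2
        a = w[idx].sum() / w2
        q += e - gamma * a * a
    return q


def _refine_partition(
    w: np.ndarray, membership: np.ndarray, gamma: float
) -> tuple[float, np.ndarray]:
    """Greedy single-node moves (including to a fresh singleton) until no
    move improves Q; a local-optimum polish after each Louvain restart.

    Uses the incremental dQ of moving node v from community a to b:
    2(k_vb - k_va)/W - 2 gamma k_v (S_b - (S_a - k_v))/W^2, with W the
    total ordered-pair weight, k_vc the weight from v into c and S_c the
    community strength sum.
    """
    memb = membership.copy()
    n = w.shape[0]
    w2 = w.sum()
    k = w.sum(axis=1)
    improved = True
    while improved:
        improved = False
        for v in range(n):
            a = memb[v]
            n_slots = memb.max() + 2  # existing communities + one empty slot
            kvc = np.bincount(memb, weights=w[v], minlength=n_slots)
            sig = np.bincount(memb, weights=k, minlength=n_slots)
            sig_a_ex = sig[a] - k[v]
            dq = 2 * (kvc - kvc[a]) / w2 - gamma * 2 * k[v] * (
                sig - sig_a_ex
            ) / w2**2
            dq[a] = 0.0
            # the empty slot has kvc = 0, sig = 0 (singleton move)
            dq[n_slots - 1] = -2 * kvc[a] / w2 - gamma * 2 * k[v] * (
                -sig_a_ex
            ) / w2**2
            best = int(np.argmax(dq))
            if dq[best] > 1e-13:
                memb[v] = best
                improved = True
    _, memb = np.unique(memb, return_inverse=True)
    return _q_of(w, memb, gamma), memb


def modularity(
    c: Connectome | np.ndarray,
    gamma: float = 1.0,
    n_restarts: int = 20,
    seed: int | None = 0,
) -> tuple[float, np.ndarray]:
    """Best weighted Louvain modularity over seeded restarts.

    Each restart's partition is polished by greedy single-node moves to a
    local optimum of Q.  Returns ``(Q, membership)``; ``gamma`` is the
    resolution parameter of the generalised Newman-Girvan quality.
    """
    w = _weights_of(c)
    if w.sum() == 0:
        raise ValueError("modularity undefined on an empty network")
    g, ew = _to_igraph(w)
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        _with_igraph_seed(None if seed is None else seed + r)
        part = g.community_multilevel(weights=ew, resolution=gamma)
        starts = [np.asarray(part.membership)]
        # diversification: greedy refinement also from a random partition,
        # which escapes the multilevel pass's characteristic local optima
        starts.append(rng.integers(0, max(2, min(n // 2, 6)), n))
        for start in starts:
            qval, refined = _refine_partition(w, start, gamma)
            if qval > best_q:
                best_q, best_part = qval, refined
    # the trivial one-community partition is always admissible (Q = 0)
    if best_q < 0:
        best_q, best_part = 0.0, np.zeros(w.shape[0], dtype=int)
    return float(best_q), best_part


# ---------------------------------------------------------------------------
# Null ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullEnsembleSpec:
    """Configuration of the degree/strength/weight-preserving null ensemble.

    ``rewire_iterations`` scales the number of attempted double edge swaps
    (iterations x number of edges); ``assignment_chunks`` controls the
    greedy strength-matched weight placement granularity.
    """

    n_nulls: int = 1000
    rewire_iterations: int = 10
    seed: int = 0
    assignment_chunks: int = 100
    refine_sweeps: int = 10

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")


def _rank_matched_weights(
    edges: np.ndarray,
    sorted_weights: np.ndarray,
    target_strength: np.ndarray,
    n_chunks: int,
) -> np.ndarray:
    """Place a weight multiset on a fixed edge list so node strengths
    approximate a target sequence.

    Greedy descending assignment: edges are repeatedly ranked by the
    product of residual target strengths of their endpoints and the
    largest unassigned weights go to the top-ranked edges, a chunk at a
    time; residuals are updated after every chunk.
    """
    n_edges = len(edges)
    out = np.empty(n_edges)
    resid = target_strength.astype(float).copy()
    remaining = np.arange(n_edges)
    ptr = 0
    chunk = max(1, int(np.ceil(n_edges / n_chunks)))
    while len(remaining):
        i, j = edges[remaining, 0], edges[remaining, 1]
        score = resid[i] * resid[j]
        m = min(chunk, len(remaining))
        if m == len(remaining):
            top = np.arange(len(remaining))
        else:
            top = np.argpartition(-score, m - 1)[:m]
        # within the chunk, keep descending-score order for rank matching
        take = top[np.argsort(-score[top], kind="stable")]
        sel = remaining[take]
        w = sorted_weights[ptr : ptr + len(sel)]
        out[sel] = w
        np.add.at(resid, edges[sel, 0], -w)
        np.add.at(resid, edges[sel, 1], -w)
        ptr += len(sel)
        mask = np.ones(len(remaining), dtype=bool)
        mask[take] = False
        remaining = remaining[mask]
    return out


def _strength_swap_refine(
    edges: np.ndarray,
    ew: np.ndarray,
    target: np.ndarray,
    rng: np.random.Generator,
    n_sweeps: int = 10,
    tol: float = 0.02,
) -> np.ndarray:
    """Pairwise weight swaps that reduce the squared strength error.

    Polishes the greedy rank-matched placement: each sweep proposes one
    random exchange partner per edge and accepts swaps that lower
    ``sum((strength - target)^2)``.  Stops once the relative L2 strength
    error drops below ``tol`` (skipping entirely if the greedy placement
    is already that good) or when a sweep makes no improvement.
    """
    n_edges = len(edges)
    d = -target.astype(float).copy()
    np.add.at(d, edges[:, 0], ew)
    np.add.at(d, edges[:, 1], ew)
    norm2 = float(target @ target) or 1.0
    total = float(d @ d)
    if total / norm2 <= tol * tol:
        return ew
    n_nodes = len(target)
    for _ in range(n_sweeps):
        e = rng.permutation(n_edges)
        f = rng.integers(0, n_edges, n_edges)
        delta = ew[f] - ew[e]
        i, j = edges[e, 0], edges[e, 1]
        k, l = edges[f, 0], edges[f, 1]
        # shared endpoints cancel in both the linear and quadratic terms
        n_shared = (
            (i == k).astype(int) + (i == l) + (j == k) + (j == l)
        )
        de = 2 * delta * (d[i] + d[j] - d[k] - d[l]) + delta**2 * (4 - 2 * n_shared)
        improving = np.flatnonzero((e != f) & (delta != 0) & (de < -1e-15))
        if len(improving) == 0:
            break
        improving = improving[np.argsort(de[improving])]
        touched = np.zeros(n_nodes, dtype=bool)
        improved = False
        for idx in improving:
            a, b = e[idx], f[idx]
            nodes = (edges[a, 0], edges[a, 1], edges[b, 0], edges[b, 1])
            if any(touched[v] for v in nodes):
                continue  # stale dE once a neighbouring swap is accepted
            ew[a], ew[b] = ew[b], ew[a]
            dlt = delta[idx]
            d[edges[a, 0]] += dlt
            d[edges[a, 1]] += dlt
            d[edges[b, 0]] -= dlt
            d[edges[b, 1]] -= dlt
            for v in nodes:
                touched[v] = True
            total += de[idx]
            improved = True
        if not improved or total / norm2 <= tol * tol:
            break
    return ew


def null_ensemble(
    c: Connectome | np.ndarray, spec: NullEnsembleSpec
) -> list[np.ndarray]:
    """Random networks preserving degree sequence and weight multiset
    exactly and the strength sequence approximately.

    Each null: (1) Maslov-Sneppen double edge swaps on the binary
    topology, (2) greedy rank-matched placement of the original weight
    multiset on the rewired edges.
    """
    w = _weights_of(c)
    n = w.shape[0]
    rows, cols = np.nonzero(np.triu(w, k=1))
    n_edges = len(rows)
    if n_edges < 2:
        warnings.warn("network has < 2 edges; null ensemble returns copies")
        return [w.copy() for _ in range(spec.n_nulls)]
    weights_desc = np.sort(w[rows, cols])[::-1]
    strength = w.sum(axis=1)
    base = ig.Graph(n=n, edges=list(zip(rows.tolist(), cols.tolist())))
    nulls = []
    for r in range(spec.n_nulls):
        g = base.copy()
        _with_igraph_seed(spec.seed + r)
        g.rewire(n=spec.rewire_iterations * n_edges, mode="simple")
        edges = np.asarray(g.get_edgelist(), dtype=int)
        ew = _rank_matched_weights(
            edges, weights_desc, strength, spec.assignment_chunks
        )
        ew = _strength_swap_refine(
            edges, ew, strength,
            np.random.default_rng([spec.seed, r]),
            n_sweeps=spec.refine_sweeps,
        )
        m = np.zeros((n, n))
        m[edges[:, 0], edges[:, 1]] = ew
        m += m.T
        nulls.append(m)
    return nulls


def normalize(metric_value: float, null_values: np.ndarray | list[float]) -> float:
    """Ratio of an observed metric to the mean of its null distribution."""
    null_values = np.asarray(null_values, dtype=float)
    if len(null_values) == 0:
        raise ValueError("null value list is empty")
    mu = null_values.mean()
    if mu == 0:
        raise ValueError("null mean is zero; normalized metric undefined")
    return float(metric_value / mu)


def normalized_global_metrics(
    c: Connectome | np.ndarray, spec: NullEnsembleSpec
) -> dict[str, float]:
    """Raw and null-normalised efficiency and clustering of one network."""
    w = _weights_of(c)
    e_raw = global_efficiency(w)
    c_raw = clustering(w)
    nulls = null_ensemble(w, spec)
    e_null = np.array([global_efficiency(m) for m in nulls])
    c_null = np.array([clustering(m) for m in nulls])
    return {
        "efficiency_raw": e_raw,
        "clustering_raw": c_raw,
        "efficiency_norm": normalize(e_raw, e_null),
        "clustering_norm": normalize(c_raw, c_null),
    }


# ---------------------------------------------------------------------------
# Density sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalMetrics:
    """Global graph parameters of one network at one density level."""

    kappa: float
    q50: float
    efficiency_raw: float
    efficiency_norm: float
    clustering_raw: float
    clustering_norm: float
    modularity: float
    density: float


@dataclass
class DensitySweep:
    """Per-density global metrics plus node strengths at one fixed density."""

    table: pd.DataFrame = field(repr=False)
    node_strengths: np.ndarray = field(repr=False)
    strength_kappa: float = 0.5

    def metric_curve(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    @property
    def kappas(self) -> np.ndarray:
        return self.table["kappa"].to_numpy()


def compute_all(
    c: Connectome,
    kappas: list[float],
    reference: Connectome,
    spec: NullEnsembleSpec,
    strength_kappa: float = 0.5,
    modularity_restarts: int = 20,
) -> DensitySweep:
    """Global metrics of one connectome over a proportional-threshold sweep.

    Masks come from the reference network (the healthy group average), so
    they are nested across densities and shared between subjects.  Node
    strengths are evaluated once, at the fixed local-analysis density
    ``strength_kappa``.
    """
    if reference.n_nodes != c.n_nodes:
        raise ValueError("reference and connectome dimensions differ")
    rows = []
    for i, kappa in enumerate(kappas):
        masked = apply_mask(c, density_mask(reference, kappa))
        nm = normalized_global_metrics(
            masked, NullEnsembleSpec(
                n_nulls=spec.n_nulls,
                rewire_iterations=spec.rewire_iterations,
                seed=spec.seed + 1000 * i,
                assignment_chunks=spec.assignment_chunks,
            ),
        )
        qmod, _ = modularity(masked, n_restarts=modularity_restarts, seed=spec.seed + i)
        rows.append(
            GlobalMetrics(
                kappa=kappa,
                q50=q50(masked),
                efficiency_raw=nm["efficiency_raw"],
                efficiency_norm=nm["efficiency_norm"],
                clustering_raw=nm["clustering_raw"],
                clustering_norm=nm["clustering_norm"],
                modularity=qmod,
                density=masked.density,
            ).__dict__
        )
    strengths = node_strength(apply_mask(c, density_mask(reference, strength_kappa)))
    return DensitySweep(
        table=pd.DataFrame(rows),
        node_strengths=strengths,
        strength_kappa=strength_kappa,
    )
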