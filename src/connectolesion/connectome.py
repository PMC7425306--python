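"""Weighted connectivity matrices: construction, thresholding, subsetting.

Edge weights follow the tractography convention of streamline counts
normalised by the summed volumes of the two regions:

    w(s, t) = counts(s, t) / (volume(s) + volume(t))

Proportional thresholding retains the top-kappa fraction of node pairs of a
*reference* network (typically the healthy group average) and applies the
resulting binary sparsity mask multiplicatively to every subject, so all
subjects share one topology per density level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import HEMISPHERES

SCOPES = ("whole_brain", "left_hemisphere", "right_hemisphere", "hemisphere")


def _check_square(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    return m


@dataclass
class Connectome:
    """A symmetric, zero-diagonal weighted network over an ordered node set.

    ``nodes`` is a node-metadata table aligned with the matrix rows
    (columns name / hemisphere / node_class / volume_mm3); it may be None
    for anonymous networks (e.g. toy graphs in tests).
    """

    weights: np.ndarray = field(repr=False)
    nodes: pd.DataFrame | None = field(default=None, repr=False)
    scope: str = "whole_brain"

    def __post_init__(self) -> None:
        w = _check_square(self.weights)
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be exactly symmetric; use symmetrize()")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if self.nodes is not None and len(self.nodes) != w.shape[0]:
            raise ValueError("node table length does not match matrix dimension")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def density(self) -> float:
        """Fraction of off-diagonal unordered pairs with nonzero weight."""
        n = self.n_nodes
        iu = np.triu_indices(n, k=1)
        return float(np.count_nonzero(self.weights[iu]) / len(iu[0]))

    def copy(self) -> "Connectome":
        return Connectome(
            weights=self.weights.copy(),
            nodes=None if self.nodes is None else self.nodes.copy(),
            scope=self.scope,
        )


@dataclass(frozen=True)
class SparsityMask:
    """Binary symmetric mask retaining the strongest node pairs of one
    reference network at target density ``kappa``."""

    mask: np.ndarray = field(repr=False)
    kappa: float = 1.0

    @property
    def n_retained_pairs(self) -> int:
        iu = np.triu_indices(self.mask.shape[0], k=1)
        return int(self.mask[iu].sum())


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def symmetrize(raw: np.ndarray) -> np.ndarray:
    """Average a square matrix with its own transpose."""
    raw = _check_square(raw)
    return (raw + raw.T) / 2.0


def weights_from_counts(
    counts: np.ndarray,
    volumes: Sequence[float] | np.ndarray,
    nodes: pd.DataFrame | None = None,
    scope: str = "whole_brain",
) -> Connectome:
    """Volume-normalised weighting: w(s,t) = counts(s,t)/(vol_s + vol_t)."""
    counts = _check_square(counts)
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 1 or len(volumes) != counts.shape[0]:
        raise ValueError("volumes must match matrix dimension")
    if np.any(volumes <= 0):
        raise ValueError("volumes must be positive")
    if not np.array_equal(counts, counts.T):
        raise ValueError("counts must be symmetric; symmetrize first")
    denom = volumes[:, None] + volumes[None, :]
    w = counts / denom
    np.fill_diagonal(w, 0.0)
    return Connectome(weights=symmetrize(w), nodes=nodes, scope=scope)


def group_average(connectomes: Sequence[Connectome]) -> Connectome:
    """Element-wise arithmetic mean of a group of aligned connectomes.

    Left- and right-hemisphere networks may be pooled (both hemispheres
    share one region sequence); the result then carries the generic
    ``hemisphere`` scope.
    """
    if len(connectomes) == 0:
        raise ValueError("cannot average an empty list")
    scopes = {c.scope for c in connectomes}
    n = connectomes[0].n_nodes
    for c in connectomes:
        if c.n_nodes != n:
            raise ValueError("connectomes differ in dimension")
    if len(scopes) == 1:
        scope = scopes.pop()
    elif scopes <= {"left_hemisphere", "right_hemisphere", "hemisphere"}:
        scope = "hemisphere"
    else:
        raise ValueError(f"cannot pool scopes {sorted(scopes)}")
    mean = np.mean([c.weights for c in connectomes], axis=0)
    return Connectome(weights=symmetrize(mean), nodes=connectomes[0].nodes, scope=scope)


def density_mask(reference: Connectome | np.ndarray, kappa: float) -> SparsityMask:
    """Mask of the round(kappa * P) strongest pairs of the reference network.

    P = n(n-1)/2 unordered off-diagonal pairs; the retained count uses
    round-half-away-from-zero.  Ties in the reference weights are broken by
    (row, column) lexicographic order in the upper triangle, which makes
    masks from a single reference nested across densities.
    """
    if not 0 < kappa <= 1:
        raise ValueError(f"kappa must be in (0, 1], got {kappa}")
    ref = reference.weights if isinstance(reference, Connectome) else _check_square(reference)
    n = ref.shape[0]
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    k_keep = _round_half_away(kappa * n_pairs)
    vals = ref[iu]
    # stable sort on -weight keeps lexicographic (row, col) order among ties
    order = np.argsort(-vals, kind="stable")
    keep = order[:k_keep]
    mask = np.zeros((n, n), dtype=np.int8)
    mask[iu[0][keep], iu[1][keep]] = 1
    mask = mask + mask.T
    return SparsityMask(mask=mask, kappa=kappa)


def apply_mask(c: Connectome, m: SparsityMask) -> Connectome:
    """Threshold a connectome by element-wise multiplication with a mask."""
    if m.mask.shape != c.weights.shape:
        raise ValueError("mask dimension does not match connectome")
    return Connectome(weights=c.weights * m.mask, nodes=c.nodes, scope=c.scope)


def hemisphere_submatrix(c: Connectome, side: str) -> Connectome:
    """Extract one hemisphere's principal submatrix (intrahemispheric network)."""
    if side not in HEMISPHERES:
        raise ValueError(f"side must be one of {HEMISPHERES}, got {side!r}")
    if c.scope != "whole_brain":
        raise ValueError("hemisphere extraction requires a whole-brain connectome")
    if c.nodes is None:
        raise ValueError("hemisphere extraction requires node metadata")
    idx = np.flatnonzero((c.nodes["hemisphere"] == side).to_numpy())
    sub = c.weights[np.ix_(idx, idx)]
    return Connectome(
        weights=sub,
        nodes=c.nodes.iloc[idx].reset_index(drop=True),
        scope=f"{side}_hemisphere",
    )


def sweep_kappas(start: float = 0.20, stop: float = 0.80, step: float = 0.05) -> list[float]:
    """The default proportional-thresholding grid: 20%..80% in steps of 5%."""
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_matrix_csv(path: str | Path, matrix: np.ndarray) -> None:
    """Headerless CSV, full matrix, shortest lossless float representation."""
    matrix = _check_square(matrix)
    with open(path, "w") as fh:
        for row in matrix:
            fh.write(",".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    m = np.loadtxt(path, delimiter=",", ndmin=2)
    return _check_square(m)


def write_nodes_tsv(path: str | Path, nodes: pd.DataFrame) -> None:
    out = nodes.rename(columns={"node_class": "class"})[
        ["name", "hemisphere", "class", "volume_mm3"]
    ].copy()
    out["volume_mm3"] = [repr(float(v)) for v in out["volume_mm3"]]
    out.to_csv(path, sep="\t", index=False)


def read_nodes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.rename(columns={"class": "node_class"})


def to_graphml(c: Connectome, path: str | Path) -> None:
    """Export to GraphML with node attributes and an edge 'weight' attribute."""
    import networkx as nx

    g = nx.Graph()
    for i in range(c.n_nodes):
        attrs = {}
        if c.nodes is not None:
            row = c.nodes.iloc[i]
            attrs = {
                "name": str(row["name"]),
                "hemisphere": str(row["hemisphere"]),
                "node_class": str(row["node_class"]),
                "volume_mm3": float(row["volume_mm3"]),
            }
        g.add_node(i, **attrs)
    iu = np.triu_indices(c.n_nodes, k=1)
    for i, j in zip(*iu):
        w = c.weights[i, j]
        if w > 0:
            g.add_edge(int(i), int(j), weight=float(w))
    nx.write_graphml(g, str(path))
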