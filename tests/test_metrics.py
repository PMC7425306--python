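"""Graph metrics against independent brute-force oracles, plus the
null-ensemble contract."""

import itertools

import networkx as nx
import numpy as np
import pytest

import connectolesion as cl
from connectolesion.metrics import NullEnsembleSpec

from conftest import random_toy_graph


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def efficiency_oracle(w: np.ndarray) -> float:
    """All-pairs Dijkstra through networkx on 1/weight lengths."""
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, length=1.0 / w[i, j])
    total = 0.0
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i in range(n):
        for j in range(n):
            if i != j and j in lengths.get(i, {}):
                d = lengths[i][j]
                if d > 0:
                    total += 1.0 / d
    return total / (n * (n - 1))


def clustering_oracle(w: np.ndarray) -> float:
    """Onnela coefficient by explicit triple enumeration."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0
    what = np.cbrt(w / wmax)
    coefs = []
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = len(nbrs)
        if k < 2:
            coefs.append(0.0)
            continue
        s = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h:
                    s += what[i, j] * what[i, h] * what[j, h]
        coefs.append(s / (k * (k - 1)))
    return float(np.mean(coefs))


def modularity_oracle(w: np.ndarray) -> float:
    """Best weighted Newman-Girvan Q over all partitions (n <= 8)."""
    n = w.shape[0]
    m2 = w.sum()

    def q_of(partition):
        q = 0.0
        for block in partition:
            idx = np.array(block)
            e = w[np.ix_(idx, idx)].sum() / m2
            a = w[idx].sum() / m2
            q += e - a**2
        return q

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1 :]
            yield [[first]] + part

    return max(q_of(p) for p in partitions(list(range(n))))


# ---------------------------------------------------------------------------
# Elementary metric examples
# ---------------------------------------------------------------------------

class TestQ50:
    def test_median_of_nonzero_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 2.0
        w[2, 3] = w[3, 2] = 3.0
        assert cl.q50(w) == 2.0
        w[0, 3] = w[3, 0] = 4.0
        assert cl.q50(w) == 2.5

    def test_constant_weights(self):
        w = np.full((5, 5), 0.7)
        np.fill_diagonal(w, 0)
        assert cl.q50(w) == pytest.approx(0.7)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            cl.q50(np.zeros((4, 4)))


class TestNodeStrength:
    def test_sum_of_incident_weights(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 1.5
        s = cl.node_strength(w)
        assert s[0] == 2.0
        assert s[1] == 0.5

    def test_isolated_node_and_handshake(self):
        rng = np.random.default_rng(0)
        w = random_toy_graph(rng, 8)
        w[3, :] = w[:, 3] = 0.0
        s = cl.node_strength(w)
        assert s[3] == 0.0
        assert s.sum() == pytest.approx(w.sum())


class TestGlobalEfficiency:
    def test_complete_uniform_graph_closed_form(self):
        for w_val in (0.5, 1.0, 2.0):
            w = np.full((6, 6), w_val)
            np.fill_diagonal(w, 0)
            assert cl.global_efficiency(w) == pytest.approx(w_val)

    def test_edgeless_graph(self):
        assert cl.global_efficiency(np.zeros((5, 5))) == 0.0

    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert cl.global_efficiency(w) == pytest.approx((1 + 1 + 0.5) / 3)


class TestClustering:
    def test_uniform_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert cl.clustering(w) == pytest.approx(1.0)

    def test_tree_has_no_closed_triples(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (1, 3)]:
            w[i, j] = w[j, i] = 1.0
        assert cl.clustering(w) == 0.0

    def test_weighted_triangle_hand_value(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.125
        # every node: (1 * 1 * 0.125)^(1/3) = 0.5
        assert cl.clustering(w) == pytest.approx(0.5)


class TestModularity:
    def test_two_disconnected_cliques(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        q, part = cl.modularity(w, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(set(part[:4])) == 1 and len(set(part[4:])) == 1

    def test_complete_graph_has_no_structure(self):
        w = np.ones((6, 6)) - np.eye(6)
        q, part = cl.modularity(w, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(set(part)) == 1

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            cl.modularity(np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# Oracle agreement and structural invariants
# ---------------------------------------------------------------------------

class TestOracleAgreement:
    def test_efficiency_and_clustering_on_seeded_toys(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            w = random_toy_graph(rng, n)
            assert cl.global_efficiency(w) == pytest.approx(
                efficiency_oracle(w), abs=1e-10
            )
            assert cl.clustering(w) == pytest.approx(clustering_oracle(w), abs=1e-10)

    def test_modularity_matches_exhaustive_partitions(self):
        rng = np.random.default_rng(321)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            w = random_toy_graph(rng, n)
            if w.sum() == 0:
                continue
            q, _ = cl.modularity(w, seed=1)
            assert q == pytest.approx(modularity_oracle(w), abs=1e-10)

    def test_efficiency_monotone_under_edge_addition(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 8
            w = random_toy_graph(rng, n, density=0.3)
            e0 = cl.global_efficiency(w)
            zeros = np.argwhere(np.triu(w == 0, k=1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w[i, j] = w[j, i] = rng.uniform(0.1, 2.0)
            assert cl.global_efficiency(w) >= e0 - 1e-12


class TestScalingInvariance:
    def test_scale_free_and_scale_linear_metrics(self, hemi_fixture):
        w = hemi_fixture.weights
        for factor in (0.1, 3.0):
            scaled = w * factor
            assert cl.clustering(scaled) == pytest.approx(cl.clustering(w), rel=1e-12)
            q1, _ = cl.modularity(scaled, seed=0)
            q0, _ = cl.modularity(w, seed=0)
            assert q1 == pytest.approx(q0, rel=1e-9)
            assert cl.q50(scaled) == pytest.approx(factor * cl.q50(w), rel=1e-12)
            assert cl.global_efficiency(scaled) == pytest.approx(
                factor * cl.global_efficiency(w), rel=1e-9
            )
            np.testing.assert_allclose(
                cl.node_strength(scaled), factor * cl.node_strength(w), rtol=1e-12
            )


# ---------------------------------------------------------------------------
# Null ensemble
# ---------------------------------------------------------------------------

class TestNullEnsemble:
    def test_preserves_degrees_and_weight_multiset(self, hemi_fixture):
        w = hemi_fixture.weights
        nulls = cl.null_ensemble(w, NullEnsembleSpec(n_nulls=10, seed=0))
        deg = (w > 0).sum(axis=1)
        iu = np.triu_indices(w.shape[0], k=1)
        sorted_w = np.sort(w[iu])
        for m in nulls:
            np.testing.assert_array_equal((m > 0).sum(axis=1), deg)
            np.testing.assert_allclose(np.sort(m[iu]), sorted_w, rtol=1e-12)

    def test_strength_sequence_approximation(self, hemi_fixture):
        w = hemi_fixture.weights
        nulls = cl.null_ensemble(w, NullEnsembleSpec(n_nulls=10, seed=1))
        s = cl.node_strength(w)
        for m in nulls:
            err = np.linalg.norm(cl.node_strength(m) - s) / np.linalg.norm(s)
            assert err < 0.05

    def test_deterministic_under_seed(self, hemi_fixture):
        spec = NullEnsembleSpec(n_nulls=3, seed=5)
        a = cl.null_ensemble(hemi_fixture.weights, spec)
        b = cl.null_ensemble(hemi_fixture.weights, spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_degenerate_topology_warns(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.warns(UserWarning):
            nulls = cl.null_ensemble(w, NullEnsembleSpec(n_nulls=2, seed=0))
        np.testing.assert_array_equal(nulls[0], w)


class TestNormalize:
    def test_ratio_and_zero_cases(self):
        assert cl.normalize(2.0, [2.0, 2.0]) == 1.0
        assert cl.normalize(0.0, [1.0, 3.0]) == 0.0
        with pytest.raises(ValueError):
            cl.normalize(1.0, [])
        with pytest.raises(ValueError):
            cl.normalize(1.0, [0.0, 0.0])

    def test_random_network_self_normalises(self):
        """An Erdos-Renyi-like weighted network is its own null model: the
        normalised efficiency must sit within a few percent of 1."""
        rng = np.random.default_rng(11)
        w = random_toy_graph(rng, 41, density=0.5)
        nm = cl.normalized_global_metrics(w, NullEnsembleSpec(n_nulls=100, seed=2))
        assert 0.95 <= nm["efficiency_norm"] <= 1.05


class TestComputeAll:
    def test_sweep_shape_and_nesting(self, hemi_average):
        sweep = cl.compute_all(
            hemi_average,
            cl.sweep_kappas(),
            hemi_average,
            NullEnsembleSpec(n_nulls=5, seed=0),
        )
        assert len(sweep.table) == 13
        assert sweep.node_strengths.shape == (41,)
        # achieved density grows with kappa until the raw support saturates
        dens = sweep.table["density"].to_numpy()
        assert np.all(np.diff(dens) >= 0)
        assert dens[-1] > dens[0]

    def test_single_kappa(self, hemi_fixture):
        sweep = cl.compute_all(
            hemi_fixture, [0.4], hemi_fixture, NullEnsembleSpec(n_nulls=5, seed=0)
        )
        assert len(sweep.table) == 1
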