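"""Null models, supra-matrix assembly, modularity and generalized Louvain."""

import numpy as np
import pytest

from multinet.cohort_io import CohortError
from multinet.multilayer import (
    Partition,
    assemble_multilayer,
    consensus_node_labels,
    genlouvain,
    louvain_sweep,
    modularity_q,
    newman_girvan_null,
    signed_configuration_null,
    supra_modularity,
)

from conftest import make_layer, random_layer, set_partitions


def brute_force_q(net, g):
    """Quadruple-sum oracle for Q written without any matrix algebra."""
    n, L = g.shape
    total = 0.0
    for l in range(L):
        for i in range(n):
            for j in range(n):
                if g[i, l] == g[j, l]:
                    total += net.A[l][i, j] - net.gamma[l] * net.M[l][i, j]
    for i in range(n):
        for l in range(L):
            for r in range(L):
                if l == r:
                    continue
                if net.coupling == "ordinal" and abs(l - r) != 1:
                    continue
                if g[i, l] == g[i, r]:
                    total += net.omega
    return total / net.two_mu


def exhaustive_best_q(net):
    """Maximum Q over every set partition of the node-layers."""
    n, L = net.n_subjects, net.n_layers
    best = -np.inf
    for labels in set_partitions(n * L):
        g = labels.reshape(L, n).T
        best = max(best, modularity_q(net, g))
    return best


def triangle_layer():
    w = np.ones((3, 3)) - np.eye(3)
    return make_layer(w)


def two_cliques_layer():
    w = np.zeros((6, 6))
    for block in (slice(0, 3), slice(3, 6)):
        w[block, block] = 1.0
    np.fill_diagonal(w, 0.0)
    return make_layer(w)


class TestNullModels:
    def test_triangle_closed_form(self):
        M = newman_girvan_null(triangle_layer())
        assert np.allclose(M, 2.0 / 3.0)  # k=2 everywhere, 2m=6

    def test_star_closed_form(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        M = newman_girvan_null(make_layer(w))
        assert np.isclose(M[0, 1], 0.5)       # 3*1/6
        assert np.isclose(M[1, 2], 1.0 / 6.0)  # 1*1/6

    def test_row_sums_equal_strengths(self):
        layer = random_layer(np.random.default_rng(0), 5, signed=False)
        M = newman_girvan_null(layer)
        assert np.allclose(M.sum(axis=1), layer.weights.sum(axis=1), atol=1e-12)

    def test_zero_total_weight_raises(self):
        with pytest.raises(CohortError, match="zero"):
            newman_girvan_null(make_layer(np.zeros((3, 3))))

    def test_signed_null_reduces_to_ng_on_nonnegative(self):
        layer = random_layer(np.random.default_rng(1), 6, signed=False)
        assert np.allclose(
            signed_configuration_null(layer), newman_girvan_null(layer), atol=1e-12
        )

    def test_signed_null_row_sums_and_boundedness(self):
        layer = random_layer(np.random.default_rng(2), 6, signed=True)
        M = signed_configuration_null(layer)
        assert np.allclose(M.sum(axis=1), layer.weights.sum(axis=1), atol=1e-10)
        # near-cancelling weights must not blow up
        assert np.abs(M).max() < 10 * np.abs(layer.weights).max()


class TestAssemble:
    def test_two_mu_no_coupling(self):
        rng = np.random.default_rng(3)
        layers = [random_layer(rng, 3, m, signed=False) for m in ("mri", "pet")]
        net = assemble_multilayer(layers, 1.0, 0.0)
        assert np.isclose(net.two_mu, sum(l.weights.sum() for l in layers))

    def test_two_mu_counts_couplings_from_both_endpoints(self):
        # 2 layers, 3 subjects, each layer total weight 6, omega=1 -> 12 + 6 = 18
        layers = [triangle_layer(), triangle_layer()]
        layers[1].modality_id = "pet"
        net = assemble_multilayer(layers, 1.0, 1.0)
        assert np.isclose(net.two_mu, 18.0)

    def test_categorical_coupling_topology(self):
        rng = np.random.default_rng(4)
        n, L = 4, 5
        sids = [f"s{i}" for i in range(n)]
        mods = ["mri", "pet", "csf", "cognition", "genetics"]
        layers = [random_layer(rng, n, m, signed=False, subject_ids=sids) for m in mods]
        net = assemble_multilayer(layers, 1.0, 2.5)
        B = supra_modularity(net)
        off = B.copy()
        for l in range(L):
            off[l * n : (l + 1) * n, l * n : (l + 1) * n] = 0.0
        # each node-layer couples to exactly L-1 copies of itself
        assert np.all((off != 0).sum(axis=1) == L - 1)
        assert np.all(off[off != 0] == 2.5)

    def test_mismatched_subjects_raise(self):
        a = random_layer(np.random.default_rng(5), 3, "mri")
        b = random_layer(np.random.default_rng(6), 3, "pet",
                         subject_ids=["x", "y", "z"])
        with pytest.raises(CohortError, match="mismatched"):
            assemble_multilayer([a, b])


class TestModularityQ:
    def test_single_layer_one_community_is_zero(self):
        layer = random_layer(np.random.default_rng(7), 5, signed=False)
        net = assemble_multilayer([layer], 1.0, 0.0)
        g = np.zeros((5, 1), dtype=int)
        assert abs(modularity_q(net, g)) < 1e-12

    def test_two_cliques_half(self):
        net = assemble_multilayer([two_cliques_layer()], 1.0, 0.0)
        g = np.array([0, 0, 0, 1, 1, 1])[:, None]
        assert np.isclose(modularity_q(net, g), 0.5, atol=1e-12)
        assert np.isclose(brute_force_q(net, g), 0.5, atol=1e-12)

    def test_matches_quadruple_sum_oracle_multilayer(self):
        rng = np.random.default_rng(8)
        sids = ["a", "b", "c"]
        layers = [random_layer(rng, 3, m, subject_ids=sids) for m in ("mri", "pet")]
        net = assemble_multilayer(layers, [1.0, 1.4], 0.5)
        g = np.array([[0, 1], [0, 0], [1, 1]])
        assert np.isclose(modularity_q(net, g), brute_force_q(net, g), atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_supra_equals_quadruple_sum_random_signed(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 7))
        L = int(rng.integers(1, 4))
        sids = [f"s{i}" for i in range(n)]
        mods = ["mri", "pet", "csf"][:L]
        layers = [random_layer(rng, n, m, signed=True, subject_ids=sids) for m in mods]
        net = assemble_multilayer(layers, list(rng.uniform(0.5, 2.0, L)), float(rng.uniform(0, 2)))
        g = rng.integers(0, 3, size=(n, L))
        assert np.isclose(modularity_q(net, g), brute_force_q(net, g), atol=1e-12)

    def test_relabeling_leaves_q_unchanged(self):
        rng = np.random.default_rng(9)
        layers = [random_layer(rng, 4, m) for m in ("mri", "pet")]
        layers[1].subject_ids = layers[0].subject_ids
        net = assemble_multilayer(layers, 1.0, 0.7)
        g = rng.integers(0, 3, size=(4, 2))
        perm = np.array([2, 0, 1])
        assert np.isclose(modularity_q(net, g), modularity_q(net, perm[g]), atol=1e-14)

    def test_singletons_closed_form_omega_zero(self):
        rng = np.random.default_rng(10)
        layers = [random_layer(rng, 5, m, signed=False) for m in ("mri", "pet")]
        layers[1].subject_ids = layers[0].subject_ids
        gamma = [1.0, 1.7]
        net = assemble_multilayer(layers, gamma, 0.0)
        g = np.arange(10).reshape(2, 5).T  # all node-layers distinct
        expected = 0.0
        for l, layer in enumerate(layers):
            k = layer.weights.sum(axis=1)
            expected -= gamma[l] * (k**2).sum() / k.sum()
        assert np.isclose(modularity_q(net, g), expected / net.two_mu, atol=1e-12)


def planted_two_block_net(omega=1.0):
    """6 subjects, 2 layers; within-block weight 1, between 0."""
    w = np.zeros((6, 6))
    w[:3, :3] = 1.0
    w[3:, 3:] = 1.0
    np.fill_diagonal(w, 0.0)
    layers = [make_layer(w, "mri"), make_layer(w, "pet")]
    return assemble_multilayer(layers, 1.0, omega)


class TestLouvain:
    def test_sweep_monotone_q_on_random_instances(self):
        rng = np.random.default_rng(11)
        for trial in range(50):
            n = int(rng.integers(3, 6))
            L = int(rng.integers(1, 3))
            sids = [f"s{i}" for i in range(n)]
            layers = [
                random_layer(rng, n, m, signed=True, subject_ids=sids)
                for m in ("mri", "pet")[:L]
            ]
            net = assemble_multilayer(layers, 1.0, float(rng.uniform(0, 1)))
            g0 = np.arange(n * L).reshape(L, n).T
            p0 = Partition(sids, net.layer_ids, g0, modularity_q(net, g0))
            p1 = louvain_sweep(net, p0, np.random.default_rng(trial))
            assert p1.q >= p0.q - 1e-12

    def test_sweep_keeps_optimal_singletons(self):
        # strongly repulsive network: optimum is all-singletons
        w = -np.ones((3, 3))
        np.fill_diagonal(w, 0.0)
        net = assemble_multilayer([make_layer(w)], 1.0, 0.0)
        g0 = np.arange(3)[:, None]
        p0 = Partition(net.subject_ids, net.layer_ids, g0, modularity_q(net, g0))
        p1 = louvain_sweep(net, p0, np.random.default_rng(0))
        assert np.array_equal(p1.g, g0)

    def test_planted_blocks_recovered(self):
        # 2 blocks x 2 subjects x 2 layers (8 node-layers): first verify by
        # exhaustive enumeration that the planted partition is Q-optimal,
        # then that genlouvain attains it (a single phase-1 sweep stalls at
        # subject-copy pairs because the coupling gain exceeds the
        # within-block gain; aggregation is what carries it the rest of the
        # way).
        w = np.zeros((4, 4))
        w[:2, :2] = 1.0
        w[2:, 2:] = 1.0
        np.fill_diagonal(w, 0.0)
        layers = [make_layer(w, "mri"), make_layer(w, "pet")]
        net = assemble_multilayer(layers, 1.0, 1.0)
        planted = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        q_planted = modularity_q(net, planted)
        assert np.isclose(q_planted, exhaustive_best_q(net), atol=1e-12)
        part = genlouvain(net, restarts=10, seed=2)
        assert np.isclose(part.q, q_planted, atol=1e-10)
        assert np.array_equal(part.g, part.g[:, :1].repeat(2, axis=1))
        assert len(np.unique(part.g[:, 0])) == 2

    def test_genlouvain_merges_blocks_where_sweep_stalls(self):
        net = planted_two_block_net(omega=1.0)
        g0 = np.arange(12).reshape(2, 6).T
        p0 = Partition(net.subject_ids, net.layer_ids, g0, modularity_q(net, g0))
        p1 = louvain_sweep(net, p0, np.random.default_rng(1))
        assert p1.q >= p0.q
        full = genlouvain(net, restarts=10, seed=1)
        assert full.q > p1.q
        for l in range(2):
            col = full.g[:, l]
            assert len(np.unique(col)) == 2
            assert (col[:3] == col[0]).all() and (col[3:] == col[3]).all()

    def test_genlouvain_exhaustive_small(self):
        # 3 subjects x 2 layers: 203 partitions of 6 node-layers
        rng = np.random.default_rng(12)
        sids = ["a", "b", "c"]
        layers = [random_layer(rng, 3, m, subject_ids=sids) for m in ("mri", "pet")]
        net = assemble_multilayer(layers, 1.0, 0.8)
        best = exhaustive_best_q(net)
        part = genlouvain(net, restarts=20, seed=0)
        assert np.isclose(part.q, best, atol=1e-10)

    def test_genlouvain_deterministic(self):
        net = planted_two_block_net()
        a = genlouvain(net, restarts=5, seed=7)
        b = genlouvain(net, restarts=5, seed=7)
        assert np.array_equal(a.g, b.g)
        assert a.q == b.q

    def test_large_omega_forces_layer_consistency(self):
        rng = np.random.default_rng(13)
        sids = [f"s{i}" for i in range(8)]
        layers = [
            random_layer(rng, 8, m, signed=True, subject_ids=sids)
            for m in ("mri", "pet", "csf")
        ]
        omega = 1e3 * max(np.abs(l.weights).max() for l in layers)
        net = assemble_multilayer(layers, 1.0, omega)
        part = genlouvain(net, restarts=5, seed=3)
        assert np.all(part.g.std(axis=1) == 0)

    def test_monolayer_reduction_matches_networkx(self):
        # L=1, omega=0: Q must equal single-layer Newman-Girvan modularity
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(14)
        layer = random_layer(rng, 8, signed=False)
        net = assemble_multilayer([layer], 1.0, 0.0)
        part = genlouvain(net, restarts=10, seed=1)
        G = nx.from_numpy_array(layer.weights)
        comms = [set(np.where(part.g[:, 0] == c)[0]) for c in np.unique(part.g[:, 0])]
        q_nx = nx.algorithms.community.modularity(G, comms, weight="weight")
        assert np.isclose(part.q, q_nx, atol=1e-10)


class TestConsensus:
    def _part(self, g):
        g = np.asarray(g)
        return Partition(
            subject_ids=[f"s{i}" for i in range(g.shape[0])],
            layer_ids=[f"L{l}" for l in range(g.shape[1])],
            g=g,
            q=0.0,
        )

    def test_unanimous(self):
        labels, split = consensus_node_labels(self._part([[2, 2, 2, 2, 2]]))
        assert labels[0] == 2 and not split[0]

    def test_majority(self):
        labels, split = consensus_node_labels(self._part([[1, 1, 2, 2, 2]]))
        assert labels[0] == 2 and split[0]

    def test_tie_goes_to_earliest_layer(self):
        labels, split = consensus_node_labels(self._part([[1, 2]]))
        assert labels[0] == 1 and split[0]
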