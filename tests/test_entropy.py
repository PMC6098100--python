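"""Entropy engine checks against independent brute-force walk enumeration."""

import numpy as np
import pytest

from netnet import (
    Network,
    entropy_table,
    graph_entropy,
    markov_matrix,
    mean_node_entropy,
    node_entropies,
    walk_distribution,
)


def brute_force_walk(trans, initial, k):
    """Enumerate every length-k walk explicitly and sum its probability mass."""
    n = len(initial)
    out = np.zeros(n)

    def rec(node, prob, steps):
        if steps == k:
            out[node] += prob
            return
        for nxt in range(n):
            if trans[node, nxt] > 0:
                rec(nxt, prob * trans[node, nxt], steps + 1)

    for start in range(n):
        if initial[start] > 0:
            rec(start, initial[start], 0)
    return out


def _random_small_graphs():
    """Every-shape zoo with <= 6 nodes: random, isolated-node, weighted."""
    rng = np.random.default_rng(42)
    graphs = []
    for n in (3, 4, 5, 6):
        a = (rng.random((n, n)) < 0.5).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        graphs.append(Network(list(range(n)), a))
    iso = np.zeros((4, 4))
    iso[0, 1] = iso[1, 0] = 1.0  # nodes 2, 3 isolated
    graphs.append(Network(["a", "b", "c", "d"], iso))
    w = np.zeros((5, 5))
    for i, j, wt in [(0, 1, 2.0), (1, 2, 0.5), (2, 3, 1.5), (3, 4, 3.0), (0, 4, 1.0)]:
        w[i, j] = w[j, i] = wt
    graphs.append(Network(list("vwxyz"), w, weighted=True))
    return graphs


class TestMarkovMatrix:
    def test_path_degree_normalization(self, path3):
        m = markov_matrix(path3)
        expect = np.array([[0, 1, 0], [0.5, 0, 0.5], [0, 1, 0]])
        assert np.allclose(m.transition, expect)
        assert np.allclose(m.initial, 1 / 3)

    def test_triangle_off_diagonal_half(self, k3):
        m = markov_matrix(k3)
        assert np.allclose(m.transition, (np.ones((3, 3)) - np.eye(3)) / 2)

    def test_isolated_node_self_loop(self):
        net = Network(["only"], np.zeros((1, 1)))
        m = markov_matrix(net)
        assert m.transition.tolist() == [[1.0]] and m.initial.tolist() == [1.0]

    def test_rows_stochastic_under_powers(self, suite):
        for net in suite.values():
            power = np.linalg.matrix_power(markov_matrix(net).transition, 5)
            assert np.allclose(power.sum(axis=1), 1.0, atol=1e-10)


class TestWalkDistribution:
    def test_k0_returns_initial(self, path3):
        m = markov_matrix(path3)
        assert np.array_equal(walk_distribution(m, 0), m.initial)

    def test_path_k1_matches_hand_enumeration(self, path3):
        # 1/3 of mass at each node; a and c both send everything to b
        assert np.allclose(
            walk_distribution(markov_matrix(path3), 1), [1 / 6, 2 / 3, 1 / 6]
        )

    def test_uniform_stationary_on_triangle(self, k3):
        m = markov_matrix(k3)
        for k in range(6):
            assert np.allclose(walk_distribution(m, k), 1 / 3)

    def test_negative_k_rejected(self, path3):
        with pytest.raises(ValueError):
            walk_distribution(markov_matrix(path3), -1)

    @pytest.mark.parametrize("k", range(6))
    def test_matrix_power_equals_brute_force_enumeration(self, k):
        for net in _random_small_graphs():
            m = markov_matrix(net)
            expect = brute_force_walk(m.transition, m.initial, k)
            assert np.allclose(walk_distribution(m, k), expect, atol=1e-12)


class TestNodeEntropies:
    def test_triangle_closed_form(self, k3):
        for profile in node_entropies(k3):
            assert np.allclose(profile.sh, np.log2(3) / 3)

    def test_path_k1_hand_values(self, path3):
        sh = {p.node_id: p.sh for p in node_entropies(path3)}
        assert sh["b"][1] == pytest.approx((2 / 3) * np.log2(3 / 2), abs=1e-12)
        assert sh["a"][1] == pytest.approx((1 / 6) * np.log2(6), abs=1e-12)
        assert sh["c"][1] == pytest.approx(sh["a"][1])

    def test_single_node_zero_entropy(self):
        net = Network(["only"], np.zeros((1, 1)))
        assert node_entropies(net)[0].sh[0] == 0.0

    def test_per_row_alternative_reading(self, k3):
        # from any triangle node the 1-step row is (0.5, 0.5) over neighbours
        profiles = node_entropies(k3, per_row=True)
        for p in profiles:
            assert p.sh[0] == 0.0 and p.sh[1] == pytest.approx(1.0)

    def test_relabeling_invariance(self, suite):
        rng = np.random.default_rng(3)
        for net in suite.values():
            perm = rng.permutation(net.n)
            shuffled = Network(
                [net.node_ids[i] for i in perm], net.adjacency[np.ix_(perm, perm)]
            )
            a = {p.node_id: p.sh for p in node_entropies(net)}
            b = {p.node_id: p.sh for p in node_entropies(shuffled)}
            for lab in a:
                assert np.allclose(a[lab], b[lab])


class TestGraphEntropy:
    def test_triangle_is_log2_3(self, k3):
        for k in range(6):
            assert graph_entropy(k3, k) == pytest.approx(np.log2(3))

    def test_path_k1_sum(self, path3):
        expect = (2 / 3) * np.log2(3 / 2) + 2 * (1 / 6) * np.log2(6)
        assert graph_entropy(path3, 1) == pytest.approx(expect)
        assert mean_node_entropy(path3, 1) == pytest.approx(expect / 3)

    @pytest.mark.parametrize("n", [3, 4, 5, 7])
    def test_complete_graph_exactly_log2_n(self, n):
        net = Network(list(range(n)), np.ones((n, n)) - np.eye(n))
        for k in range(6):
            assert graph_entropy(net, k) == pytest.approx(np.log2(n), abs=1e-12)

    def test_regular_graphs_hit_log_n(self):
        # 5-cycle: 2-regular and connected, so the uniform start is stationary
        adj = np.zeros((5, 5))
        for i in range(5):
            adj[i, (i + 1) % 5] = adj[(i + 1) % 5, i] = 1
        net = Network(list(range(5)), adj)
        for k in range(6):
            assert graph_entropy(net, k) == pytest.approx(np.log2(5))

    def test_upper_bound_log_n(self, suite):
        for net in suite.values():
            for k in range(6):
                assert graph_entropy(net, k) <= np.log2(net.n) + 1e-12

    def test_natural_log_base_rescales(self, k3):
        assert graph_entropy(k3, 2, log_base=np.e) == pytest.approx(np.log(3))


def test_entropy_table_schema(path3):
    table = entropy_table(path3)
    assert list(table.columns) == ["node_id"] + [f"Sh_{k}" for k in range(6)]
    assert len(table) == 3
    assert np.isfinite(table.iloc[:, 1:].to_numpy()).all()
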