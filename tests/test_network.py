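import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizonet import network as net


def taxa_frame(**rows):
    n = len(next(iter(rows.values())))
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T


class TestSpearman:
    def test_hand_case_rho_08(self):
        rho, _ = net.spearman_matrix(
            taxa_frame(x=[1, 2, 3, 4, 5], y=[2, 1, 4, 3, 5])
        )
        assert rho.loc["x", "y"] == pytest.approx(0.8)

    def test_perfect_and_inverted(self):
        x = [1.0, 2.5, 3.0, 4.7, 5.1, 9.0]  # increasing: reversal inverts ranks
        rho, _ = net.spearman_matrix(taxa_frame(x=x, y=x, z=x[::-1]))
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["x", "z"] == pytest.approx(-1.0)

    def test_exact_small_sample_p_matches_enumeration(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        _, pmat = net.spearman_matrix(taxa_frame(x=x, y=y))
        # exhaustive oracle: all 5! permutations of y's ranks
        obs = 0.8
        count = 0
        perms = list(itertools.permutations([1, 2, 3, 4, 5]))
        for perm in perms:
            d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4, 5], perm))
            r = 1 - 6 * d2 / (5 * 24)
            if abs(r) >= obs - 1e-12:
                count += 1
        assert pmat.loc["x", "y"] == pytest.approx(count / len(perms))

    def test_constant_taxon_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, pmat = net.spearman_matrix(
                taxa_frame(x=[1, 2, 3, 4, 5], c=[2, 2, 2, 2, 2])
            )
        assert np.isnan(rho.loc["x", "c"])
        assert pmat.loc["x", "c"] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            net.spearman_matrix(taxa_frame(x=[1, 2, 3], y=[3, 2, 1]))


class TestBuildNetwork:
    def _matrices(self, rho_xy, p_xy):
        taxa = ["x", "y"]
        rho = pd.DataFrame([[1.0, rho_xy], [rho_xy, 1.0]], index=taxa, columns=taxa)
        p = pd.DataFrame([[0.0, p_xy], [p_xy, 0.0]], index=taxa, columns=taxa)
        return rho, p

    def test_strong_significant_pair_is_positive_edge(self):
        rho, p = self._matrices(0.85, 0.01)
        g = net.build_network(rho, p).graph
        assert g.has_edge("x", "y") and g["x"]["y"]["sign"] == 1

    def test_threshold_boundary_is_strict(self):
        rho, p = self._matrices(0.8, 0.01)
        with pytest.warns(UserWarning, match="no edges"):
            assert net.build_network(rho, p).n_edges == 0

    def test_insignificant_strong_negative_excluded(self):
        rho, p = self._matrices(-0.9, 0.2)
        with pytest.warns(UserWarning):
            assert net.build_network(rho, p).n_edges == 0

    def test_negative_edge_carries_sign(self):
        rho, p = self._matrices(-0.9, 0.001)
        g = net.build_network(rho, p).graph
        assert g["x"]["y"]["sign"] == -1

    def test_invalid_params_rejected(self):
        rho, p = self._matrices(0.9, 0.001)
        with pytest.raises(ValueError):
            net.build_network(rho, p, net.NetworkParams(rho_threshold=1.5))

    def test_construction_order_invariant(self, small_tables):
        from rhizonet.io import to_relative_abundance

        _, counts, _, meta = small_tables
        rel = net.filter_taxa(to_relative_abundance(counts))
        rho, p = net.spearman_matrix(rel)
        a = net.build_network(rho, p)
        perm = rel.sample(frac=1, random_state=1)
        rho2, p2 = net.spearman_matrix(perm)
        b = net.build_network(rho2, p2)
        edges = lambda n: {frozenset(e) for e in n.graph.edges}
        assert edges(a) == edges(b)


class TestNegativeEdgeRatio:
    def _net_with_signs(self, signs):
        g = nx.Graph()
        for i, s in enumerate(signs):
            g.add_edge(f"a{i}", f"b{i}", sign=s, rho=0.9 * s, p=0.01, weight=0.9)
        return net.CooccurrenceNetwork(graph=g, params=net.NetworkParams())

    def test_fraction(self):
        assert net.negative_edge_ratio(
            self._net_with_signs([-1] * 3 + [1] * 7)
        ) == pytest.approx(0.3)

    def test_all_positive_zero(self):
        assert net.negative_edge_ratio(self._net_with_signs([1, 1])) == 0.0

    def test_edgeless_undefined(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        n = net.CooccurrenceNetwork(graph=g, params=net.NetworkParams())
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(net.negative_edge_ratio(n))


class TestModules:
    def _as_network(self, g):
        for u, v in g.edges:
            g[u][v].setdefault("weight", 1.0)
        return net.CooccurrenceNetwork(graph=g, params=net.NetworkParams())

    def test_two_disconnected_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        part = net.detect_modules(self._as_network(g))
        assert part.module_ids == [1, 2]
        assert set(part.members(1)) in ({0, 1, 2, 3, 4, 5}, {6, 7, 8, 9, 10, 11})

    def test_edgeless_nodes_unlabeled(self):
        g = nx.empty_graph(5)
        part = net.detect_modules(self._as_network(g))
        assert part.module_ids == []
        assert part.assignment.isna().all()

    def test_small_communities_unlabeled(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(3))
        part = net.detect_modules(self._as_network(g), min_module_size=5)
        assert part.module_ids == [1]
        assert len(part.members(1)) == 6

    def test_labels_stable_across_runs(self):
        g = nx.disjoint_union(nx.complete_graph(7), nx.complete_graph(6))
        a = net.detect_modules(self._as_network(g), seed=1)
        b = net.detect_modules(self._as_network(g), seed=1)
        pd.testing.assert_series_equal(a.assignment, b.assignment)


class TestNaturalConnectivity:
    def test_triangle_closed_form(self):
        expected = math.log((math.e**2 + 2 * math.e**-1) / 3)
        assert net.natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-10
        )
        assert expected == pytest.approx(0.9963, abs=5e-5)

    def test_path_closed_form(self):
        r2 = math.sqrt(2)
        expected = math.log((math.e**r2 + 1 + math.e**-r2) / 3)
        assert net.natural_connectivity(nx.path_graph(3)) == pytest.approx(
            expected, abs=1e-10
        )
        assert expected == pytest.approx(0.5797, abs=5e-5)

    def test_empty_graph_zero(self):
        assert net.natural_connectivity(nx.empty_graph(7)) == pytest.approx(0.0)

    def test_matches_matrix_exponential_trace(self):
        from scipy.linalg import expm

        rng = np.random.default_rng(0)
        for _ in range(25):
            g = nx.gnp_random_graph(
                int(rng.integers(2, 15)), float(rng.uniform(0.1, 0.9)),
                seed=int(rng.integers(2**31)),
            )
            a = nx.to_numpy_array(g)
            oracle = np.log(np.trace(expm(a)) / len(a))
            assert net.natural_connectivity(g) == pytest.approx(oracle, abs=1e-8)

    def test_edge_removal_never_increases(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            before = net.natural_connectivity(g)
            edges = list(g.edges)
            u, v = edges[rng.integers(len(edges))]
            h = g.copy()
            h.remove_edge(u, v)
            assert net.natural_connectivity(h) <= before + 1e-12


class TestRobustnessCurve:
    def _wrap(self, g):
        return net.CooccurrenceNetwork(graph=g, params=net.NetworkParams())

    def test_complete_graph_closed_form(self):
        # removing k nodes from K8 leaves K_{8-k}: curve is deterministic
        curve = net.robustness_curve(
            self._wrap(nx.complete_graph(8)),
            fractions=(0.125, 0.25, 0.5), n_reps=5, seed=0,
        )
        def k_nat(n):
            lam = np.array([n - 1.0] + [-1.0] * (n - 1))
            return float(np.log(np.mean(np.exp(lam))))
        expected = [k_nat(7), k_nat(6), k_nat(4)]
        assert np.allclose(curve.mean, expected)
        assert np.allclose(curve.sd, 0.0)

    def test_intact_value_recorded(self):
        g = nx.complete_graph(6)
        curve = net.robustness_curve(self._wrap(g), fractions=(0.2,), n_reps=3, seed=0)
        assert curve.intact == pytest.approx(net.natural_connectivity(g))

    def test_mean_curve_non_increasing_on_er_graphs(self):
        g = nx.gnp_random_graph(50, 0.2, seed=4)
        curve = net.robustness_curve(
            self._wrap(g), fractions=(0.1, 0.3, 0.5), n_reps=60, seed=2
        )
        assert curve.mean[0] >= curve.mean[1] >= curve.mean[2]
        assert curve.intact >= curve.mean[0]

    def test_reproducible_and_fraction_validation(self):
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        a = net.robustness_curve(self._wrap(g), n_reps=5, seed=9)
        b = net.robustness_curve(self._wrap(g), n_reps=5, seed=9)
        assert np.allclose(a.mean, b.mean)
        with pytest.raises(ValueError):
            net.robustness_curve(self._wrap(g), fractions=(0.0, 0.5))
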