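"""Interactome construction, node metrics and power-law fitting."""

import math

import networkx as nx
import numpy as np
import pytest

from netprio import graph as G

from conftest import brute_force_path_metrics


# ---------------------------------------------------------------------------
# build_interactome / giant_component
# ---------------------------------------------------------------------------

class TestBuildInteractome:
    def test_dedup_and_self_loop_removal(self):
        g = G.build_interactome([("A", "B"), ("B", "A"), ("A", "A"), ("B", "C")])
        assert set(g.nodes()) == {"A", "B", "C"}
        assert {frozenset(e) for e in g.edges()} == {
            frozenset({"A", "B"}), frozenset({"B", "C"})}
        assert g.graph["n_self_dropped"] == 1
        assert g.graph["n_dup_dropped"] == 1

    def test_node_filter_keeps_both_endpoint_edges_and_isolated_members(self):
        g = G.build_interactome(
            [("A", "B"), ("B", "C"), ("C", "D")], node_filter={"A", "B", "C", "E"})
        assert "D" not in g
        assert {frozenset(e) for e in g.edges()} == {
            frozenset({"A", "B"}), frozenset({"B", "C"})}
        assert g.degree("E") == 0  # isolated filter gene retained

    def test_malformed_row_raises_with_line_number(self):
        with pytest.raises(G.EdgeListParseError, match="row 2"):
            G.build_interactome([("A", "B"), ("A", "B", "C")])

    def test_edge_list_round_trip(self, tmp_path, default_bundle):
        p = tmp_path / "edges.tsv"
        G.write_edge_list(default_bundle.graph, p)
        back = G.read_edge_list(p)
        assert {frozenset(e) for e in back.edges()} == {
            frozenset(e) for e in default_bundle.graph.edges()}

    def test_comment_lines_ignored(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# header\nA\tB\n\nB\tC\n")
        g = G.read_edge_list(p)
        assert g.number_of_edges() == 2


class TestGiantComponent:
    def test_tie_broken_by_lexicographically_smallest_member(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"),
                          ("D", "E"), ("E", "F"), ("D", "F")])
        giant, rep = G.giant_component(g)
        assert set(giant.nodes()) == {"A", "B", "C"}
        assert rep.n_components == 2

    def test_isolated_nodes_counted(self, path3):
        path3.add_node("D")
        giant, rep = G.giant_component(path3)
        assert set(giant.nodes()) == {"A", "B", "C"}
        assert rep.n_isolated == 1

    def test_matches_bfs_component_search(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            g = nx.gnp_random_graph(30, 0.05, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes()})
            giant, _ = G.giant_component(g)
            # oracle: exhaustive BFS from every node
            best = max((len(nx.node_connected_component(g, v)) for v in g), default=0)
            assert giant.number_of_nodes() == best


# ---------------------------------------------------------------------------
# degree / local metrics
# ---------------------------------------------------------------------------

class TestDegreeMetrics:
    def test_path_degrees(self, path3):
        k, _ = G.degree_metrics(path3)
        assert k == {"A": 1, "B": 2, "C": 1}

    def test_star_degree_distribution(self, star5):
        _, dist = G.degree_metrics(star5)
        assert dist == {1: 0.8, 4: 0.2}

    def test_handshake_identity_and_distribution_sums_to_one(self, default_bundle):
        k, dist = G.degree_metrics(default_bundle.graph)
        assert sum(k.values()) == 2 * default_bundle.graph.number_of_edges()
        assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9)


class TestNeighborhoodConnectivity:
    def test_star(self, star5):
        assert G.neighborhood_connectivity(star5, "X") == 1.0
        assert G.neighborhood_connectivity(star5, "A") == 4.0

    def test_path_ends_and_center(self, path3):
        assert G.neighborhood_connectivity(path3, "A") == 2.0
        assert G.neighborhood_connectivity(path3, "B") == 1.0

    def test_isolated_node_is_nan(self, path3):
        path3.add_node("Z")
        assert math.isnan(G.neighborhood_connectivity(path3, "Z"))

    def test_unknown_gene(self, path3):
        with pytest.raises(KeyError):
            G.neighborhood_connectivity(path3, "Q")


class TestClusteringCoefficient:
    def test_triangle_is_one(self, triangle):
        assert G.clustering_coefficient(triangle, "A") == 1.0

    def test_star_center_is_zero(self, star5):
        assert G.clustering_coefficient(star5, "X") == 0.0

    def test_paw_apex_one_third(self, paw):
        assert G.clustering_coefficient(paw, "A") == pytest.approx(1 / 3)

    def test_degree_below_two_is_nan(self, paw):
        assert math.isnan(G.clustering_coefficient(paw, "D"))

    def test_complete_graph_all_ones(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, str)
        assert all(G.clustering_coefficient(g, v) == 1.0 for v in g)


class TestTopologicalCoefficient:
    def test_triangle(self, triangle):
        # each pair shares 1 neighbor and is directly linked: J=2, T=2/2/k=1
        for v in "ABC":
            assert G.topological_coefficient(triangle, v) == pytest.approx(1.0)

    def test_star_center_zero(self, star5):
        assert G.topological_coefficient(star5, "X") == 0.0

    def test_four_cycle(self, cycle4):
        # for A the only qualifying node is C: shares B and D, no direct edge
        assert G.topological_coefficient(cycle4, "A") == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, str)
            for v in g:
                nbrs = set(g.neighbors(v))
                js = {}
                for j in g:
                    if j == v:
                        continue
                    shared = len(nbrs & set(g.neighbors(j)))
                    if shared:
                        js[j] = shared + (1 if g.has_edge(v, j) else 0)
                expect = (sum(js.values()) / len(js) / len(nbrs)
                          if js and len(nbrs) > 1 else 0.0)
                assert G.topological_coefficient(g, v) == pytest.approx(expect)


# ---------------------------------------------------------------------------
# shortest-path metrics
# ---------------------------------------------------------------------------

class TestShortestPathMetrics:
    def test_path3_values(self, path3):
        stress, bet, aspl = G.shortest_path_metrics(path3)
        assert stress["B"] == 1
        assert bet["B"] == pytest.approx(1.0)
        assert aspl["A"] == pytest.approx(1.5)

    def test_triangle_no_intermediates(self, triangle):
        stress, bet, _ = G.shortest_path_metrics(triangle)
        assert all(v == 0 for v in stress.values())
        assert all(v == 0 for v in bet.values())

    def test_path4_stress(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
        stress, _, _ = G.shortest_path_metrics(g)
        assert stress["B"] == 2  # geodesics A-C and A-D

    def test_isolated_node_aspl_nan(self, path3):
        path3.add_node("Z")
        _, _, aspl = G.shortest_path_metrics(path3)
        assert math.isnan(aspl["Z"])

    def test_betweenness_matches_networkx(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(40, 0.1, seed=3), str)
        giant, _ = G.giant_component(g)
        _, bet, _ = G.shortest_path_metrics(giant)
        ref = nx.betweenness_centrality(giant, normalized=True)
        for v in giant:
            assert bet[v] == pytest.approx(ref[v], abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 20))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, str)
            stress, bet, aspl = G.shortest_path_metrics(g)
            estress, ebet, easpl = brute_force_path_metrics(g)
            for v in g:
                assert stress[v] == estress[v]
                assert bet[v] == pytest.approx(ebet[v], abs=1e-9)
                if math.isnan(easpl[v]):
                    assert math.isnan(aspl[v])
                else:
                    assert aspl[v] == pytest.approx(easpl[v], abs=1e-9)

    def test_stress_and_betweenness_rank_identically_on_trees(self):
        # unique geodesics => identical induced rankings
        g = nx.relabel_nodes(nx.random_labeled_tree(25, seed=5), str)
        stress, bet, _ = G.shortest_path_metrics(g)
        order_s = sorted(g, key=lambda v: (-stress[v], v))
        order_b = sorted(g, key=lambda v: (-bet[v], v))
        assert order_s == order_b


class TestComputeMetrics:
    def test_columns_and_row_order(self, paw):
        m = G.compute_metrics(paw)
        assert list(m.columns) == G.METRIC_COLUMNS
        assert list(m.index) == ["A", "B", "C", "D"]

    def test_adding_edge_never_decreases_degree(self, paw):
        before = G.compute_metrics(paw)["degree"]
        paw.add_edge("D", "C")
        after = G.compute_metrics(paw)["degree"]
        assert (after[before.index] >= before).all()

    def test_metrics_tsv_round_trip_with_na(self, path3, tmp_path):
        path3.add_node("Z")
        m = G.compute_metrics(path3)
        p = tmp_path / "m.tsv"
        G.write_metrics(m, p)
        assert "NA" in p.read_text()
        back = G.read_metrics(p)
        assert back.shape == m.shape
        assert math.isnan(back.loc["Z", "avg_short_path"])
        assert back.loc["B", "degree"] == 2


# ---------------------------------------------------------------------------
# power-law fitting
# ---------------------------------------------------------------------------

class TestPowerLawFit:
    def test_continuous_closed_form_exact(self):
        # all values at e * xmin: alpha = 1 + n / sum(ln x/xmin) = 2 exactly
        values = [math.e] * 100
        fit = G.fit_power_law(values, discrete=False, xmin=1.0)
        assert fit.alpha == pytest.approx(-2.0, abs=1e-12)

    def test_discrete_recovery(self):
        rng = np.random.default_rng(123)
        x = G.sample_power_law(5000, 2.85, 2, rng, discrete=True)
        fit = G.fit_power_law(x, discrete=True)
        assert abs(fit.alpha_magnitude - 2.85) <= 0.15

    def test_continuous_recovery(self):
        rng = np.random.default_rng(456)
        x = G.sample_power_law(5000, 2.13, 1.0, rng, discrete=False)
        fit = G.fit_power_law(x, discrete=False)
        assert abs(fit.alpha_magnitude - 2.13) <= 0.15

    def test_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(789)
        x = G.sample_power_law(5000, 2.5, 1.0, rng, discrete=False)
        fit = G.fit_power_law(x, discrete=False, xmin=1.0)
        assert fit.n_tail == 5000
        assert abs(fit.alpha_magnitude - 2.5) <= 3 * fit.alpha_stderr

    def test_too_few_values_raises(self):
        with pytest.raises(G.PowerLawFitError):
            G.fit_power_law([1.0, 2.0, 3.0])

    def test_degenerate_tail_raises(self):
        with pytest.raises(G.PowerLawFitError):
            G.fit_power_law([5.0] * 100)

    def test_fit_invariants(self):
        rng = np.random.default_rng(9)
        x = G.sample_power_law(500, 3.0, 1.0, rng)
        fit = G.fit_power_law(x)
        assert fit.alpha_magnitude > 1
        assert fit.xmin >= x.min()
        assert 0 <= fit.ks_statistic <= 1
        assert fit.n_tail >= 2
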