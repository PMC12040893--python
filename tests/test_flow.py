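"""Volume entropy and directed capacities: closed forms, scaling, invariants."""

import numpy as np
import networkx as nx
import pytest

from dyncoreflow import (AcyclicGraphError, MetricGraph, edge_capacity_matrix,
                         solve_volume_entropy, spectral_radius, to_metric_graph)
from dyncoreflow.flow import build_edge_operator, flow_timecourse, solve_flow

from conftest import unit_length_metric_graph


class TestToMetricGraph:
    def test_length_is_one_minus_r(self):
        adj = np.array([[0, 1], [1, 0]], dtype=float)
        w = np.array([[0, 0.65], [0.65, 0]])
        mg = to_metric_graph(adj, w)
        assert mg.lengths[0] == pytest.approx(0.35)

    def test_near_perfect_correlation_clipped(self):
        adj = np.array([[0, 1], [1, 0]], dtype=float)
        w = np.array([[0, 0.99], [0.99, 0]])
        mg = to_metric_graph(adj, w)
        assert mg.lengths[0] == pytest.approx(0.05)

    def test_restricts_to_giant_component(self):
        a = nx.to_numpy_array(nx.disjoint_union(
            nx.erdos_renyi_graph(90, 0.1, seed=1), nx.complete_graph(10)))
        mg = to_metric_graph(a)
        assert mg.n_nodes == 90
        assert mg.component_fraction == pytest.approx(0.9)

    def test_directed_edge_count_is_twice_undirected(self):
        g = nx.erdos_renyi_graph(20, 0.3, seed=2)
        mg = to_metric_graph(nx.to_numpy_array(g))
        assert mg.n_directed == 2 * mg.n_edges


class TestEdgeOperator:
    def test_cycle_rows_have_single_continuation(self):
        op = build_edge_operator(unit_length_metric_graph(nx.cycle_graph(4)))
        counts = np.diff(op.S.indptr)
        assert (counts == 1).all()

    def test_k4_row_sums_are_degree_minus_one_at_h0(self):
        op = build_edge_operator(unit_length_metric_graph(nx.complete_graph(4)))
        rs = np.asarray(op.matrix(0.0).sum(axis=1)).ravel()
        np.testing.assert_allclose(rs, 2.0)

    def test_tree_operator_is_nilpotent(self):
        op = build_edge_operator(unit_length_metric_graph(nx.path_graph(6)))
        assert spectral_radius(op, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_entries_decrease_in_h(self):
        op = build_edge_operator(unit_length_metric_graph(nx.complete_graph(4)))
        assert spectral_radius(op, 1.0) < spectral_radius(op, 0.5) \
            < spectral_radius(op, 0.0)


class TestSpectralRadius:
    @pytest.mark.parametrize("graph,h,expected", [
        (nx.complete_graph(4), 0.0, 2.0),
        (nx.cycle_graph(5), 0.0, 1.0),
        (nx.complete_graph(4), np.log(2), 1.0),
    ])
    def test_closed_forms(self, graph, h, expected):
        op = build_edge_operator(unit_length_metric_graph(graph))
        assert spectral_radius(op, h) == pytest.approx(expected, abs=1e-9)


class TestVolumeEntropy:
    @pytest.mark.parametrize("d", [3, 4, 5])
    def test_regular_graph_closed_form(self, d):
        g = nx.random_regular_graph(d, 12, seed=3)
        h = solve_volume_entropy(unit_length_metric_graph(g))
        assert h == pytest.approx(np.log(d - 1), abs=1e-6)

    def test_single_cycle_is_zero(self):
        for n in (3, 5, 9):
            h = solve_volume_entropy(unit_length_metric_graph(nx.cycle_graph(n)))
            assert h == pytest.approx(0.0, abs=1e-8)

    def test_petersen_graph(self):
        h = solve_volume_entropy(unit_length_metric_graph(nx.petersen_graph()))
        assert h == pytest.approx(np.log(2), abs=1e-6)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scaling_law(self, c):
        g = nx.erdos_renyi_graph(15, 0.3, seed=5)
        h1 = solve_volume_entropy(unit_length_metric_graph(g))
        hc = solve_volume_entropy(unit_length_metric_graph(g, scale=c))
        assert hc == pytest.approx(h1 / c, abs=1e-6)

    def test_tree_raises(self):
        with pytest.raises(AcyclicGraphError):
            solve_volume_entropy(unit_length_metric_graph(nx.path_graph(5)))

    def test_adding_edge_never_decreases_entropy(self):
        rng = np.random.default_rng(6)
        g = nx.erdos_renyi_graph(12, 0.3, seed=1)
        if not nx.is_connected(g):
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        g = nx.convert_node_labels_to_integers(g)
        for _ in range(10):
            h0 = solve_volume_entropy(unit_length_metric_graph(g))
            candidates = [(u, v) for u in g for v in g
                          if u < v and not g.has_edge(u, v)]
            if not candidates:
                break
            u, v = candidates[rng.integers(len(candidates))]
            g.add_edge(u, v)
            h1 = solve_volume_entropy(unit_length_metric_graph(g))
            assert h1 >= h0 - 1e-8



class TestCapacities:
    def test_k4_uniform_capacities(self):
        mg = unit_length_metric_graph(nx.complete_graph(4))
        fr = edge_capacity_matrix(mg, np.log(2))
        np.testing.assert_allclose(fr.capacities, 1 / 12, atol=1e-10)
        np.testing.assert_allclose(fr.afferent, 0.25, atol=1e-10)
        np.testing.assert_allclose(fr.efferent, 0.25, atol=1e-10)

    def test_cycle_capacities_per_node(self):
        mg = unit_length_metric_graph(nx.cycle_graph(5))
        fr = edge_capacity_matrix(mg, 0.0)
        np.testing.assert_allclose(fr.afferent, 0.2, atol=1e-8)
        np.testing.assert_allclose(fr.efferent, 0.2, atol=1e-8)

    @pytest.mark.parametrize("graph", [
        nx.complete_graph(4), nx.cycle_graph(5), nx.petersen_graph(),
        nx.complete_bipartite_graph(3, 3),
    ])
    def test_normalisation_and_vertex_transitive_uniformity(self, graph):
        mg = unit_length_metric_graph(graph)
        fr = edge_capacity_matrix(mg, solve_volume_entropy(mg))
        n = mg.n_nodes
        assert fr.afferent.sum() == pytest.approx(1.0, abs=1e-12)
        assert fr.efferent.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(fr.afferent - 1 / n).max() <= 1e-8
        assert np.abs(fr.efferent - 1 / n).max() <= 1e-8

    def test_lollipop_afferent_efferent_discordance(self, lollipop_graph):
        mg = unit_length_metric_graph(lollipop_graph)
        fr = edge_capacity_matrix(mg, solve_volume_entropy(mg))
        assert np.abs(fr.afferent - fr.efferent).max() > 1e-4
        assert fr.reducible
        assert fr.afferent.sum() == pytest.approx(1.0, abs=1e-12)
        assert fr.efferent.sum() == pytest.approx(1.0, abs=1e-12)

    def test_capacity_matrix_shape_and_marginals(self, lollipop_graph):
        mg = unit_length_metric_graph(lollipop_graph)
        fr = edge_capacity_matrix(mg, solve_volume_entropy(mg))
        m = fr.capacity_matrix()
        assert m.shape == (mg.n_nodes, mg.n_nodes)
        np.testing.assert_allclose(m.sum(axis=0), fr.afferent, atol=1e-12)
        np.testing.assert_allclose(m.sum(axis=1), fr.efferent, atol=1e-12)

    def test_permutation_equivariance(self):
        g = nx.erdos_renyi_graph(12, 0.35, seed=8)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        g = nx.convert_node_labels_to_integers(g)
        mg = unit_length_metric_graph(g)
        h = solve_volume_entropy(mg)
        fr = edge_capacity_matrix(mg, h)
        rng = np.random.default_rng(1)
        perm = rng.permutation(g.number_of_nodes())
        adj = nx.to_numpy_array(g)
        mg_p = to_metric_graph(adj[np.ix_(perm, perm)])
        mg_p = MetricGraph(mg_p.nodes, mg_p.edges, np.ones(mg_p.n_edges),
                           mg_p.weights, mg_p.component_fraction)
        fr_p = edge_capacity_matrix(mg_p, solve_volume_entropy(mg_p))
        np.testing.assert_allclose(fr_p.afferent, fr.afferent[perm], atol=1e-8)
        np.testing.assert_allclose(fr_p.efferent, fr.efferent[perm], atol=1e-8)


class TestFlowTimecourse:
    def test_constant_graph_constant_flow(self):
        # a series whose every window yields the same thresholded graph
        rng = np.random.default_rng(4)
        base = rng.standard_normal(120)
        data = np.vstack([base + 0.1 * rng.standard_normal(120) for _ in range(8)])
        from dyncoreflow import WindowSpec, build_windowed_graphs
        gs = build_windowed_graphs(data, WindowSpec(window_frames=60,
                                                    shift_frames=30))
        res = flow_timecourse(gs, "positive")
        hs = [r.h for r in res.values() if r is not None]
        assert len(hs) >= 2
        assert np.ptp(hs) < 0.2 * max(hs)

    def test_degenerate_windows_yield_missing(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((10, 100))   # pure noise: no edges survive
        from dyncoreflow import WindowSpec, build_windowed_graphs
        gs = build_windowed_graphs(data, WindowSpec(window_frames=84,
                                                    shift_frames=8))
        res = flow_timecourse(gs, "positive")
        assert all(r is None for r in res.values())

    def test_subthreshold_edges_do_not_change_entropy(self):
        # adding edges below threshold leaves the channel graph, hence h*, alone
        rng = np.random.default_rng(6)
        n = 12
        r = np.full((n, n), 0.3)
        clique = np.arange(6)
        r[np.ix_(clique, clique)] = 0.9
        np.fill_diagonal(r, 0)
        from dyncoreflow import split_and_threshold
        g1 = split_and_threshold(r.copy())
        r2 = r.copy()
        r2[r2 == 0.3] = 0.5             # still below theta_pos
        g2 = split_and_threshold(r2)
        assert (g1.pos_adj == g2.pos_adj).all()
        f1 = solve_flow(g1.pos_adj, np.abs(g1.r))
        f2 = solve_flow(g2.pos_adj, np.abs(g2.r))
        assert f1.h == pytest.approx(f2.h, abs=1e-10)
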