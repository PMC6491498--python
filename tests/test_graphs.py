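"""Graph construction, path-length metrics, null models, hubs."""

import numpy as np
import pytest

from conftest import floyd_warshall_oracle, random_connected_weighted_graph
from ftdnet.graphs import (
    BrainGraph,
    NullEnsembleSpec,
    build_graph,
    compute_global_metrics,
    compute_nodal_metrics,
    generate_null_ensemble,
    identify_hubs,
)


class FakeConn:
    def __init__(self, values, subject_id="s"):
        self.values = values
        self.subject_id = subject_id


def three_node_path():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 0.5
    return BrainGraph("path", w, 1.0)


class TestBuildGraph:
    def test_all_positive_full_density_keeps_everything(self, rng):
        c = np.full((6, 6), 0.4)
        np.fill_diagonal(c, 1.0)
        g = build_graph(FakeConn(c), "zero", 1.0)
        assert g.n_edges == 15
        assert np.allclose(g.weights[~np.eye(6, dtype=bool)], 0.4)

    def test_density_point_one_has_495_edges_containing_spanning_tree(self, rng):
        a = rng.standard_normal((100, 400))
        c = np.corrcoef(a)
        g = build_graph(FakeConn(c), "zero", 0.10)
        assert g.n_edges == 495
        # independent maximum-spanning-tree oracle (Kruskal with union-find)
        w = np.where(c > 0, c, 0.0)
        np.fill_diagonal(w, 0.0)
        iu, ju = np.triu_indices(100, 1)
        order = np.argsort(w[iu, ju])[::-1]
        parent = list(range(100))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        mst_edges = []
        for k in order:
            i, j = int(iu[k]), int(ju[k])
            if w[i, j] <= 0:
                break
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                mst_edges.append((i, j))
        assert len(mst_edges) == 99
        for i, j in mst_edges:
            assert g.weights[i, j] > 0, f"spanning-tree edge ({i},{j}) missing"

    def test_all_negative_with_zero_policy_errors(self):
        c = np.full((5, 5), -0.3)
        np.fill_diagonal(c, 1.0)
        with pytest.raises(ValueError, match="connected"):
            build_graph(FakeConn(c), "zero", 0.5)

    def test_absolute_policy_rectifies_negatives(self):
        c = np.full((5, 5), -0.3)
        np.fill_diagonal(c, 1.0)
        g = build_graph(FakeConn(c), "absolute", 1.0)
        assert np.allclose(g.weights[~np.eye(5, dtype=bool)], 0.3)

    def test_realized_density_tracks_target(self, rng):
        a = rng.standard_normal((60, 200))
        g = build_graph(FakeConn(np.corrcoef(a)), "zero", 0.2)
        assert g.edge_density == pytest.approx(0.2, abs=1 / (60 * 59 / 2))


class TestMetrics:
    def test_unit_complete_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        g = BrainGraph("tri", w, 1.0)
        nm = compute_nodal_metrics(g)
        np.testing.assert_allclose(nm.strength, 2.0)
        np.testing.assert_allclose(nm.farness, 1.0)
        np.testing.assert_allclose(nm.nodal_efficiency, 1.0)
        gm = compute_global_metrics(g)
        assert gm.global_efficiency_raw == pytest.approx(1.0)

    def test_three_node_path_against_hand_computed_values(self):
        # distances: AB = 1, BC = 2, AC = 3 (via B)
        nm = compute_nodal_metrics(three_node_path())
        np.testing.assert_allclose(nm.strength, [1.0, 1.5, 0.5])
        np.testing.assert_allclose(nm.farness, [2.0, 1.5, 2.5])
        assert nm.nodal_efficiency[0] == pytest.approx((1 + 1 / 3) / 2)
        gm = compute_global_metrics(three_node_path())
        assert gm.global_efficiency_raw == pytest.approx((1 + 1 / 2 + 1 / 3) / 3)
        assert gm.connection_strength_total == pytest.approx(3.0)

    def test_metrics_invariant_under_node_relabeling(self, rng):
        g = random_connected_weighted_graph(rng)
        perm = rng.permutation(g.n_nodes)
        gp = BrainGraph("perm", g.weights[np.ix_(perm, perm)], g.edge_density)
        nm, nmp = compute_nodal_metrics(g), compute_nodal_metrics(gp)
        np.testing.assert_allclose(nmp.strength, nm.strength[perm], atol=1e-12)
        np.testing.assert_allclose(nmp.farness, nm.farness[perm], atol=1e-12)

    def test_handshake_identity(self, rng):
        g = random_connected_weighted_graph(rng)
        gm = compute_global_metrics(g)
        assert gm.connection_strength_total == pytest.approx(
            2 * np.triu(g.weights, 1).sum()
        )

    def test_uniform_weight_scaling(self, rng):
        """Scaling weights by c scales strength and efficiency by c; the
        normalized efficiency is unchanged."""
        g = random_connected_weighted_graph(rng)
        c = 3.7
        gs = BrainGraph("scaled", c * g.weights, g.edge_density)
        nulls = generate_null_ensemble(g, NullEnsembleSpec(20, 3, 5))
        nulls_s = [BrainGraph(n.subject_id, c * n.weights, n.edge_density) for n in nulls]
        gm, gms = compute_global_metrics(g, nulls), compute_global_metrics(gs, nulls_s)
        assert gms.global_efficiency_raw == pytest.approx(c * gm.global_efficiency_raw)
        assert gms.connection_strength_total == pytest.approx(
            c * gm.connection_strength_total
        )
        assert gms.global_efficiency_normalized == pytest.approx(
            gm.global_efficiency_normalized, rel=1e-9
        )

    def test_agrees_with_floyd_warshall_oracle_on_random_graphs(self, rng):
        for _ in range(15):
            g = random_connected_weighted_graph(rng, n_max=20)
            d = floyd_warshall_oracle(g.weights)
            off = ~np.eye(g.n_nodes, dtype=bool)
            nm = compute_nodal_metrics(g)
            np.testing.assert_allclose(
                nm.farness, [d[i, off[i]].mean() for i in range(g.n_nodes)], atol=1e-9
            )
            gm = compute_global_metrics(g)
            assert gm.global_efficiency_raw == pytest.approx(
                (1 / d[off]).mean(), abs=1e-9
            )


class TestNullEnsemble:
    def test_degree_sequence_and_weight_multiset_preserved(self, rng):
        g = random_connected_weighted_graph(rng)
        nulls = generate_null_ensemble(g, NullEnsembleSpec(10, 5, 42))
        deg = (g.weights > 0).sum(axis=1)
        weights = np.sort(g.edge_list()[:, 2])
        for n in nulls:
            assert ((n.weights > 0).sum(axis=1) == deg).all()
            np.testing.assert_allclose(np.sort(n.edge_list()[:, 2]), weights)

    def test_nulls_stay_connected(self, rng):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        g = random_connected_weighted_graph(rng)
        for n in generate_null_ensemble(g, NullEnsembleSpec(10, 5, 7)):
            assert connected_components(csr_matrix(n.weights), directed=False)[0] == 1

    def test_complete_graph_topology_unchanged_weights_permuted(self, rng):
        n = 8
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        w[iu, ju] = rng.uniform(0.1, 1.0, len(iu))
        w += w.T
        g = BrainGraph("full", w, 1.0)
        nulls = generate_null_ensemble(g, NullEnsembleSpec(5, 5, 9))
        for null in nulls:
            assert (null.weights > 0).sum() == (g.weights > 0).sum()
            np.testing.assert_allclose(
                np.sort(null.edge_list()[:, 2]), np.sort(g.edge_list()[:, 2])
            )

    def test_seeded_reproducibility(self, rng):
        g = random_connected_weighted_graph(rng)
        a = generate_null_ensemble(g, NullEnsembleSpec(3, 5, 99))
        b = generate_null_ensemble(g, NullEnsembleSpec(3, 5, 99))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.weights, y.weights)


class TestHubs:
    def test_equal_strengths_give_empty_hub_set(self):
        assert not identify_hubs(np.full(50, 3.3)).any()

    def test_single_outlier_is_the_only_hub(self, rng):
        s = rng.standard_normal(100)
        s[17] = 5.0 + s.max()
        flags = identify_hubs(s)
        assert flags[17]
        assert flags.sum() == 1

    def test_hub_set_depends_only_on_reference_strengths(self, rng):
        s = rng.standard_normal(60)
        flags = identify_hubs(s.copy())
        np.testing.assert_array_equal(flags, identify_hubs(s.copy()))

    def test_hub_attack_shrinks_strength_gap(self, rng):
        """Scaling hub-incident weights by 0.7 strictly reduces the
        hub-minus-nonhub strength gap."""
        g = random_connected_weighted_graph(rng, n_max=25)
        nm = compute_nodal_metrics(g)
        hubs = np.argsort(nm.strength)[-3:]
        flags = np.zeros(g.n_nodes, dtype=bool)
        flags[hubs] = True
        gap = nm.strength[flags].mean() - nm.strength[~flags].mean()
        w = g.weights.copy()
        w[flags, :] *= 0.7
        w[:, flags] *= 0.7
        w[np.ix_(flags, flags)] /= 0.7  # hub-hub edges scaled once, not twice
        nm2 = compute_nodal_metrics(BrainGraph("attacked", w, g.edge_density))
        gap2 = nm2.strength[flags].mean() - nm2.strength[~flags].mean()
        assert gap2 < gap
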