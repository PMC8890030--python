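import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from richconn import richclub as rc


def brute_force_phi(adj: np.ndarray) -> dict[int, float]:
    """Exhaustive oracle: explicit subgraph construction per k."""
    deg = adj.sum(axis=1)
    out = {}
    for k in range(1, int(deg.max()) + 1):
        nodes = [i for i in range(len(adj)) if deg[i] > k]
        n = len(nodes)
        if n < 2:
            out[k] = None
            continue
        e = sum(int(adj[a, b]) for ai, a in enumerate(nodes)
                for b in nodes[ai + 1:])
        out[k] = 2.0 * e / (n * (n - 1))
    return out


class TestRichClubCoefficient:
    def test_complete_graph_is_one_everywhere(self):
        adj = 1 - np.eye(5, dtype=np.int8)
        prof = rc.rich_club_coefficient(rc.BinaryGraph(adj))
        defined = np.isfinite(prof.phi)
        assert defined.any()
        assert np.allclose(prof.phi[defined], 1.0)

    def test_star_graph_undefined_above_leaf_degree(self):
        adj = np.zeros((6, 6), dtype=np.int8)
        adj[0, 1:] = adj[1:, 0] = 1
        prof = rc.rich_club_coefficient(rc.BinaryGraph(adj))
        # at k=1 only the hub has degree > 1 -> N>1 = 1 -> undefined
        assert prof.n_gt_k[0] == 1
        assert np.isnan(prof.phi[0])

    def test_toy_core_graph_matches_bruteforce(self, toy_core_graph):
        prof = rc.rich_club_coefficient(toy_core_graph)
        oracle = brute_force_phi(toy_core_graph.adjacency)
        for k, expected in oracle.items():
            got = prof.phi[k - 1]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=0)

    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    def test_exact_oracle_equivalence_on_random_graphs(self, p, rng):
        """Matches exhaustive subgraph counting exactly on ER graphs,
        and networkx's rich_club_coefficient where both are defined."""
        for rep in range(67):
            n = int(rng.integers(5, 26))
            g = random_graph(n, p, rng)
            prof = rc.rich_club_coefficient(g)
            oracle = brute_force_phi(g.adjacency)
            for k, expected in oracle.items():
                got = prof.phi[k - 1]
                assert (np.isnan(got) if expected is None
                        else got == expected)
            nxg = nx.from_numpy_array(g.adjacency)
            if g.n_edges and not list(nx.selfloop_edges(nxg)):
                nx_phi = nx.rich_club_coefficient(nxg, normalized=False)
                for k, v in nx_phi.items():
                    if 1 <= k <= len(prof.phi) and np.isfinite(prof.phi[k - 1]):
                        assert prof.phi[k - 1] == pytest.approx(v, abs=1e-12)

    def test_adding_hub_hub_edge_never_decreases_phi(self, rng):
        """Monotone relation: an extra edge between two high-degree
        non-adjacent nodes cannot lower phi at any k below both of their
        degrees (above that, the edge changes which nodes qualify for the
        subgraph, so monotonicity is not guaranteed)."""
        for _ in range(20):
            g = random_graph(15, 0.3, rng)
            deg = g.degrees()
            order = np.argsort(-deg)
            pair = None
            for ai in range(len(order)):
                for bi in range(ai + 1, len(order)):
                    a, b = int(order[ai]), int(order[bi])
                    if g.adjacency[a, b] == 0:
                        pair = (a, b)
                        break
                if pair:
                    break
            if pair is None:
                continue
            adj2 = g.adjacency.copy()
            adj2[pair[0], pair[1]] = adj2[pair[1], pair[0]] = 1
            before = rc.rich_club_coefficient(g).phi
            after = rc.rich_club_coefficient(rc.BinaryGraph(adj2)).phi
            # membership is fixed only strictly below both endpoint degrees
            k_stable = int(min(deg[pair[0]], deg[pair[1]])) - 1
            kk = min(len(before), len(after), k_stable)
            both = np.isfinite(before[:kk]) & np.isfinite(after[:kk])
            assert np.all(after[:kk][both] >= before[:kk][both] - 1e-12)


class TestRewiring:
    def test_degree_sequence_preserved_exactly(self, rng):
        for rep in range(25):
            n = int(rng.integers(8, 30))
            g = random_graph(n, 0.3, rng)
            if g.n_edges < 2:
                continue
            out = rc.rewire_preserving_degree(g, seed=int(rng.integers(2**31)))
            assert np.array_equal(out.degrees(), g.degrees())
            assert out.n_edges == g.n_edges

    def test_complete_graph_unchanged(self):
        adj = 1 - np.eye(6, dtype=np.int8)
        out = rc.rewire_preserving_degree(rc.BinaryGraph(adj), seed=3)
        assert np.array_equal(out.adjacency, adj)

    def test_two_seeds_differ_same_degrees(self, rng):
        g = random_graph(20, 0.3, rng)
        a = rc.rewire_preserving_degree(g, seed=1)
        b = rc.rewire_preserving_degree(g, seed=2)
        assert not np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.degrees(), b.degrees())


class TestNormalizedRichClub:
    def test_complete_graph_normalizes_to_one(self):
        adj = 1 - np.eye(6, dtype=np.int8)
        prof = rc.normalized_rich_club(rc.BinaryGraph(adj), n_null=5, seed=0)
        defined = np.isfinite(prof.phi_norm)
        assert np.allclose(prof.phi_norm[defined], 1.0)

    def test_deterministic_under_fixed_seed(self, rng):
        g = random_graph(20, 0.3, rng)
        a = rc.normalized_rich_club(g, n_null=3, seed=7)
        b = rc.normalized_rich_club(g, n_null=3, seed=7)
        assert np.array_equal(a.phi_norm, b.phi_norm, equal_nan=True)

    def test_planted_core_exceeds_one_at_low_k(self):
        from richconn.synthetic_cohort import planted_core_graph
        adj, _ = planted_core_graph(n_nodes=60, density=0.12, core_size=9,
                                    seed=4)
        prof = rc.normalized_rich_club(rc.BinaryGraph(adj), n_null=50, seed=4)
        window = (prof.k_levels >= 2) & (prof.k_levels <= 8)
        vals = prof.phi_norm[window]
        assert np.all(vals[np.isfinite(vals)] > 1.0)

    def test_rewired_graph_has_phinorm_near_one(self, rng):
        """The null model's own expectation: analysing an already-rewired
        graph gives mean phi_norm ~ 1 at well-populated k."""
        g = random_graph(40, 0.25, rng)
        base = rc.rewire_preserving_degree(g, seed=11)
        ratios = []
        for seed in range(8):
            prof = rc.normalized_rich_club(base, n_null=25, seed=seed)
            ok = np.isfinite(prof.phi_norm) & (prof.n_gt_k >= 10)
            ratios.append(prof.phi_norm[ok])
        mean = np.mean(np.concatenate(ratios))
        assert 0.95 <= mean <= 1.05


class TestRichNodesAndEdges:
    def test_top_17_of_116_at_fraction_015(self, rng):
        sel = rc.select_rich_nodes(rng.random(116), 0.15)
        assert len(sel) == 17

    def test_fraction_one_selects_all(self):
        assert len(rc.select_rich_nodes(np.arange(10), 1.0)) == 10

    def test_tie_break_prefers_lower_index(self):
        sel = rc.select_rich_nodes(np.array([5.0, 5.0, 4.0, 3.0]), 0.5)
        assert set(sel) == {0, 1}

    def test_zero_selection_rejected(self):
        with pytest.raises(ValueError):
            rc.select_rich_nodes(np.arange(5), 0.1)

    def test_k4_classification_counts(self):
        adj = 1 - np.eye(4, dtype=np.int8)
        cmap = rc.classify_edges(rc.BinaryGraph(adj), [0, 1])
        assert cmap.counts == {"rich": 1, "feeder": 4, "local": 1}

    def test_empty_and_full_rich_sets(self):
        adj = 1 - np.eye(4, dtype=np.int8)
        assert rc.classify_edges(rc.BinaryGraph(adj), []).counts["local"] == 6
        assert rc.classify_edges(rc.BinaryGraph(adj),
                                 range(4)).counts["rich"] == 6

    def test_classification_matches_membership_invariant(self, rng):
        g = random_graph(15, 0.4, rng)
        rich = [1, 5, 9]
        cmap = rc.classify_edges(g, rich)
        for i, j, c in zip(cmap.edge_i, cmap.edge_j, cmap.edge_class):
            n_rich = (i in rich) + (j in rich)
            assert c == {0: "local", 1: "feeder", 2: "rich"}[n_rich]


class TestNodalEfficiency:
    def test_complete_graph_unit_efficiency(self):
        adj = 1 - np.eye(7, dtype=np.int8)
        m = rc.nodal_efficiency(rc.BinaryGraph(adj))
        assert np.allclose(m.efficiency, 1.0)

    def test_path_graph_hand_values(self):
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1
        m = rc.nodal_efficiency(rc.BinaryGraph(adj))
        assert m.efficiency[1] == pytest.approx(1.0)
        assert m.efficiency[0] == pytest.approx(0.75)
        assert m.efficiency[2] == pytest.approx(0.75)

    def test_isolated_node_zero(self):
        adj = np.zeros((4, 4), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = 1
        m = rc.nodal_efficiency(rc.BinaryGraph(adj))
        assert m.efficiency[3] == 0.0

    def test_matches_networkx_on_random_graphs(self, rng):
        for _ in range(5):
            g = random_graph(12, 0.3, rng)
            mine = rc.nodal_efficiency(g).efficiency
            nxg = nx.from_numpy_array(g.adjacency)
            for i in range(12):
                lengths = nx.single_source_shortest_path_length(nxg, i)
                oracle = sum(1 / d for j, d in lengths.items() if j != i) / 11
                assert mine[i] == pytest.approx(oracle, abs=1e-12)


class TestSummaries:
    def test_summary_excludes_undefined(self):
        p1 = rc.rich_club_coefficient(rc.BinaryGraph(1 - np.eye(5, dtype=np.int8)))
        prof = rc.RichClubProfile(
            k_levels=p1.k_levels, phi=p1.phi, n_gt_k=p1.n_gt_k,
            e_gt_k=p1.e_gt_k, phi_random_mean=p1.phi,
            phi_random_sd=np.zeros_like(p1.phi),
            phi_norm=np.where(np.isfinite(p1.phi), 2.0, np.nan))
        out = rc.summarize_profiles([prof, prof])
        defined = np.isfinite(out["phi_norm"])
        assert np.allclose(out["phi_norm"][defined], 2.0)

    def test_rich_club_effect_window(self):
        k = np.arange(1, 10)
        good = np.where((k >= 2) & (k <= 8), 1.2, np.nan)
        assert rc.has_rich_club_effect(good, k)
        bad = good.copy()
        bad[4] = 0.9
        assert not rc.has_rich_club_effect(bad, k)
        assert not rc.has_rich_club_effect(np.full(9, np.nan), k)
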