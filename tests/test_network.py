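"""Network construction gates, module roles, robustness measures, cohesion."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from litterome import network
from litterome.containers import CommunityTable


def make_table(rows, samples=None, taxa=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{i}" for i in range(rows.shape[1])]
    return CommunityTable(counts=pd.DataFrame(rows, index=samples, columns=taxa))


class TestPrevalenceFilter:
    def test_boundary_occupancy_retained(self):
        # present in 4 of 5 samples = exactly 80% → kept
        rows = np.full((5, 2), 50)
        rows[0, 1] = 0
        out = network.prevalence_filter(make_table(rows))
        assert "t1" in out.taxon_ids

    def test_low_abundance_removed(self):
        rows = np.full((5, 2), 100_000)
        rows[:, 1] = 4  # mean relative abundance 4e-5 < 1e-4 in every sample
        out = network.prevalence_filter(make_table(rows))
        assert out.taxon_ids == ["t0"]

    def test_toy_fixture_matches_hand_enumeration(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(1, 50, size=(5, 10))
        rows[:, 3] = 0            # absent everywhere
        rows[0:2, 7] = 0          # occupancy 3/5 < 0.8
        rows[:, 9] = 1            # rare but both gates use relative shares
        table = make_table(rows)
        rel = rows / rows.sum(axis=1, keepdims=True)
        expected = [
            f"t{j}" for j in range(10)
            if rel[:, j].mean() >= 1e-4 and (rows[:, j] > 0).mean() >= 0.8
        ]
        assert network.prevalence_filter(table).taxon_ids == expected

    def test_all_removed_raises(self):
        rows = np.zeros((5, 2), dtype=int)
        rows[0] = [5, 5]
        rows[1:] = [[1, 0], [0, 1], [1, 0], [0, 1]]
        with pytest.raises(ValueError, match="no taxa"):
            network.prevalence_filter(make_table(rows), min_occupancy=1.0)


def hand_bh(pvalues):
    """Benjamini–Hochberg step-up computed the long way."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvalues[idx] * m / rank)
        q[idx] = prev
    return q


class TestCorrelationNetwork:
    def test_monotone_profiles_give_unit_rho(self):
        rows = np.array([[1, 2, 10], [2, 4, 9], [3, 6, 8], [4, 8, 7], [5, 10, 6]])
        g = network.correlation_network(make_table(rows), rho_min=0.99, q_max=1.01)
        assert g.edges["t0", "t1"]["rho"] == pytest.approx(1.0)
        assert g.edges["t0", "t2"]["rho"] == pytest.approx(-1.0)

    def test_constant_taxon_pairs_skipped(self):
        # equal sample totals keep t1 constant after the relative transform
        rows = np.array([[1, 5, 4], [2, 5, 3], [3, 5, 2], [4, 5, 1], [2, 5, 3]])
        with pytest.warns(UserWarning, match="undefined"):
            g = network.correlation_network(make_table(rows), rho_min=0.0, q_max=1.01)
        assert not g.has_edge("t0", "t1")

    def test_bh_adjustment_matches_hand_step_up(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(1, 100, size=(8, 5))  # 10 taxon pairs
        table = make_table(rows)
        g = network.correlation_network(table, rho_min=0.0, q_max=1.01)
        rel = rows / rows.sum(axis=1, keepdims=True)
        pvals, pairs = [], []
        for i, j in itertools.combinations(range(5), 2):
            pvals.append(stats.spearmanr(rel[:, i], rel[:, j]).pvalue)
            pairs.append((f"t{i}", f"t{j}"))
        expected_q = hand_bh(np.array(pvals))
        for (u, v), q in zip(pairs, expected_q):
            assert g.edges[u, v]["q"] == pytest.approx(q, rel=1e-9)

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(1, 100, size=(10, 6))
        table = make_table(rows)
        full = network.correlation_network(table, rho_min=0.0, q_max=1.01)
        assert full.number_of_edges() == 15  # complete correlation graph
        strict = network.correlation_network(table, rho_min=0.8, q_max=0.01)
        assert set(strict.edges()) <= set(full.edges())

    def test_retained_edges_satisfy_both_gates(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=12)
        rows = np.abs(
            np.array([base + rng.normal(scale=0.05, size=12) for _ in range(6)])
        ).T * 100 + 1
        g = network.correlation_network(make_table(rows.astype(int)), rho_min=0.8, q_max=0.01)
        for _, _, d in g.edges(data=True):
            assert abs(d["rho"]) >= 0.8
            assert d["q"] < 0.01


class TestModulesAndRoles:
    def planted_graph(self):
        g = nx.Graph()
        for offset, names in ((0, "abcde"), (0, "vwxyz")):
            for u, v in itertools.combinations(names, 2):
                g.add_edge(u, v)
        g.add_edge("a", "v")  # bridge
        return g

    def test_two_cliques_recovered(self):
        mods = network.detect_modules(self.planted_graph(), seed=0)
        assert len(set(mods.values())) == 2
        assert len({mods[c] for c in "abcde"}) == 1
        assert len({mods[c] for c in "vwxyz"}) == 1

    def test_single_clique_single_module(self):
        mods = network.detect_modules(nx.complete_graph(6), seed=0)
        assert len(set(mods.values())) == 1

    def test_determinism(self):
        g = nx.barabasi_albert_graph(40, 3, seed=5)
        assert network.detect_modules(g, seed=3) == network.detect_modules(g, seed=3)

    def test_edgeless_graph_warns(self):
        g = nx.empty_graph(4)
        with pytest.warns(UserWarning, match="edgeless"):
            mods = network.detect_modules(g)
        assert len(set(mods.values())) == 4

    def test_participation_identities(self):
        g = self.planted_graph()
        mods = network.detect_modules(g, seed=0)
        roles = network.node_roles(g, mods)
        assert roles.loc["b", "pi"] == 0.0  # all edges inside own module
        # bridge endpoint: degree 5, 4 within + 1 across → Pi = 1 − (16+1)/25
        assert roles.loc["a", "pi"] == pytest.approx(1 - (16 + 1) / 25)

    def test_even_split_participation(self):
        g = nx.Graph([("hub", "m1"), ("hub", "m2")])
        roles = network.node_roles(g, {"hub": 0, "m1": 0, "m2": 1})
        assert roles.loc["hub", "pi"] == pytest.approx(0.5)

    def test_star_center_is_module_hub(self):
        g = nx.star_graph(12)
        roles = network.node_roles(g, {n: 0 for n in g.nodes()})
        assert roles.loc[0, "zi"] >= 2.5
        assert roles.loc[0, "role"] == "module_hub"
        assert roles.loc[0, "keystone"]

    def test_role_partition_exhaustive_and_exclusive(self):
        g = nx.barabasi_albert_graph(60, 3, seed=2)
        roles = network.node_roles(g, network.detect_modules(g, seed=2))
        assert set(roles["role"]) <= {"peripheral", "connector", "module_hub", "network_hub"}
        assert roles["role"].notna().all()
        assert (roles["keystone"] == (roles["role"] != "peripheral")).all()


class TestRobustnessMeasures:
    def test_efficiency_closed_forms(self):
        assert network.efficiency(nx.complete_graph(7)) == pytest.approx(1.0)
        assert network.efficiency(nx.path_graph(3)) == pytest.approx(5 / 6)

    def test_natural_connectivity_k3(self):
        # adjacency spectrum of K3 is {2, −1, −1}
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert network.natural_connectivity(nx.complete_graph(3)) == pytest.approx(expected)

    def test_molloy_reed_k4(self):
        assert network.molloy_reed_fraction(nx.complete_graph(4)) == pytest.approx(0.5)

    def test_empty_graph_conventions(self):
        g = nx.empty_graph(0)
        assert network.efficiency(g) == 0.0
        assert network.natural_connectivity(g) == 0.0
        assert network.molloy_reed_fraction(g) == 0.0

    def test_natural_connectivity_decreases_under_edge_deletion(self):
        """Exhaustive spectral check over every 4-node graph."""
        nodes = range(4)
        all_edges = list(itertools.combinations(nodes, 2))
        for mask in range(64):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(e for b, e in enumerate(all_edges) if mask >> b & 1)
            nc = network.natural_connectivity(g)
            for e in list(g.edges()):
                h = g.copy()
                h.remove_edge(*e)
                assert network.natural_connectivity(h) <= nc + 1e-12


class TestRobustnessCurves:
    def test_targeted_removal_at_least_as_damaging(self):
        g = nx.barabasi_albert_graph(60, 2, seed=1)
        grid = np.linspace(0.0, 0.8, 9)
        targeted = network.robustness(g, "node_degree_high", "Eff", grid=grid)
        random = network.robustness(g, "node_rand", "Eff", grid=grid, n_reps=50, seed=0)
        assert np.trapezoid(targeted.values, grid) <= np.trapezoid(random.values, grid)

    def test_edge_strong_removes_heaviest_first(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("b", "c", weight=0.5)
        g.add_edge("c", "a", weight=0.2)
        curve = network.robustness(
            g, "edge_strong", "Eff", grid=np.array([0.0, 1 / 3]), seed=0
        )
        # after removing a–b the graph is the path a–c–b
        assert curve.values[1] == pytest.approx(network.efficiency(nx.path_graph(3)))

    def test_random_strategies_deterministic_under_seed(self):
        g = nx.barabasi_albert_graph(30, 2, seed=3)
        a = network.robustness(g, "node_rand", "Eigen", n_reps=5, seed=9)
        b = network.robustness(g, "node_rand", "Eigen", n_reps=5, seed=9)
        assert np.allclose(a.values, b.values)

    def test_bad_grid_rejected(self):
        g = nx.complete_graph(4)
        with pytest.raises(ValueError):
            network.robustness(g, "node_rand", "Eff", grid=np.array([0.5, 0.2]))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            network.robustness(nx.complete_graph(3), "node_strongest", "Eff")


class TestCohesion:
    def test_uniform_samples_give_zero_cohesion(self):
        # every abundance equal → observed and null correlations both vanish
        rel = pd.DataFrame(np.full((6, 4), 0.25))
        coh = network.cohesion(rel, n_null=50, seed=0)
        assert np.allclose(coh.to_numpy(), 0.0)

    def test_sign_contract_over_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raw = rng.dirichlet(np.ones(8), size=6)
            coh = network.cohesion(pd.DataFrame(raw), n_null=50, seed=seed)
            assert (coh["positive_cohesion"] >= -1e-12).all()
            assert (coh["negative_cohesion"] <= 1e-12).all()

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(11)
        rel = pd.DataFrame(rng.dirichlet(np.ones(6), size=7))
        coh = network.cohesion(rel, n_null=100, seed=4)
        perm = [3, 1, 4, 0, 6, 2, 5]
        coh_perm = network.cohesion(rel.iloc[perm], n_null=100, seed=4)
        merged = coh.join(coh_perm, lsuffix="_a", rsuffix="_b")
        assert np.allclose(
            merged["positive_cohesion_a"], merged["positive_cohesion_b"], atol=0.05
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            network.cohesion(pd.DataFrame(np.eye(3)))
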