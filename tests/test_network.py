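import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizoassembly import (
    CountTable,
    SimulationConfig,
    build_network,
    keystone_taxa,
    prevalence_filter,
    rmt_threshold,
    simulate_dataset,
    spearman_matrix,
    topology,
)
from rhizoassembly.network import CooccurrenceNetwork


def _table(rows, taxa=None):
    rows = np.asarray(rows)
    taxa = taxa or [f"t{i}" for i in range(rows.shape[1])]
    return CountTable(pd.DataFrame(
        rows, index=[f"s{i}" for i in range(rows.shape[0])], columns=taxa))


class TestPrevalenceFilter:
    def test_rare_prevalence_removed(self, rng):
        counts = rng.poisson(10, size=(12, 6)) + 1
        counts[:, 0] = 0
        counts[0, 0] = 50  # 1 of 12 samples < ceil(12/3) = 4
        t = prevalence_filter(_table(counts), min_rel=0.0,
                              min_prevalence_fraction=1 / 3)
        assert "t0" not in t.taxon_ids

    def test_both_rules_satisfied_kept(self, rng):
        counts = rng.poisson(20, size=(12, 5)) + 1
        counts[:, 0] = 0
        counts[:4, 0] = 60  # 4 of 12 samples, ~1% abundance
        t = prevalence_filter(_table(counts), min_rel=1e-4,
                              min_prevalence_fraction=1 / 3)
        assert "t0" in t.taxon_ids

    def test_zero_thresholds_identity(self, rng):
        t = _table(rng.poisson(5, size=(6, 8)) + 1)
        assert prevalence_filter(t, 0.0, 0.0) == t

    def test_too_few_survivors_is_error(self, rng):
        counts = np.zeros((9, 6), dtype=int)
        counts[:, 0] = 10
        counts[0, 1:] = 1
        with pytest.raises(ValueError, match="at least 4"):
            prevalence_filter(_table(counts), 0.0, 1 / 3)


class TestSpearman:
    def test_monotone_map_is_one(self, rng):
        x = rng.integers(0, 50, 8)
        t = _table(np.column_stack([x, 2 * x + 1, 50 - x]))
        rho, p = spearman_matrix(t)
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        assert rho.iloc[0, 2] == pytest.approx(-1.0)

    def test_tied_average_ranks(self):
        t = _table(np.column_stack([[1, 2, 2, 4, 5], [1, 3, 3, 5, 6]]))
        rho, _ = spearman_matrix(t)
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_taxon_flagged_as_zero(self, rng):
        cols = [rng.integers(0, 30, 6), np.full(6, 7), rng.integers(0, 30, 6)]
        rho, p = spearman_matrix(_table(np.column_stack(cols)))
        assert rho.iloc[1, 0] == 0.0
        assert p.iloc[1, 0] == 1.0

    def test_needs_five_samples(self):
        with pytest.raises(ValueError):
            spearman_matrix(_table(np.ones((4, 5), dtype=int)))


class TestRmtThreshold:
    def _block_rho(self, n_per_block=15, within=0.9, between=0.2, noise=0.03):
        rng = np.random.default_rng(1)
        n = 2 * n_per_block
        rho = np.full((n, n), between) + rng.normal(0, noise, (n, n))
        rho[:n_per_block, :n_per_block] = within + rng.normal(0, noise, (n_per_block,) * 2)
        rho[n_per_block:, n_per_block:] = within + rng.normal(0, noise, (n_per_block,) * 2)
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1, 1)

    def test_transition_lies_between_block_and_background(self):
        cut = rmt_threshold(self._block_rho())
        assert 0.2 < cut <= 0.9

    def test_identity_matrix_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="transition"):
            cut = rmt_threshold(np.eye(25))
        assert cut == pytest.approx(0.95)

    def test_permutation_invariance(self, rng):
        rho = self._block_rho()
        perm = rng.permutation(rho.shape[0])
        assert rmt_threshold(rho) == rmt_threshold(rho[np.ix_(perm, perm)])

    def test_small_matrix_recommends_fixed_threshold(self):
        with pytest.raises(ValueError, match="fixed threshold"):
            rmt_threshold(np.eye(10))


def _net_from_graph(g):
    for _, _, d in g.edges(data=True):
        d.setdefault("rho", 0.9)
        d.setdefault("sign", 1)
    return CooccurrenceNetwork(g, threshold_used=0.5)


class TestBuildAndTopology:
    def _ids(self, n):
        return [f"t{i}" for i in range(n)]

    def test_complete_graph_metrics(self):
        n = 5
        rho = pd.DataFrame(0.99, index=self._ids(n), columns=self._ids(n))
        p = pd.DataFrame(1e-6, index=self._ids(n), columns=self._ids(n))
        net = build_network(rho, p, threshold=0.5)
        topo = topology(net)
        assert topo.average_degree == pytest.approx(4.0)
        assert topo.average_clustering == pytest.approx(1.0)
        assert topo.n_components == 1

    def test_path_graph_betweenness(self):
        ids = self._ids(3)
        rho = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 1.0]],
            index=ids, columns=ids)
        p = pd.DataFrame(1e-6, index=ids, columns=ids)
        net = build_network(rho, p, threshold=0.5, fdr=None)
        nodes = net.node_table().set_index("taxon_id")
        assert nodes.loc["t1", "betweenness"] == pytest.approx(1.0)
        assert nodes.loc["t0", "betweenness"] == pytest.approx(0.0)

    def test_handshake_lemma(self, rng):
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        topo = topology(_net_from_graph(g))
        assert topo.average_degree == pytest.approx(
            2 * topo.n_edges / topo.n_nodes)

    def test_empty_edge_set_is_valid(self):
        ids = self._ids(5)
        rho = pd.DataFrame(np.eye(5), index=ids, columns=ids)
        p = pd.DataFrame(1.0, index=ids, columns=ids)
        net = build_network(rho, p, threshold=0.5)
        topo = topology(net)
        assert topo.n_edges == 0
        assert topo.average_degree == 0.0

    def test_fdr_gate_blocks_weak_p(self):
        ids = self._ids(5)
        rho = pd.DataFrame(0.9, index=ids, columns=ids)
        p = pd.DataFrame(0.5, index=ids, columns=ids)
        assert build_network(rho, p, 0.5, fdr=0.05).graph.number_of_edges() == 0
        assert build_network(rho, p, 0.5, fdr=None).graph.number_of_edges() == 10


class TestKeystone:
    def test_clique_plus_pendants_toy(self):
        """The cut vertex has top degree but also top betweenness and is
        excluded; zero-betweenness clique members are flagged."""
        g = nx.complete_graph(6)
        for i in range(4):
            g.add_edge(0, f"p{i}")
        g = nx.relabel_nodes(g, {i: f"c{i}" for i in range(6)})
        nodes = keystone_taxa(_net_from_graph(g)).set_index("taxon_id")
        assert not nodes.loc["c0", "keystone"]          # the cut vertex
        assert nodes.loc[[f"c{i}" for i in range(1, 6)], "keystone"].all()
        assert not nodes.loc[[f"p{i}" for i in range(4)], "keystone"].any()

    def test_keystone_subset_of_high_degree(self, rng):
        g = nx.gnp_random_graph(20, 0.3, seed=5)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        nodes = keystone_taxa(_net_from_graph(g))
        assert (nodes["keystone"] <= nodes["high_degree"]).all()
        assert nodes["keystone"].sum() >= 1

    def test_regular_graph_total_tie_flags_all(self):
        g = nx.cycle_graph(6)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        nodes = keystone_taxa(_net_from_graph(g))
        assert nodes["keystone"].all()

    def test_needs_five_nodes(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            keystone_taxa(_net_from_graph(g))


class TestPlantedModules:
    def test_modularity_exceeds_degree_preserving_rewirings(self):
        """Taxa filtered by four distinct environments co-vary in blocks,
        so the built network should be more modular than rewired nulls."""
        groups = [("P", "BS"), ("P", "RS"), ("P", "RP"), ("P", "ES")]
        cfg = SimulationConfig(
            n_taxa=60, n_samples_per_group=8,
            groups=groups, regime="selection",
            selection_strength=2.0, depth=4000, seed=8,
            demographic_noise=0.5,
            environments={g: e for g, e in zip(groups, [-3.0, -1.0, 1.0, 3.0])},
        )
        table, _, _, _, _ = simulate_dataset(cfg)
        keep = [t for t, s in table.data.sum(axis=0).items() if s > 0]
        rho, p = spearman_matrix(table.select_taxa(keep))
        net = build_network(rho, p, threshold=0.6, fdr=None)
        g = net.graph.copy()
        g.remove_nodes_from(list(nx.isolates(g)))
        assert g.number_of_edges() >= 50
        comm = nx.community.greedy_modularity_communities(g)
        obs = nx.community.modularity(g, comm)
        rng = np.random.default_rng(0)
        null = []
        n_swap = g.number_of_edges()
        for _ in range(100):
            h = g.copy()
            nx.double_edge_swap(h, nswap=n_swap, max_tries=200 * n_swap,
                                seed=int(rng.integers(2**31)))
            null.append(nx.community.modularity(
                h, nx.community.greedy_modularity_communities(h)))
        assert obs > np.mean(null)
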