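"""Centrality measures against closed forms and a brute-force oracle."""

import networkx as nx
import numpy as np
import pytest

from conftest import brute_force_centralities
from ucsig.network_rank import centralities, combined_rank, rank_genes
from ucsig.synth import synth_network


class TestClosedForms:
    def test_star_center_and_leaves(self, star_graph):
        raw = centralities(star_graph).set_index("node")
        assert raw.loc["A", "degree"] == 4
        assert raw.loc["A", "closeness"] == pytest.approx(1.0)
        assert raw.loc["A", "betweenness"] == pytest.approx(1.0)
        for leaf in "BCDE":
            assert raw.loc[leaf, "degree"] == 1
            assert raw.loc[leaf, "closeness"] == pytest.approx(0.625)
            assert raw.loc[leaf, "betweenness"] == 0.0

    def test_path_middle_node(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        raw = centralities(g).set_index("node")
        assert raw.loc["B", "betweenness"] == pytest.approx(1.0)
        assert raw.loc["A", "betweenness"] == 0.0
        assert raw.loc["C", "betweenness"] == 0.0

    def test_isolated_nodes_score_zero(self):
        g = nx.Graph([("A", "B")])
        g.add_node("LONER")
        raw = centralities(g).set_index("node")
        assert (raw.loc["LONER"] == 0).all()

    def test_empty_graph(self):
        assert len(centralities(nx.Graph())) == 0


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_graphs_match(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, 0.15, seed=seed)
        merged = centralities(g).merge(
            brute_force_centralities(g), on="node", suffixes=("", "_oracle"))
        assert len(merged) == g.number_of_nodes()
        for col in ("degree", "closeness", "betweenness"):
            np.testing.assert_allclose(merged[col], merged[f"{col}_oracle"], atol=1e-9)


class TestCombinedRank:
    def test_star_center_rank_one(self, star_graph):
        res = combined_rank(centralities(star_graph))
        assert res.table.iloc[0]["node"] == "A"
        assert res.table.iloc[0]["rank"] == 1

    def test_symmetric_nodes_share_rank(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])  # 4-cycle
        res = combined_rank(centralities(g))
        assert set(res.table["rank"]) == {1}
        # deterministic lexicographic order among ties
        assert list(res.table["node"]) == ["A", "B", "C", "D"]

    def test_combined_in_unit_interval_and_weighted(self):
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        res = combined_rank(centralities(g), weights=(1, 0, 0))
        assert ((res.table["combined"] >= 0) & (res.table["combined"] <= 1)).all()
        # with degree-only weights the ranking follows degree
        deg_order = res.table.sort_values(["degree", "node"], ascending=[False, True])
        assert list(deg_order["rank"]) == sorted(deg_order["rank"])

    def test_relabeling_invariance(self):
        g = nx.gnp_random_graph(25, 0.2, seed=5)
        mapping = {v: f"x{(v * 7) % 25:02d}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        s1 = sorted(combined_rank(centralities(g)).table["combined"].round(12))
        s2 = sorted(combined_rank(centralities(h)).table["combined"].round(12))
        assert s1 == s2

    def test_adding_edge_never_decreases_degree(self):
        g = nx.gnp_random_graph(15, 0.2, seed=7)
        raw1 = centralities(g).set_index("node")
        missing = [p for p in nx.non_edges(g)][0]
        g.add_edge(*missing)
        raw2 = centralities(g).set_index("node")
        assert raw2.loc[missing[0], "degree"] >= raw1.loc[missing[0], "degree"]


class TestPlantedHubs:
    def test_hubs_occupy_top_ranks(self):
        core = [f"g{i}" for i in range(40)]
        hubs = ["HUB1", "HUB2", "HUB3"]
        net = synth_network(core, n_noise_nodes=20, hub_ids=hubs, seed=1)
        res = rank_genes(net)
        assert set(res.table.head(len(hubs))["node"]) == set(hubs)

    def test_er_graph_never_fakes_a_hub(self):
        """Hub-free noise graphs produce no hub-like outlier: the combined
        score of every node stays within 4 sd of the mean (simulation-derived
        bound; with a planted hub the hub's z-score always exceeds it)."""
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            net = synth_network([f"g{i}" for i in range(30)], n_noise_nodes=10,
                                hub_ids=(), seed=seed, noise_edge_prob=0.15)
            scores = combined_rank(centralities(net)).table["combined"].to_numpy()
            if scores.std() == 0 or scores.max() <= scores.mean() + 4 * scores.std():
                ok += 1
        assert ok / n_seeds >= 0.95

    def test_planted_hub_exceeds_noise_zscores(self):
        """A planted hub sits further above the mean than any node of the
        equivalent hub-free graph (same seed, same noise regime)."""
        for seed in range(20):
            noise = synth_network([f"g{i}" for i in range(30)], n_noise_nodes=10,
                                  hub_ids=(), seed=seed, noise_edge_prob=0.15)
            s0 = combined_rank(centralities(noise)).table["combined"].to_numpy()
            z_noise = (s0.max() - s0.mean()) / s0.std()
            hubbed = synth_network([f"g{i}" for i in range(30)], n_noise_nodes=10,
                                   hub_ids=("HUB1",), seed=seed, noise_edge_prob=0.15)
            t = combined_rank(centralities(hubbed)).table
            s1 = t["combined"].to_numpy()
            z_hub = (t.set_index("node").loc["HUB1", "combined"] - s1.mean()) / s1.std()
            assert z_hub > z_noise

    def test_confidence_weighting_changes_degree_scale(self):
        net = synth_network([f"g{i}" for i in range(10)], 0, ("HUB1",), seed=2)
        weighted = centralities(net, use_confidence_weights=True).set_index("node")
        assert weighted.loc["HUB1", "degree"] == pytest.approx(0.9 * 9)
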