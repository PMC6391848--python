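"""Network topology: centralities vs brute force, power law, Kruskal-Wallis."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import DERecord
from cernet.network import (
    PowerLawFit,
    betweenness_centrality,
    build_network,
    centrality_table,
    closeness_centrality,
    compare_centrality,
    degree_centrality,
    degree_histogram,
    export_network,
    fit_power_law,
    power_law_mle_exponent,
)
from cernet.triplets import CeRNATriplet

from _oracles import (
    brute_betweenness,
    brute_closeness,
    kw_h_statistic,
    kw_permutation_pvalue,
    ols_loglog,
)


def de(ids, fc=1.0):
    return [DERecord(i, "mRNA", fc, 1e-5) for i in ids]


def random_graph(rng, n_max=12):
    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < 0.3:
            g.add_edge(u, v)
    return g


class TestBuildNetwork:
    def test_single_triplet(self):
        g = build_network([CeRNATriplet("L1", "m1", "gA")], de(["L1", "m1", "gA"]))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_shared_edge_not_duplicated(self):
        trips = [CeRNATriplet("L1", "m1", "gA"), CeRNATriplet("L2", "m1", "gA")]
        g = build_network(trips, de(["L1", "L2", "m1", "gA"]))
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3

    def test_empty(self):
        g = build_network([], [])
        assert g.number_of_nodes() == 0

    def test_missing_de_record_rejected(self):
        with pytest.raises(ValueError, match="no DE record"):
            build_network([CeRNATriplet("L1", "m1", "gA")], de(["L1", "m1"]))

    def test_edges_only_touch_mirnas(self, clean_bundle):
        _, truth, _ = clean_bundle
        trips = [CeRNATriplet(*t) for t in truth.planted_triplets]
        ids = {x for t in truth.planted_triplets for x in t}
        g = build_network(trips, de(sorted(ids)))
        for u, v in g.edges:
            classes = {g.nodes[u]["rna_class"], g.nodes[v]["rna_class"]}
            assert "miRNA" in classes and len(classes) == 2


class TestCentralities:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        assert degree_centrality(g) == {"A": 1, "B": 2, "C": 1}
        bc = betweenness_centrality(g)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}
        cc = closeness_centrality(g)
        assert cc["B"] == pytest.approx(1.0)
        assert cc["A"] == pytest.approx(2 / 3)

    def test_star_center_degree(self):
        g = nx.star_graph(5)
        assert degree_centrality(g)[0] == 5

    def test_four_cycle_betweenness(self):
        bc = betweenness_centrality(nx.cycle_graph(4))
        assert all(v == pytest.approx(0.5) for v in bc.values())

    def test_complete_graph_closeness(self):
        cc = closeness_centrality(nx.complete_graph(5))
        assert all(v == pytest.approx(1.0) for v in cc.values())

    def test_disconnected_closeness_is_per_component(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        cc = closeness_centrality(g)
        oracle = brute_closeness(list(g.nodes), list(g.edges))
        for n in g.nodes:
            assert cc[n] == pytest.approx(oracle[n])

    def test_random_graphs_match_bruteforce(self, rng):
        for _ in range(30):
            g = random_graph(rng)
            nodes, edges = list(g.nodes), list(g.edges)
            bc, cc, dc = betweenness_centrality(g), closeness_centrality(g), degree_centrality(g)
            bc_o, cc_o = brute_betweenness(nodes, edges), brute_closeness(nodes, edges)
            for n in nodes:
                assert bc[n] == pytest.approx(bc_o[n], abs=1e-9)
                assert cc[n] == pytest.approx(cc_o[n], abs=1e-9)
                assert dc[n] == sum(n in e for e in edges)
            assert sum(dc.values()) == 2 * len(edges)

    def test_mirnas_carry_the_most_betweenness(self, clean_bundle):
        # every lncRNA-mRNA path crosses a miRNA in the tripartite topology
        _, truth, _ = clean_bundle
        trips = [CeRNATriplet(*t) for t in truth.planted_triplets]
        ids = {x for t in truth.planted_triplets for x in t}
        g = build_network(trips, de(sorted(ids)))
        table = centrality_table(g)
        means = table.groupby("rna_class")["bc"].mean()
        assert means["miRNA"] >= means["lncRNA"]
        assert means["miRNA"] >= means["mRNA"]


class TestPowerLaw:
    def test_exact_power_law_recovered(self):
        ks = np.arange(1, 6)
        hist = pd.DataFrame({"k": ks, "n_k": np.round(1000.0 * ks ** -2.0)})
        fit = fit_power_law(hist)
        assert fit.slope == pytest.approx(-2.0, abs=0.01)
        assert fit.r_squared > 0.999
        assert fit.n_points == 5

    def test_flat_histogram_has_zero_slope(self):
        hist = pd.DataFrame({"k": [1, 2, 4, 8], "n_k": [5, 5, 5, 5]})
        fit = fit_power_law(hist)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            g = random_graph(rng, n_max=15)
            hist = degree_histogram(g)
            if len(hist) < 2:
                continue
            fit = fit_power_law(g)
            slope_o, r2_o = ols_loglog(hist["k"], hist["n_k"])
            assert fit.slope == pytest.approx(slope_o, abs=1e-9)
            assert fit.r_squared == pytest.approx(r2_o, abs=1e-9)

    def test_single_degree_value_rejected(self):
        with pytest.raises(ValueError, match="distinct degree"):
            fit_power_law(nx.complete_graph(4))

    def test_mle_exponent_positive_on_heavy_tail(self):
        g = nx.barabasi_albert_graph(200, 2, seed=1)
        assert power_law_mle_exponent(g, k_min=2) > 1.0


class TestKruskalWallis:
    @staticmethod
    def table(groups):
        rows = []
        for cls, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append({"rna_class": cls, "dc": v, "bc": v, "cc": v})
        return pd.DataFrame(rows)

    def test_hand_computed_h(self):
        t = self.table({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        res = compare_centrality(t, metrics=("dc",))[0]
        assert res.h_statistic == pytest.approx(12 / 42 * (2 * 4 + 0 + 2 * 4))
        assert res.df == 2
        assert res.h_statistic == pytest.approx(kw_h_statistic([[1, 2], [3, 4], [5, 6]]))

    def test_pvalue_close_to_exact_permutation(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        t = self.table({"a": groups[0], "b": groups[1], "c": groups[2]})
        res = compare_centrality(t, metrics=("dc",))[0]
        exact = kw_permutation_pvalue(groups)
        # chi-square approximation at n=6 vs the exhaustive permutation law
        assert res.pvalue == pytest.approx(exact, abs=0.08)

    def test_identical_groups_give_null_result(self):
        t = self.table({"a": [2, 2], "b": [2, 2], "c": [2, 2]})
        res = compare_centrality(t, metrics=("bc",))[0]
        assert res.h_statistic == 0.0 and res.pvalue == 1.0

    def test_invariant_to_monotone_transform(self):
        t1 = self.table({"a": [1, 2, 3], "b": [4, 5, 6]})
        t2 = self.table({"a": [10, 20, 30], "b": [40, 50, 60]})
        r1 = compare_centrality(t1, metrics=("cc",))[0]
        r2 = compare_centrality(t2, metrics=("cc",))[0]
        assert r1.h_statistic == pytest.approx(r2.h_statistic)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 RNA classes"):
            compare_centrality(self.table({"a": [1, 2, 3]}))


class TestExport:
    @staticmethod
    def toy():
        trips = [CeRNATriplet("L1", "m1", "gA")]
        g = build_network(trips, de(["L1", "m1", "gA"]))
        return g, centrality_table(g)

    def test_sif_has_one_line_per_edge(self, tmp_path):
        g, _ = self.toy()
        export_network(g, tmp_path / "n.sif", "sif")
        lines = (tmp_path / "n.sif").read_text().splitlines()
        assert len(lines) == 2
        assert {ln.split("\t")[1] for ln in lines} == {"lncRNA-miRNA", "miRNA-mRNA"}

    def test_graphml_round_trip(self, tmp_path):
        g, table = self.toy()
        export_network(g, tmp_path / "n.graphml", "graphml", table=table)
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert set(back.nodes) == set(g.nodes) and set(map(frozenset, back.edges)) == set(
            map(frozenset, g.edges)
        )
        for n in g.nodes:
            assert back.nodes[n]["rna_class"] == g.nodes[n]["rna_class"]
            assert back.nodes[n]["dc"] == int(table.loc[n, "dc"])

    def test_whitespace_ids_survive_graphml(self, tmp_path):
        g = nx.Graph()
        g.add_edge("node one", "node\ttwo")
        nxpath = tmp_path / "w.graphml"
        export_network(g, nxpath, "graphml")
        back = nx.read_graphml(nxpath)
        assert set(back.nodes) == {"node one", "node\ttwo"}

    def test_sif_rejects_tab_in_id(self, tmp_path):
        g = nx.Graph()
        g.add_edge("a\tb", "c")
        with pytest.raises(ValueError, match="SIF"):
            export_network(g, tmp_path / "n.sif", "sif")

    def test_unknown_format_rejected(self, tmp_path):
        g, table = self.toy()
        with pytest.raises(ValueError, match="format"):
            export_network(g, tmp_path / "x", "gexf", table=table)
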