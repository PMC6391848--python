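"""Hypergeometric enrichment, Holm correction, kappa grouping, lncRNA transfer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from cernet.enrichment import (
    GeneSetCollection,
    annotate_lncrnas,
    enrich,
    holm_adjust,
    hypergeom_two_sided,
    kappa_score,
)
from cernet.simulate import PLANTED_SET_NAME, generate_genesets, generate_sequences
from cernet.triplets import CeRNATriplet

from _oracles import kappa_from_contingency
from test_simulate import small_config


class TestHypergeom:
    def test_hand_summed_upper_tail(self):
        # N=10, K=4, n=5, k=4: P(X>=4) = C(4,4)C(6,1)/C(10,5) = 6/252
        assert float(hypergeom.sf(3, 10, 4, 5)) == pytest.approx(6 / 252)
        assert hypergeom_two_sided(5, 4, 4, 10) == pytest.approx(2 * 6 / 252)

    def test_term_equals_universe_is_certain(self):
        assert hypergeom_two_sided(5, 10, 5, 10) == 1.0

    def test_central_overlap_caps_at_one(self):
        # k at the expectation: both tails > 0.5, doubled and capped
        assert hypergeom_two_sided(5, 4, 2, 10) == 1.0

    def test_pmf_consistency(self):
        for N, K, n in [(10, 4, 5), (30, 10, 7), (50, 25, 25)]:
            ks = np.arange(0, min(K, n) + 1)
            pmf = hypergeom.pmf(ks, N, K, n)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
            for k in ks:
                upper = hypergeom.sf(k - 1, N, K, n)
                lower = hypergeom.cdf(k, N, K, n)
                assert upper == pytest.approx(1 - lower + hypergeom.pmf(k, N, K, n), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_two_sided(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_two_sided(11, 4, 2, 10)


class TestHolm:
    def test_worked_triple(self):
        assert holm_adjust([0.011, 0.02, 0.04]) == pytest.approx([0.033, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == [0.3]

    def test_all_ones_stay_one(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_by_raw_and_bonferroni_and_matches_statsmodels(self, ps):
        adj = holm_adjust(ps)
        m = len(ps)
        ref = multipletests(ps, method="holm")[1]
        for a, p, r in zip(adj, ps, ref):
            assert p <= a <= min(1.0, m * p) + 1e-12
            assert a == pytest.approx(r, abs=1e-12)


class TestKappa:
    def test_identical_sets(self):
        u = {f"g{i}" for i in range(30)}
        a = {f"g{i}" for i in range(10)}
        assert kappa_score(a, set(a), u) == 1.0

    def test_complementary_halves_are_perfect_disagreement(self):
        u = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(50)}
        b = u - a
        assert kappa_score(a, b, u) == pytest.approx(-1.0)

    @given(
        a=st.sets(st.integers(0, 19), min_size=1),
        b=st.sets(st.integers(0, 19), min_size=1),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_contingency_oracle_and_is_symmetric(self, a, b):
        u = set(range(20))
        a = {f"g{i}" for i in a}
        b = {f"g{i}" for i in b}
        u = {f"g{i}" for i in u}
        k = kappa_score(a, b, u)
        assert k == pytest.approx(kappa_from_contingency(a, b, u), abs=1e-12)
        assert k == pytest.approx(kappa_score(b, a, u), abs=1e-12)


class TestEnrich:
    @staticmethod
    def collection():
        universe = {f"g{i}" for i in range(40)}
        sets = {
            "T1": ("d", [f"g{i}" for i in range(10)]),
            "T2": ("d", [f"g{i}" for i in range(10)]),  # identical to T1
            "T3": ("d", [f"g{i}" for i in range(20, 30)]),
        }
        return GeneSetCollection.from_sets(sets, universe=universe)

    def test_identical_enriched_terms_share_group(self):
        coll = self.collection()
        query = {f"g{i}" for i in range(10)}
        res = enrich(query, coll, p_adj_cutoff=0.05)
        by_term = {r.term: r for r in res}
        assert {"T1", "T2"} <= set(by_term)
        assert by_term["T1"].group_id == by_term["T2"].group_id

    def test_extreme_kappa_thresholds(self):
        coll = self.collection()
        query = {f"g{i}" for i in range(10)}
        singles = enrich(query, coll, p_adj_cutoff=1.0, kappa_threshold=1.0 + 1e-9)
        assert len({r.group_id for r in singles}) == len(singles)
        merged = enrich(query, coll, p_adj_cutoff=1.0, kappa_threshold=-1.0)
        assert len({r.group_id for r in merged}) == 1

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enrich({"g1"}, GeneSetCollection(sets={}, universe=frozenset({"g1"})))

    def test_padj_dominates_praw(self):
        res = enrich({f"g{i}" for i in range(10)}, self.collection(), p_adj_cutoff=1.0)
        assert all(r.p_adj >= r.p_raw for r in res)

    def test_planted_set_is_top_hit_across_seeds(self):
        """The planted gene set attains the minimum adjusted p, below 0.05,
        when the query is the set of planted up-regulated mRNAs."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = small_config(rng_seed=seed, n_mrna=120)
            _, truth = generate_sequences(cfg)
            sets = generate_genesets(truth, n_sets=15, rng_seed=seed)
            coll = GeneSetCollection.from_sets(sets, universe=set(truth.all_ids["mRNA"]))
            query = {g for g, fc in truth.planted_de_ids["mRNA"] if fc > 0}
            res = enrich(query, coll, p_adj_cutoff=1.0)
            best = min(res, key=lambda r: r.p_adj)
            if best.term == PLANTED_SET_NAME and best.p_adj < 0.05:
                wins += 1
        assert wins / n_seeds >= 0.9

    def test_random_queries_rarely_enrich(self):
        """Holm control: random queries yield at most one positive call in
        total across 20 seeds at p_adj <= 0.05."""
        total = 0
        rng = np.random.default_rng(1)
        cfg = small_config(rng_seed=0, n_mrna=120)
        _, truth = generate_sequences(cfg)
        universe = list(truth.all_ids["mRNA"])
        for seed in range(20):
            sets = generate_genesets(truth, n_sets=15, rng_seed=seed + 100)
            sets.pop(PLANTED_SET_NAME)  # keep only null sets
            coll = GeneSetCollection.from_sets(sets, universe=set(universe))
            query = set(rng.choice(universe, size=25, replace=False))
            total += len(enrich(query, coll, p_adj_cutoff=0.05))
        assert total <= 1


class TestAnnotateLncrnas:
    @staticmethod
    def results():
        from cernet.enrichment import EnrichmentResult

        return [
            EnrichmentResult(term="T", overlap=["gA"], k=1, K=5, n=2, N=40,
                             p_raw=0.001, p_adj=0.003, group_id=1)
        ]

    def test_single_path_transfer(self):
        ann = annotate_lncrnas([CeRNATriplet("L1", "m1", "gA")], self.results())
        assert ann == {"L1": ["T"]}

    def test_lncrna_without_triplets_absent(self):
        ann = annotate_lncrnas([CeRNATriplet("L1", "m1", "gA")], self.results())
        assert "L2" not in ann

    def test_transfer_through_shared_mirna(self):
        trips = [
            CeRNATriplet("L1", "m1", "gA"),
            CeRNATriplet("L2", "m1", "gB"),  # L2 shares m1, inherits gA's term
            CeRNATriplet("L3", "m2", "gB"),  # m2 reaches only gB, no terms
        ]
        ann = annotate_lncrnas(trips, self.results())
        assert ann["L1"] == ["T"] and ann["L2"] == ["T"] and ann["L3"] == []


class TestGmtIo:
    def test_round_trip_and_universe_default(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tg1\tg2\nS2\tdesc\tg2\tg3\n")
        coll = GeneSetCollection.from_gmt(p)
        assert set(coll.universe) == {"g1", "g2", "g3"}
        assert coll.sets["S1"][1] == frozenset({"g1", "g2"})

    def test_members_outside_universe_dropped(self, tmp_path, caplog):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tg1\tg9\n")
        coll = GeneSetCollection.from_gmt(p, universe={"g1", "g2"})
        assert coll.sets["S1"][1] == frozenset({"g1"})

    def test_truncated_line_rejected(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tonly-description\n")
        with pytest.raises(ValueError, match="GMT"):
            GeneSetCollection.from_gmt(p)
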