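"""Hypergeometric tail, BH step-up and the enrichment wrapper."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import exact_hypergeom_tail
from ucsig._errors import UsageError
from ucsig.enrichment import bh_adjust, enrich, hypergeom_tail
from ucsig.synth import synth_genesets
from ucsig.types import GeneSetCollection


class TestHypergeomTail:
    def test_exact_worked_example(self):
        # N=20, K=5, n=5, k=3: tail sum C(5,j)C(15,5-j)/C(20,5) = 1126/15504
        expected = exact_hypergeom_tail(3, 20, 5, 5)
        assert expected == pytest.approx(1126 / 15504)
        assert hypergeom_tail(3, 20, 5, 5) == pytest.approx(float(expected), abs=1e-12)

    def test_zero_hits_gives_one(self):
        assert hypergeom_tail(0, 100, 10, 5) == 1.0

    @settings(derandomize=True, max_examples=25)
    @given(st.data())
    def test_matches_exact_rational_oracle(self, data):
        N = data.draw(st.integers(5, 60))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeom_tail(k, N, K, n) == pytest.approx(
            float(exact_hypergeom_tail(k, N, K, n)), rel=1e-9
        )


class TestBH:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.04, 0.04, 0.04]) == pytest.approx([0.04] * 3)

    def test_never_below_input_and_capped_at_one(self):
        p = np.random.default_rng(0).uniform(size=20)
        fdr = bh_adjust(p)
        assert (fdr >= p - 1e-12).all() and (fdr <= 1.0).all()

    def test_monotone_in_rank(self):
        p = np.random.default_rng(1).uniform(size=50)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestEnrich:
    def collection(self):
        return GeneSetCollection(
            sets={
                "T1": ("hit term", {f"g{i}" for i in range(5)}),
                "T2": ("cold term", {f"g{i}" for i in range(10, 15)}),
                "TINY": ("too small", {"g0", "zz_outside"}),
            }
        )

    def test_worked_example_row(self):
        universe = [f"g{i}" for i in range(20)]
        query = ["g0", "g1", "g2", "g17", "g18"]
        res = enrich(query, universe, self.collection())
        row = res.table.set_index("term_id").loc["T1"]
        assert (row["k"], row["K"], row["n"], row["N"]) == (3, 5, 5, 20)
        assert row["p_value"] == pytest.approx(1126 / 15504)
        assert row["gene_ratio"] == pytest.approx(0.6)

    def test_zero_hit_terms_reported_with_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = enrich(["g0", "g1"], universe, self.collection())
        assert res.table.set_index("term_id").loc["T2", "p_value"] == 1.0

    def test_small_terms_skipped_and_query_trimmed(self):
        universe = [f"g{i}" for i in range(20)]
        res = enrich(["g0", "not_in_universe"], universe, self.collection(), min_term_size=3)
        assert "TINY" not in set(res.table["term_id"])
        assert res.table["n"].iloc[0] == 1  # trimmed query size

    def test_empty_universe_rejected(self):
        with pytest.raises(UsageError):
            enrich(["g1"], [], self.collection())

    def test_gene_ratio_formula(self):
        # 10 hits in a 50-gene expressed term -> ratio 0.20
        universe = [f"g{i}" for i in range(200)]
        coll = GeneSetCollection(sets={"T": ("big", {f"g{i}" for i in range(50)})})
        res = enrich([f"g{i}" for i in range(10)], universe, coll)
        assert res.table["gene_ratio"].iloc[0] == pytest.approx(0.20)

    def test_planted_term_ranks_first(self):
        universe = [f"g{i}" for i in range(500)]
        query = [f"g{i}" for i in range(25)]
        coll = synth_genesets(universe, query[:20], n_terms=15, seed=3)
        res = enrich(query, universe, coll)
        assert res.table["term_id"].iloc[0] == "TERM_PLANTED"

    def test_monte_carlo_agreement(self):
        """Hypergeometric tails match a permutation oracle within 3 MC sd."""
        rng = np.random.default_rng(42)
        n_draws = 20_000
        for _ in range(5):
            N = int(rng.integers(15, 40))
            K = int(rng.integers(3, N // 2 + 2))
            n = int(rng.integers(3, N // 2 + 2))
            k = int(rng.integers(1, min(K, n) + 1))
            universe = np.arange(N)
            hits = sum(
                (np.isin(rng.choice(universe, size=n, replace=False), np.arange(K)).sum() >= k)
                for _ in range(n_draws)
            )
            p_mc = hits / n_draws
            p = hypergeom_tail(k, N, K, n)
            sd = max(np.sqrt(p * (1 - p) / n_draws), 1e-4)
            assert abs(p - p_mc) < 3 * sd + 1e-9
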