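import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metasense.asrna_stats import (
    BinomialTestConfig,
    asrna_fraction_histogram,
    bh_adjust,
    binom_upper_p,
    call_asrna,
    genome_fraction_significant,
    percent_asrna_per_sample,
    rank_abundance,
)
from metasense.core_io import GeneRecord


def binom_upper_oracle(k, n, q):
    """Brute-force pmf summation P(X >= k)."""
    return sum(math.comb(n, j) * q**j * (1 - q) ** (n - j) for j in range(k, n + 1))


def bh_oracle(p):
    """Naive quadratic BH: adj_i = min over ranks j >= rank_i of p_(j) * m / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBinomUpper:
    def test_zero_antisense_gives_p_one(self):
        assert binom_upper_p(0, 50, 0.01) == 1.0

    def test_all_antisense_closed_form(self):
        assert binom_upper_p(10, 10, 0.5) == pytest.approx(0.5**10, rel=1e-12)

    def test_frozen_oracle_value(self):
        # k=5, n=100, q=0.01, from brute-force pmf summation
        assert binom_upper_p(5, 100, 0.01) == pytest.approx(3.432321587754513e-3, rel=1e-9)

    @pytest.mark.parametrize("n", [1, 7, 63, 500])
    def test_matches_pmf_summation(self, n):
        rng = np.random.default_rng(n)
        for q in (0.01, 0.05, 0.3):
            for k in sorted(set(int(x) for x in rng.integers(0, n + 1, 6))):
                assert binom_upper_p(k, n, q) == pytest.approx(
                    binom_upper_oracle(k, n, q), abs=1e-10
                )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binom_upper_p(1, 10, 0.0)
        with pytest.raises(ValueError):
            binom_upper_p(11, 10, 0.1)


class TestBhAdjust:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.07] * 5), 0.07)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_quadratic_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_oracle_at_scale(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=2000)
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCalls:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "sample_id", "sense", "antisense"])

    def test_enrichment_boundary_at_95pct(self):
        t = self._table([("a", "s", 5, 95), ("b", "s", 6, 94)])
        calls = call_asrna(t).set_index("gene_id")
        assert calls.loc["a", "antisense_enriched"].item() is True
        assert calls.loc["b", "antisense_enriched"].item() is False

    def test_zero_antisense_never_significant(self):
        t = self._table([("a", "s", 500, 0)])
        calls = call_asrna(t)
        assert calls["p_raw"].iloc[0] == 1.0
        assert not calls["significant"].iloc[0]

    def test_zero_total_observation_is_error(self):
        with pytest.raises(ValueError, match="zero total"):
            call_asrna(self._table([("a", "s", 0, 0)]))

    def test_adjusted_p_at_least_raw(self, toy_counts):
        calls = call_asrna(toy_counts[toy_counts.sense + toy_counts.antisense > 0])
        assert (calls["p_adj"] >= calls["p_raw"] - 1e-15).all()

    def test_raising_q_never_gains_significance(self, small_community):
        _, _, _, _, _, counts = small_community
        t = counts[(counts["sense"] + counts["antisense"]) > 0]
        lo = call_asrna(t, BinomialTestConfig(q=0.01))
        hi = call_asrna(t, BinomialTestConfig(q=0.05))
        assert (hi["p_raw"] >= lo["p_raw"] - 1e-12).all()
        assert not (hi["significant"] & ~lo["significant"]).any()

    def test_raising_alpha_never_shrinks_significant_set(self, small_community):
        _, _, _, _, _, counts = small_community
        t = counts[(counts["sense"] + counts["antisense"]) > 0]
        strict = call_asrna(t, BinomialTestConfig(alpha_adj=0.01))
        lax = call_asrna(t, BinomialTestConfig(alpha_adj=0.05))
        assert not (strict["significant"] & ~lax["significant"]).any()

    def test_bh_family_within_sample_by_default(self):
        # a second sample full of tiny p-values must not change sample s1's p_adj
        base = self._table([("a", "s1", 90, 10), ("b", "s1", 80, 20)])
        extra = self._table([(f"g{i}", "s2", 0, 100) for i in range(20)])
        alone = call_asrna(base).set_index(["gene_id", "sample_id"])["p_adj"]
        joint = call_asrna(pd.concat([base, extra], ignore_index=True)).set_index(
            ["gene_id", "sample_id"]
        )["p_adj"]
        for key in alone.index:
            assert joint.loc[key] == pytest.approx(alone.loc[key])


class TestSummaries:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "sample_id", "sense", "antisense"])

    @pytest.mark.parametrize(
        "sense,antisense,expected", [(100, 0, 0.0), (0, 100, 100.0), (90, 10, 10.0)]
    )
    def test_percent_asrna(self, sense, antisense, expected):
        t = self._table([("g", "s", sense, antisense)])
        assert percent_asrna_per_sample(t)["s"] == pytest.approx(expected)

    def test_rank_abundance_cumulative_curve(self):
        t = self._table([("a", "s", 0, 50), ("b", "s", 0, 30), ("c", "s", 0, 20)])
        curve = rank_abundance(t, "antisense")
        assert np.allclose(curve["cumulative_pct"], [50, 80, 100])

    def test_rank_abundance_single_gene(self):
        curve = rank_abundance(self._table([("a", "s", 0, 7)]), "antisense")
        assert list(curve["cumulative_pct"]) == [100.0]

    def test_rank_abundance_ties_broken_by_gene_id(self):
        t = self._table([("b", "s", 0, 10), ("a", "s", 0, 10)])
        curve = rank_abundance(t, "antisense")
        assert list(curve["gene_id"]) == ["a", "b"]
        assert np.allclose(curve["cumulative_pct"], [50, 100])

    def test_rank_abundance_monotone_ending_at_100(self, small_community):
        _, _, _, _, _, counts = small_community
        for strand in ("sense", "antisense"):
            curve = rank_abundance(counts, strand)
            for _, sub in curve.groupby("sample_id"):
                assert (np.diff(sub["cumulative_pct"]) >= -1e-9).all()
                assert sub["cumulative_pct"].iloc[-1] == pytest.approx(100.0)

    def test_top_n_removal_drops_dominant_genes(self, small_community):
        _, _, _, truth, _, counts = small_community
        full = rank_abundance(counts, "antisense")
        trimmed = rank_abundance(counts, "antisense", top_n_removed=10)
        top10 = set(
            counts.groupby("gene_id")["antisense"].sum().nlargest(10).index
        )
        assert top10.isdisjoint(set(trimmed["gene_id"]))
        # dominance falls: cumulative share at rank 3 decreases
        f3 = full[full["rank"] == 3].set_index("sample_id")["cumulative_pct"]
        t3 = trimmed[trimmed["rank"] == 3].set_index("sample_id")["cumulative_pct"]
        assert (t3 <= f3.loc[t3.index] + 1e-9).all()

    def test_genome_fraction_significant(self):
        recs = [
            GeneRecord("a", "G1", "c", 0, 10, "+"),
            GeneRecord("b", "G1", "c", 20, 30, "+"),
            GeneRecord("c", "G2", "c", 0, 10, "+"),
        ]
        calls = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "sample_id": ["s"] * 3,
                "significant": [True, False, False],
            }
        )
        out = genome_fraction_significant(calls, recs).set_index("genome_id")
        assert out.loc["G1", "pct_significant"] == pytest.approx(50.0)
        assert out.loc["G2", "pct_significant"] == pytest.approx(0.0)


class TestHistogram:
    def _table(self, pairs):
        return pd.DataFrame(
            [(f"g{i}", "s", s, a) for i, (s, a) in enumerate(pairs)],
            columns=["gene_id", "sample_id", "sense", "antisense"],
        )

    def test_all_zero_antisense_in_dedicated_zero_bin(self):
        h = asrna_fraction_histogram(self._table([(10, 0), (5, 0)]))
        assert h.set_index("bin")["fraction"]["0"] == pytest.approx(1.0)

    def test_pure_end_bins_split_evenly(self):
        h = asrna_fraction_histogram(self._table([(10, 0), (0, 10)]))
        by_bin = h.set_index("bin")["fraction"]
        assert by_bin["0"] == pytest.approx(0.5)
        assert by_bin["100"] == pytest.approx(0.5)

    def test_interior_value_right_closed_bin(self):
        h = asrna_fraction_histogram(self._table([(5, 5)]))  # exactly 50%
        assert h["bin"].iloc[0] == "(40,50]"

    def test_fractions_sum_to_one_per_facet(self, small_community):
        _, _, meta, _, _, counts = small_community
        t = counts[(counts["sense"] + counts["antisense"]) > 0]
        genome_of = pd.Series({f"genome{g:03d}_g{i:04d}": f"genome{g:03d}"
                               for g in range(4) for i in range(40)})
        cov = pd.Series({m.genome_id: m.dna_coverage for m in meta})
        gene_cov = genome_of.map(cov)
        h = asrna_fraction_histogram(
            t, coverage=gene_cov, coverage_facets=[0, 10, 1000]
        )
        sums = h.groupby("facet", observed=True)["fraction"].sum()
        assert np.allclose(sums, 1.0)
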