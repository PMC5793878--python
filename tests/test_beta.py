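"""Regulatory potential, KS function test, rank-product targets."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdrift.beta import (
    beta_function_test,
    classify_de,
    cumulative_rank_curves,
    dmr_gene_enrichment,
    rank_product_targets,
    regulatory_potential,
)


def gene_frame(tss_list, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(tss_list))],
            "chrom": chrom,
            "tss": tss_list,
        }
    )


def dmr_frame(centers, width=100, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [c - width // 2 for c in centers],
            "end": [c + width // 2 for c in centers],
        }
    )


class TestRegulatoryPotential:
    @pytest.mark.parametrize(
        "offset,expected",
        [(0, math.exp(-0.5)), (50_000, math.exp(-2.5)), (100_000, math.exp(-4.5))],
    )
    def test_closed_forms_along_decay(self, offset, expected):
        genes = gene_frame([500_000])
        dmrs = dmr_frame([500_000 + offset])
        S = regulatory_potential(genes, dmrs)
        assert S.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_additive_over_dmrs(self):
        genes = gene_frame([500_000])
        dmrs = dmr_frame([500_000, 550_000])
        S = regulatory_potential(genes, dmrs)
        assert S.iloc[0] == pytest.approx(math.exp(-0.5) + math.exp(-2.5), abs=1e-12)

    def test_zero_beyond_window(self):
        genes = gene_frame([500_000])
        dmrs = dmr_frame([500_000 + 150_001])
        assert regulatory_potential(genes, dmrs).iloc[0] == 0.0

    def test_monotone_in_distance(self):
        genes = gene_frame([500_000])
        vals = [regulatory_potential(genes, dmr_frame([500_000 + d])).iloc[0]
                for d in (0, 10_000, 40_000, 90_000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def brute_force_ks_greater(x, y):
    """Exact one-sided two-sample KS p by enumeration of all splits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])

    def d_plus(a, b):
        grid = np.sort(pooled)
        fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
        fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
        return np.max(fa - fb)

    observed = d_plus(x, y)
    n = x.size
    count = total = 0
    for combo in itertools.combinations(range(pooled.size), n):
        a = pooled[list(combo)]
        b = np.delete(pooled, list(combo))
        total += 1
        if d_plus(a, b) >= observed - 1e-12:
            count += 1
    return observed, count / total


class TestFunctionTest:
    def test_no_separation_gives_null(self):
        S = pd.Series([3.0, 2.0, 1.0, 3.0, 2.0, 1.0], index=list("abcdef"))
        cls = pd.Series(["UP", "UP", "UP", "NON", "NON", "NON"], index=list("abcdef"))
        d, p = beta_function_test(S, cls)["UP"]
        assert p > 0.5

    def test_matches_exhaustive_enumeration(self):
        # UP at ranks 1,2 vs NON at ranks 3,4,5
        S = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        cls = pd.Series(["UP", "UP", "NON", "NON", "NON"], index=list("abcde"))
        d, p = beta_function_test(S, cls)["UP"]
        ranks_up, ranks_non = [1, 2], [3, 4, 5]
        d_ref, p_ref = brute_force_ks_greater(ranks_up, ranks_non)
        assert d == pytest.approx(d_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_single_gene_class_still_computes(self):
        S = pd.Series([5.0, 4.0, 3.0, 2.0], index=list("abcd"))
        cls = pd.Series(["UP", "NON", "NON", "NON"], index=list("abcd"))
        d, p = beta_function_test(S, cls)["UP"]
        assert 0 < p <= 1

    def test_invariant_to_monotone_transform_of_potential(self):
        rng = np.random.default_rng(0)
        S = pd.Series(rng.random(40), index=[f"g{i}" for i in range(40)])
        cls = pd.Series(["UP"] * 10 + ["NON"] * 30, index=S.index)
        a = beta_function_test(S, cls)["UP"]
        b = beta_function_test(np.exp(5 * S), cls)["UP"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_background_raises(self):
        S = pd.Series([1.0, 2.0], index=["a", "b"])
        cls = pd.Series(["UP", "UP"], index=["a", "b"])
        with pytest.raises(ValueError, match="NON"):
            beta_function_test(S, cls)

    def test_cumulative_curves_end_at_one(self):
        S = pd.Series([5.0, 4.0, 3.0, 2.0], index=list("abcd"))
        cls = pd.Series(["UP", "NON", "NON", "DOWN"], index=list("abcd"))
        curves = cumulative_rank_curves(S, cls)
        assert curves.iloc[-1].tolist() == [1.0, 1.0, 1.0]


class TestRankProduct:
    def test_best_gene_rp_is_one_over_n_squared(self):
        S = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        ev = pd.Series([0.001, 0.2, 0.5, 0.9], index=list("abcd"))
        cls = pd.Series(["UP"] * 4, index=list("abcd"))
        rp = rank_product_targets(S, ev, cls, cutoff=1.1)
        assert rp.loc["a", "rank_product"] == pytest.approx(1 / 16)
        assert rp.is_target.all()  # cutoff above max RP of 1

    def test_toy_table_matches_enumeration(self):
        # ranks: S -> a1 b2 c3 d4; E -> b1 a2 d3 c4
        S = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        ev = pd.Series([0.2, 0.1, 0.9, 0.5], index=list("abcd"))
        cls = pd.Series(["UP", "DOWN", "UP", "DOWN"], index=list("abcd"))
        rp = rank_product_targets(S, ev, cls, cutoff=0.001)
        expected = {"a": (1 * 2) / 16, "b": (2 * 1) / 16, "c": (3 * 4) / 16, "d": (4 * 3) / 16}
        for g, val in expected.items():
            assert rp.loc[g, "rank_product"] == pytest.approx(val)
        assert not rp.is_target.any()

    def test_ties_share_mean_rank(self):
        S = pd.Series([2.0, 2.0, 1.0], index=list("abc"))
        ev = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        cls = pd.Series(["UP"] * 3, index=list("abc"))
        rp = rank_product_targets(S, ev, cls)
        assert rp.loc["a", "rank_S"] == rp.loc["b", "rank_S"] == 1.5

    def test_non_genes_excluded_and_empty_raises(self):
        S = pd.Series([2.0, 1.0], index=["a", "b"])
        ev = pd.Series([0.1, 0.2], index=["a", "b"])
        rp = rank_product_targets(S, ev, pd.Series(["UP", "NON"], index=["a", "b"]))
        assert list(rp.index) == ["a"]
        with pytest.raises(ValueError):
            rank_product_targets(S, ev, pd.Series(["NON", "NON"], index=["a", "b"]))


class TestClassifyAndEnrichment:
    def test_significance_and_sign_modes(self):
        de = pd.DataFrame({"log2fc": [2.0, -2.0, 0.5, -0.01], "padj": [0.01, 0.01, 0.5, 0.9]})
        sig = classify_de(de)
        assert sig.tolist() == ["UP", "DOWN", "NON", "NON"]
        sign = classify_de(de, p_max=None, lfc_min=0.05)
        assert sign.tolist() == ["UP", "DOWN", "UP", "NON"]

    def test_no_dmrs_gives_flat_scores_and_p_one(self):
        genes = gene_frame([100, 200, 300])
        cls = pd.Series(["UP", "NON", "NON"], index=genes.index)
        table, pvals = dmr_gene_enrichment(genes, dmr_frame([]), cls)
        assert (table.score == 0).all()
        assert pvals["UP"] == 1.0

    def test_doubling_window_never_decreases_counts(self):
        rng = np.random.default_rng(1)
        genes = gene_frame(sorted(rng.integers(0, 2_000_000, 30).tolist()))
        dmrs = dmr_frame(sorted(rng.integers(0, 2_000_000, 15).tolist()))
        cls = pd.Series(["NON"] * 30, index=genes.index)
        t1, _ = dmr_gene_enrichment(genes, dmrs, cls, window=50_000)
        t2, _ = dmr_gene_enrichment(genes, dmrs, cls, window=100_000)
        assert (t2.score >= t1.score).all()

    def test_planted_coupling_detected(self):
        # DOWN genes sit on DMRs; NON genes are far away
        genes = gene_frame([100_000, 120_000, 2_000_000, 2_100_000, 2_200_000])
        dmrs = dmr_frame([100_000, 121_000])
        cls = pd.Series(["DOWN", "DOWN", "NON", "NON", "NON"], index=genes.index)
        table, pvals = dmr_gene_enrichment(genes, dmrs, cls)
        down = table[table.de_class == "DOWN"].score
        non = table[table.de_class == "NON"].score
        assert down.min() > non.max()
        assert pvals["DOWN"] < 0.2  # tiny n; direction is what matters
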