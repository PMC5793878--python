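"""ssGSEA scores, median stratification, Kaplan-Meier and log-rank."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methdrift.clinical import km_estimate, logrank_test, ssgsea_matrix, ssgsea_score, stratify_samples


def brute_force_ssgsea(expression, gene_set, alpha):
    """Plain-python running sum following the same score definition."""
    items = sorted(expression.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    in_flags = [g in gene_set for g, _ in items]
    n_out = sum(1 for f in in_flags if not f)
    w = [(n - i) ** alpha if f else 0.0 for i, f in enumerate(in_flags)]
    w_sum = sum(w)
    es = 0.0
    cum_in = cum_out = 0.0
    for i in range(n):
        cum_in += w[i] / w_sum
        cum_out += (0 if in_flags[i] else 1) / n_out
        es += cum_in - cum_out
    return es


class TestSsgsea:
    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_brute_force_on_random_toys(self, alpha):
        rng = np.random.default_rng(3)
        for _ in range(20):
            expr = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
            gene_set = set(rng.choice(expr.index, size=rng.integers(2, 6), replace=False))
            ours = ssgsea_score(expr, gene_set, alpha=alpha)
            ref = brute_force_ssgsea(expr.to_dict(), gene_set, alpha)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_top_k_set_is_maximal_over_all_k_sets(self):
        rng = np.random.default_rng(1)
        expr = pd.Series(rng.permutation(10).astype(float), index=[f"g{i}" for i in range(10)])
        k = 3
        top = set(expr.sort_values(ascending=False).index[:k])
        best = ssgsea_score(expr, top)
        assert best > 0
        for combo in itertools.combinations(expr.index, k):
            assert ssgsea_score(expr, set(combo)) <= best + 1e-12

    def test_alpha_zero_depends_only_on_positions(self):
        expr_a = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        expr_b = pd.Series([100.0, 9.0, 8.5, 0.3, 0.1], index=list("abcde"))
        s = {"b", "d"}
        assert ssgsea_score(expr_a, s, alpha=0.0) == pytest.approx(
            ssgsea_score(expr_b, s, alpha=0.0), abs=1e-12
        )

    def test_random_set_mean_near_zero_on_exchangeable_data(self):
        # the unweighted score is symmetric under exchangeability; with
        # alpha > 0 the rank weighting gives a small positive offset
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        scores = []
        for _ in range(300):
            expr = pd.Series(rng.normal(size=30), index=genes)
            scores.append(ssgsea_score(expr, set(genes[:5]), alpha=0.0))
        assert abs(np.mean(scores)) < 0.5  # |ES| can reach ~15 on one draw

    def test_disjoint_set_raises(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="no genes"):
            ssgsea_score(expr, {"zzz"})


class TestStratification:
    def test_median_split_enumeration(self):
        scores = pd.DataFrame(
            {"FA": [1.0, 2.0, 3.0, 4.0], "GLY": [4.0, 3.0, 2.0, 1.0]},
            index=list("wxyz"),
        )
        out = stratify_samples(scores)
        # medians are 2.5 on both axes: two samples land on each side
        assert (out.FA_level == ["low", "low", "high", "high"]).all()
        assert (out.GLY_level == ["high", "high", "low", "low"]).all()
        assert out.stratum.tolist() == [
            "FA_low|GLY_high", "FA_low|GLY_high", "FA_high|GLY_low", "FA_high|GLY_low",
        ]

    def test_ties_at_median_go_low(self):
        scores = pd.DataFrame({"A": [1.0, 2.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0, 4.0]})
        out = stratify_samples(scores)
        assert (out.A_level == ["low", "low", "low", "high"]).all()

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({"A": rng.normal(size=20), "B": rng.normal(size=20)})
        a = stratify_samples(scores)
        b = stratify_samples(scores.apply(lambda c: np.exp(3 * c)))
        assert (a.stratum == b.stratum).all()

    def test_custom_split_points(self):
        scores = pd.DataFrame({"A": [1.0, 5.0], "B": [1.0, 5.0]})
        out = stratify_samples(scores, split={"A": 0.0, "B": 0.0})
        assert (out.A_level == "high").all()

    def test_errors(self):
        with pytest.raises(ValueError, match="two score columns"):
            stratify_samples(pd.DataFrame({"A": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="at least two"):
            stratify_samples(pd.DataFrame({"A": [1.0], "B": [1.0]}))
        with pytest.raises(ValueError, match="no split"):
            stratify_samples(pd.DataFrame({"A": [1.0, 1.0], "B": [1.0, 2.0]}))


def manual_km(times, events):
    """Product-limit estimator tabulated by hand logic."""
    df = pd.DataFrame({"t": times, "e": events}).sort_values("t")
    s = 1.0
    out = {}
    at_risk = len(df)
    for t, grp in df.groupby("t"):
        d = grp.e.sum()
        if d:
            s *= 1 - d / at_risk
        out[t] = s
        at_risk -= len(grp)
    return out


def manual_logrank(t1, e1, t2, e2):
    """Observed-minus-expected tabulation over pooled event times."""
    all_t = sorted(set(list(t1) + list(t2)))
    O = E = V = 0.0
    for t in all_t:
        n1 = sum(1 for x in t1 if x >= t)
        n2 = sum(1 for x in t2 if x >= t)
        d1 = sum(1 for x, e in zip(t1, e1) if x == t and e)
        d2 = sum(1 for x, e in zip(t2, e2) if x == t and e)
        d, n = d1 + d2, n1 + n2
        if d == 0 or n < 2:
            continue
        O += d1
        E += d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestSurvival:
    def test_km_no_events_is_flat_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km.survival == 1.0).all()

    def test_km_two_subjects_by_hand(self):
        km = km_estimate([1.0, 5.0], [1, 0])
        at_1 = km.loc[km.time == 1.0, "survival"].iloc[0]
        assert at_1 == pytest.approx(0.5)

    def test_km_matches_empirical_sf_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5.0, 40)
        km = km_estimate(times, np.ones(40, dtype=int))
        ref = manual_km(times, np.ones(40, dtype=int))
        for t, s in ref.items():
            got = km.loc[km.time == t, "survival"].iloc[0]
            assert got == pytest.approx(s, abs=1e-10)
        # with every subject an event the estimator is the empirical SF
        emp = 1.0 - np.searchsorted(np.sort(times), km.time, side="right") / 40
        assert np.allclose(km.survival, emp, atol=1e-10)

    def test_km_monotone_non_increasing(self):
        km = km_estimate([3.0, 1.0, 4.0, 1.0, 5.0], [1, 0, 1, 1, 0])
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])

    def test_logrank_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_logrank_matches_hand_tabulation(self):
        t1, e1 = [1.0, 4.0, 6.0], [1, 1, 0]
        t2, e2 = [2.0, 5.0, 7.0], [1, 0, 1]
        stat, _ = logrank_test(t1, e1, t2, e2)
        assert stat == pytest.approx(manual_logrank(t1, e1, t2, e2), abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


class TestMatrixScoring:
    def test_matrix_matches_per_sample_scores(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(12, 3)),
                            index=[f"g{i}" for i in range(12)], columns=list("xyz"))
        sets = {"S1": {"g0", "g1", "g2"}, "S2": {"g5", "g9"}}
        mat = ssgsea_matrix(expr, sets)
        for s in "xyz":
            for name, members in sets.items():
                assert mat.loc[s, name] == pytest.approx(ssgsea_score(expr[s], members))
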