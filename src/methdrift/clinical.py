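"""Single-sample gene-set scoring, stratification and survival comparison.

The per-sample enrichment score follows the ssGSEA construction: with the
sample's genes ordered by expression descending, the score is the summed
difference between the weighted in-set rank ECDF and the unweighted
out-of-set ECDF,

    ES = sum_i [ P_in^w(i) - P_out(i) ],
    P_in^w(i) = sum_{j<=i, j in set} w_j / sum_{j in set} w_j,
    w_j = (rank value of gene j)^alpha      (top gene has rank value N),
    P_out(i) = #{j<=i, j not in set} / N_out,

with alpha = 0.25 by default.  Samples are stratified low/high at the
cohort median of each of two set scores (2x2 strata); strata are compared
by Kaplan-Meier estimation and the two-group log-rank test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "ssgsea_score",
    "ssgsea_matrix",
    "stratify_samples",
    "km_estimate",
    "logrank_test",
]


def ssgsea_score(expression: pd.Series, gene_set: set[str], alpha: float = 0.25) -> float:
    """ssGSEA enrichment score of one gene set in one sample.

    ``expression`` is indexed by gene id.  Ties in expression are broken
    by gene id for determinism.  Genes in the set but not measured are
    ignored; an empty intersection is an error.
    """
    genes = expression.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    if not in_set.any():
        raise ValueError("gene set shares no genes with the expression profile")
    values = expression.to_numpy(dtype=float)
    order = np.lexsort((genes, -values))  # descending expression, gene-id tie-break
    in_sorted = in_set[order]
    n = genes.size
    rank_value = np.arange(n, 0, -1, dtype=float)  # N for the top gene
    weights = np.where(in_sorted, rank_value**alpha, 0.0)
    w_total = weights.sum()
    n_out = n - in_sorted.sum()
    if n_out == 0:
        raise ValueError("gene set covers every measured gene")
    p_in = np.cumsum(weights) / w_total
    p_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expression: pd.DataFrame, gene_sets: dict[str, set[str]], alpha: float = 0.25
) -> pd.DataFrame:
    """Score every sample (column) against every gene set; samples x sets."""
    out = {
        name: [ssgsea_score(expression[s], members, alpha) for s in expression.columns]
        for name, members in gene_sets.items()
    }
    return pd.DataFrame(out, index=expression.columns)


def stratify_samples(scores: pd.DataFrame, split: dict[str, float] | None = None) -> pd.DataFrame:
    """2x2 stratification of samples by two gene-set score axes.

    ``scores`` has exactly two columns (one per set).  Each axis is split
    at the cohort median by default, or at ``split[set_name]`` when given
    (e.g. a reference-group mean).  Scores <= the split point are 'low'
    (ties at the median go low).  All-equal scores on an axis cannot be
    split and raise.  Returns per-axis levels plus a combined stratum
    label ``"<set1>_<low/high>|<set2>_<low/high>"``.
    """
    if scores.shape[1] != 2:
        raise ValueError("stratification needs exactly two score columns")
    if len(scores) < 2:
        raise ValueError("need at least two samples to stratify")
    out = pd.DataFrame(index=scores.index)
    levels = []
    for col in scores.columns:
        x = scores[col].to_numpy(dtype=float)
        cut = float(np.median(x)) if split is None or col not in split else float(split[col])
        if np.all(x == x[0]):
            raise ValueError(f"all scores equal on axis {col!r}; no split possible")
        lvl = np.where(x <= cut, "low", "high")
        out[f"{col}_level"] = lvl
        levels.append([f"{col}_{v}" for v in lvl])
    out["stratum"] = ["|".join(pair) for pair in zip(*levels)]
    return out


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a frame with columns ``time`` and ``survival`` (the step
    function evaluated at each distinct event/censor time; right-
    continuous and non-increasing).  Censored observations leave the
    curve unchanged and only shrink the risk set.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p value)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(times_a, times_b, event_observed_A=np.asarray(events_a, dtype=int),
                      event_observed_B=np.asarray(events_b, dtype=int))
    return float(res.test_statistic), float(res.p_value)
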