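"""Rao-Scott overdispersion-corrected likelihood-ratio test for methylation.

Replicated bisulfite counts are clustered binomial data: reads within a
replicate share that animal's methylation state, so the pooled counts are
overdispersed relative to a single binomial.  The test computes the usual
binomial G² for equality of two group proportions on the pooled counts and
deflates it by a design effect estimated from the between-replicate
heterogeneity chi-square, in the spirit of Rao & Scott's first-order
correction for survey-clustered categorical data.

Two design-effect quantities appear:

* per-group ``d_g = max(1, X²_het / (n_g - 1))`` — the classical clamped
  estimate, used to report the *effective (weighted) coverage*
  ``Σ_g T_g / d_g`` that the downstream site filter thresholds at 10;
* the pooled, unclamped ``d̄ = (X²_1 + X²_2) / (df_1 + df_2)`` used to
  deflate G².  Because d̄ is itself an estimate on few degrees of freedom,
  G²/d̄ is referred to an F(1, df_1 + df_2) distribution rather than χ²(1);
  with one replicate per group there is no heterogeneity information and
  the test reduces exactly to the uncorrected binomial G-test on χ²(1).
  This second-order-style reference keeps the size of the test near
  nominal both for binomial data and under beta-binomial overdispersion
  with five replicates per group, where dividing by a clamped 4-df
  estimate and using χ²(1) is markedly liberal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .matrix import CpGCountMatrix, GroupCounts

__all__ = ["SiteTestResult", "estimate_design_effect", "rslrt_test", "site_scan"]

_RESULT_COLUMNS = [
    "p1", "p2", "delta", "G2", "d1", "d2", "dbar", "df_het",
    "G2_adj", "p_value", "weighted_coverage",
]


@dataclass
class SiteTestResult:
    """Outcome of the Rao-Scott LRT at one CpG or one region."""

    p1: float
    p2: float
    delta: float
    G2: float
    d1: float
    d2: float
    dbar: float
    df_het: int
    G2_adj: float
    p_value: float
    weighted_coverage: float


def _heterogeneity(meth: np.ndarray, total: np.ndarray) -> tuple[float, int]:
    """Between-replicate heterogeneity X² about the pooled proportion.

    Returns ``(X², df)`` with df = n_replicates - 1.  X² is NaN when it is
    inestimable (single replicate, or pooled proportion 0 or 1).
    """
    n = total.size
    p_hat = meth.sum() / total.sum()
    if n < 2 or p_hat <= 0.0 or p_hat >= 1.0:
        return float("nan"), 0
    resid = meth - total * p_hat
    x2 = float(np.sum(resid**2 / (total * p_hat * (1.0 - p_hat))))
    return x2, n - 1


def estimate_design_effect(group: GroupCounts) -> float:
    """Clamped per-group design effect d = max(1, X²_het / (n - 1)).

    Equals 1 when heterogeneity is inestimable (one replicate, or pooled
    proportion exactly 0 or 1).  Used for the effective-coverage filter;
    always >= 1 so effective coverage never exceeds raw coverage.
    """
    x2, df = _heterogeneity(group.meth, group.total)
    if df == 0:
        return 1.0
    return max(1.0, x2 / df)


def _rslrt_arrays(
    m1: np.ndarray, t1: np.ndarray, m2: np.ndarray, t2: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised Rao-Scott LRT over ``(n_sites, n_reps)`` count arrays.

    Replicates with total 0 are treated as uncovered and excluded from
    both the pooled proportions (they contribute nothing) and the
    heterogeneity estimate.  Every site must be covered in both groups.
    """
    m1 = np.atleast_2d(np.asarray(m1, dtype=np.float64))
    t1 = np.atleast_2d(np.asarray(t1, dtype=np.float64))
    m2 = np.atleast_2d(np.asarray(m2, dtype=np.float64))
    t2 = np.atleast_2d(np.asarray(t2, dtype=np.float64))

    out: dict[str, np.ndarray] = {}
    parts = []
    for m, t in ((m1, t1), (m2, t2)):
        T = t.sum(axis=1)
        M = m.sum(axis=1)
        if np.any(T <= 0):
            raise ValueError("every site must have coverage in both groups")
        p_hat = M / T
        n_rep = (t > 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(
                t > 0,
                (m - t * p_hat[:, None]) ** 2 / (t * p_hat[:, None] * (1.0 - p_hat[:, None])),
                0.0,
            )
            x2 = contrib.sum(axis=1)
        df = np.where((n_rep >= 2) & (p_hat > 0) & (p_hat < 1), n_rep - 1, 0)
        x2 = np.where(df > 0, x2, np.nan)
        d_clamped = np.where(df > 0, np.maximum(1.0, x2 / np.maximum(df, 1)), 1.0)
        parts.append((M, T, p_hat, x2, df, d_clamped))

    (M1, T1, p1, x2_1, df1, d1), (M2, T2, p2, x2_2, df2, d2) = parts
    p0 = (M1 + M2) / (T1 + T2)

    def loglik(M: np.ndarray, T: np.ndarray, q: np.ndarray) -> np.ndarray:
        return xlogy(M, q) + xlogy(T - M, 1.0 - q)

    G2 = 2.0 * (
        loglik(M1, T1, p1) + loglik(M2, T2, p2)
        - loglik(M1, T1, p0) - loglik(M2, T2, p0)
    )
    G2 = np.maximum(G2, 0.0)  # guard tiny negative round-off

    df_het = df1 + df2
    x2_pool = np.nansum(np.stack([x2_1, x2_2]), axis=0)
    # pooled unclamped deflator; floored well below 1 only to avoid division by 0
    dbar = np.where(df_het > 0, np.maximum(x2_pool / np.maximum(df_het, 1), 1e-3), 1.0)
    G2_adj = G2 / dbar
    p_value = np.where(
        df_het > 0,
        stats.f.sf(G2_adj, 1, np.maximum(df_het, 1)),
        stats.chi2.sf(G2_adj, 1),
    )
    p_value = np.where(G2 == 0.0, 1.0, p_value)

    out["p1"], out["p2"], out["delta"] = p1, p2, p2 - p1
    out["G2"], out["d1"], out["d2"] = G2, d1, d2
    out["dbar"], out["df_het"] = dbar, df_het
    out["G2_adj"], out["p_value"] = G2_adj, p_value
    out["weighted_coverage"] = T1 / d1 + T2 / d2
    return out


def rslrt_test(g1: GroupCounts, g2: GroupCounts) -> SiteTestResult:
    """Rao-Scott LRT for equal methylation proportion between two groups.

    Degenerate inputs (both groups all-unmethylated or all-methylated)
    give G2 = 0 and p = 1 rather than an error.
    """
    arrays = _rslrt_arrays(
        g1.meth[None, :], g1.total[None, :], g2.meth[None, :], g2.total[None, :]
    )
    return SiteTestResult(**{k: arrays[k][0].item() for k in _RESULT_COLUMNS})


def site_scan(
    matrix: CpGCountMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Apply the Rao-Scott LRT at every CpG covered in both groups.

    Returns a frame sorted by (chrom, pos) with one row per shared site
    and the :class:`SiteTestResult` fields as columns.  Sites covered in
    only one group are skipped; their number is recorded in
    ``result.attrs["n_skipped_one_group"]``.
    """
    for g in (group_a, group_b):
        if g not in matrix.meth:
            raise KeyError(f"group {g!r} not present in matrix")
    t_a = matrix.total[group_a]
    t_b = matrix.total[group_b]
    cov_a = t_a.sum(axis=1) > 0
    cov_b = t_b.sum(axis=1) > 0
    shared = cov_a & cov_b
    skipped = int(((cov_a | cov_b) & ~shared).sum())
    idx = np.flatnonzero(shared)
    if idx.size == 0:
        res = pd.DataFrame(columns=["chrom", "pos", *_RESULT_COLUMNS])
    else:
        arrays = _rslrt_arrays(
            matrix.meth[group_a][idx], t_a[idx], matrix.meth[group_b][idx], t_b[idx]
        )
        res = pd.DataFrame({"chrom": matrix.chrom[idx], "pos": matrix.pos[idx], **arrays})
    res.attrs["n_skipped_one_group"] = skipped
    res.attrs["groups"] = (group_a, group_b)
    return res
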