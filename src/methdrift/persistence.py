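"""Persistence of methylation changes after an intervention.

For each DMR called between control (LF) and case (HF), the
post-intervention group's pooled methylation level is placed on the
control-to-case axis via the retention index

    r = (m_FO - m_LF) / (m_HF - m_LF),

clipped to [-0.5, 1.5]: r = 1 means the change was fully retained after
the intervention, r = 0 fully reversed.  A fixed-threshold rule labels
each DMR retained / lost / intermediate, and an unsupervised k-means view
over the three group means (relabelled C1..Ck by descending mean r)
is reported alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .matrix import CpGCountMatrix

__all__ = [
    "group_methylation_levels",
    "retention_index",
    "compute_persistence",
    "classify_persistence",
    "cluster_dmrs",
]

R_CLIP = (-0.5, 1.5)


def group_methylation_levels(
    dmrs: pd.DataFrame, matrix: CpGCountMatrix, groups: list[str]
) -> pd.DataFrame:
    """Pooled methylation level of each DMR in each group.

    Pooled over member CpGs and replicates (sum meth / sum total).  DMRs
    must carry a ``members`` column of CpG positions.
    """
    pos_index = pd.MultiIndex.from_arrays([matrix.chrom, matrix.pos])
    rows = []
    for rec in dmrs.itertuples(index=False):
        idx = pos_index.get_indexer([(rec.chrom, p) for p in rec.members])
        if np.any(idx < 0):
            raise ValueError(f"DMR {rec.chrom}:{rec.start}-{rec.end} has member CpGs absent from matrix")
        row = {}
        for g in groups:
            m = matrix.meth[g][idx].sum()
            t = matrix.total[g][idx].sum()
            if t == 0:
                raise ValueError(f"DMR {rec.chrom}:{rec.start}-{rec.end} uncovered in group {g!r}")
            row[f"m_{g}"] = m / t
        rows.append(row)
    out = pd.concat([dmrs.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    return out


def retention_index(m_lf, m_hf, m_fo):
    """Retention index r = (m_FO - m_LF)/(m_HF - m_LF), clipped to [-0.5, 1.5].

    NaN (flagged, not an error) when the control and case levels coincide
    and the axis is undefined.  Works on scalars or aligned arrays.
    """
    m_lf = np.asarray(m_lf, dtype=float)
    m_hf = np.asarray(m_hf, dtype=float)
    m_fo = np.asarray(m_fo, dtype=float)
    span = m_hf - m_lf
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(span == 0.0, np.nan, (m_fo - m_lf) / np.where(span == 0.0, 1.0, span))
    r = np.clip(r, *R_CLIP)
    return r if r.ndim else float(r)


def compute_persistence(
    dmrs: pd.DataFrame,
    matrix: CpGCountMatrix,
    group_lf: str = "LF",
    group_hf: str = "HF",
    group_fo: str = "HF-LF",
) -> pd.DataFrame:
    """Retention index of every DMR across the three-group design."""
    levels = group_methylation_levels(dmrs, matrix, [group_lf, group_hf, group_fo])
    levels = levels.rename(
        columns={f"m_{group_lf}": "m_LF", f"m_{group_hf}": "m_HF", f"m_{group_fo}": "m_FO"}
    )
    levels["r"] = retention_index(
        levels["m_LF"].to_numpy(), levels["m_HF"].to_numpy(), levels["m_FO"].to_numpy()
    )
    levels["r_undefined"] = levels["r"].isna()
    if levels["r_undefined"].any():
        warnings.warn(
            f"{int(levels['r_undefined'].sum())} DMRs have identical control and case "
            "levels; retention undefined",
            stacklevel=2,
        )
    return levels


def classify_persistence(
    calls: pd.DataFrame, retained_min: float = 0.7, lost_max: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold rule: retained (r >= retained_min), lost (r <= lost_max), else intermediate.

    Returns the calls with a ``persistence_class`` column and a summary of
    class counts per DMR direction.  The three labels partition every DMR
    with a defined r exhaustively and exclusively.
    """
    if lost_max >= retained_min:
        raise ValueError("need lost_max < retained_min")
    r = calls["r"].to_numpy()
    cls = np.where(
        np.isnan(r),
        "undefined",
        np.where(r >= retained_min, "retained", np.where(r <= lost_max, "lost", "intermediate")),
    )
    out = calls.copy()
    out["persistence_class"] = cls
    summary = (
        out.groupby(["direction", "persistence_class"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return out, summary


def cluster_dmrs(
    calls: pd.DataFrame, k: int = 6, seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """k-means clustering of DMRs on (m_LF, m_HF, m_FO), labelled C1..Ck.

    Cluster labels are reassigned by descending mean retention index so C1
    is always the most-retained cluster.  Empty effective clusters (all
    points identical, k-means collapse) are flagged with a warning.
    """
    if k > len(calls):
        raise ValueError(f"k={k} exceeds the number of DMRs ({len(calls)})")
    X = calls[["m_LF", "m_HF", "m_FO"]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on duplicate points
        km = KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit(X)
    raw = km.labels_
    r = calls["r"].to_numpy()
    mean_r = []
    for lbl in range(k):
        members = r[raw == lbl]
        mean_r.append(np.nanmean(members) if members.size else -np.inf)
    order = np.argsort(mean_r)[::-1]  # descending mean r
    relabel = {int(old): f"C{rank + 1}" for rank, old in enumerate(order)}
    out = calls.copy()
    out["cluster"] = [relabel[int(l)] for l in raw]
    occupied = out["cluster"].nunique()
    if occupied < k:
        warnings.warn(f"only {occupied} of {k} clusters are occupied (degenerate data)", stacklevel=2)
    return out
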