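"""Site -> merge -> region DMR calling.

The procedure mirrors the three printed stages:

1. keep CpGs with site-level Rao-Scott p < 0.05, absolute methylation
   difference > 10 % and total weighted (design-effect-deflated)
   coverage >= 10;
2. chain same-direction differentially methylated CpGs whose successive
   gaps are <= 5,000 bp on one chromosome into candidate regions;
3. re-test each candidate at the region level (member-CpG counts summed
   per replicate), Benjamini-Hochberg-adjust the region p values jointly
   over all candidates, and keep regions with adjusted p < 0.01, absolute
   methylation difference > 30 % or proportion fold change > 5, and at
   least 2 differentially methylated member CpGs.

All inequalities are strict exactly as printed.  Hyper- and hypo-DMRs are
merged separately so a region's direction is always well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix import CpGCountMatrix
from .rslrt import rslrt_test, site_scan

__all__ = ["DmrCallerConfig", "call_dm_sites", "merge_dm_sites", "test_regions", "call_dmrs"]

DMR_COLUMNS = [
    "dmr_id", "chrom", "start", "end", "direction", "n_dm_cpgs", "members",
    "p1", "p2", "delta", "fold_change", "p_value", "p_adj", "passes",
]


@dataclass
class DmrCallerConfig:
    """Thresholds of the three calling stages (defaults as printed)."""

    site_p: float = 0.05
    site_min_delta: float = 0.10
    site_min_weighted_coverage: float = 10.0
    merge_gap: int = 5_000
    region_padj: float = 0.01
    region_min_delta: float = 0.30
    region_min_fold: float = 5.0
    fold_change_eps: float = 0.01  # zero guard for the proportion fold change
    min_dm_cpgs: int = 2
    members_only: bool = True  # aggregate member DM CpGs, not all CpGs in span


def _check_sorted(frame: pd.DataFrame) -> None:
    order = np.lexsort((frame["pos"].to_numpy(), frame["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(frame))):
        raise ValueError("site results must be sorted by (chrom, pos)")


def call_dm_sites(results: pd.DataFrame, config: DmrCallerConfig | None = None) -> pd.DataFrame:
    """Filter site-scan results to differentially methylated CpGs.

    Keeps sites with p < ``site_p`` AND |delta| > ``site_min_delta`` AND
    weighted coverage >= ``site_min_weighted_coverage``; adds a
    ``direction`` column ('hyper' when group B exceeds group A).
    """
    config = config or DmrCallerConfig()
    _check_sorted(results)
    keep = (
        (results["p_value"] < config.site_p)
        & (results["delta"].abs() > config.site_min_delta)
        & (results["weighted_coverage"] >= config.site_min_weighted_coverage)
    )
    out = results.loc[keep].copy()
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)


def merge_dm_sites(sites: pd.DataFrame, config: DmrCallerConfig | None = None) -> pd.DataFrame:
    """Chain same-direction DM CpGs within ``merge_gap`` bp into candidates.

    Chaining runs per (chromosome, direction): a new candidate starts when
    the gap to the previous same-direction CpG exceeds the merge gap.
    Singleton chains are kept (the >= 2 DM-CpG rule is applied at the
    region stage).  The region span runs from the first member CpG start
    to the last member CpG end (pos + 1, half-open).
    """
    config = config or DmrCallerConfig()
    _check_sorted(sites)
    records = []
    if len(sites):
        for (chrom, direction), grp in sites.groupby(["chrom", "direction"], sort=True):
            pos = grp["pos"].to_numpy()
            breaks = np.flatnonzero(np.diff(pos) > config.merge_gap) + 1
            for chunk in np.split(pos, breaks):
                records.append(
                    {
                        "chrom": chrom,
                        "start": int(chunk[0]),
                        "end": int(chunk[-1]) + 1,
                        "direction": direction,
                        "members": list(int(p) for p in chunk),
                        "n_dm_cpgs": len(chunk),
                    }
                )
    out = pd.DataFrame(records, columns=["chrom", "start", "end", "direction", "members", "n_dm_cpgs"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _fold_change(p1: float, p2: float, eps: float) -> float:
    return (max(p1, p2) + eps) / (min(p1, p2) + eps)


def test_regions(
    candidates: pd.DataFrame,
    matrix: CpGCountMatrix,
    group_a: str,
    group_b: str,
    config: DmrCallerConfig | None = None,
) -> pd.DataFrame:
    """Region-level Rao-Scott re-test of merged candidates.

    Per candidate, member-CpG counts (or all CpGs in the span when
    ``members_only`` is off) are summed per replicate into one
    group-counts pair and re-tested; BH adjustment is joint over all
    candidates of the comparison, both directions together.
    """
    config = config or DmrCallerConfig()
    if candidates.empty:
        out = candidates.copy()
        for col in ["p1", "p2", "delta", "fold_change", "p_value", "p_adj", "passes", "dmr_id"]:
            out[col] = pd.Series(dtype=float if col not in ("passes", "dmr_id") else object)
        return out[DMR_COLUMNS]

    pos_index = pd.MultiIndex.from_arrays([matrix.chrom, matrix.pos])
    rows = []
    for rec in candidates.itertuples(index=False):
        if config.members_only:
            keys = [(rec.chrom, p) for p in rec.members]
        else:
            in_span = (
                (matrix.chrom == rec.chrom)
                & (matrix.pos >= rec.start)
                & (matrix.pos < rec.end)
            )
            keys = list(zip(matrix.chrom[in_span], matrix.pos[in_span]))
        idx = pos_index.get_indexer(keys)
        if len(idx) == 0 or np.any(idx < 0):
            raise ValueError(f"candidate {rec.chrom}:{rec.start}-{rec.end} references CpGs absent from the matrix")
        g1 = matrix.region_counts(group_a, idx)
        g2 = matrix.region_counts(group_b, idx)
        res = rslrt_test(g1, g2)
        rows.append(
            {
                "p1": res.p1,
                "p2": res.p2,
                "delta": res.delta,
                "fold_change": _fold_change(res.p1, res.p2, config.fold_change_eps),
                "p_value": res.p_value,
            }
        )
    out = pd.concat([candidates.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    out["p_adj"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["passes"] = (
        (out["p_adj"] < config.region_padj)
        & (
            (out["delta"].abs() > config.region_min_delta)
            | (out["fold_change"] > config.region_min_fold)
        )
        & (out["n_dm_cpgs"] >= config.min_dm_cpgs)
    )
    out["dmr_id"] = [f"dmr_{i + 1}" for i in range(len(out))]
    return out[DMR_COLUMNS]


@dataclass
class DmrCallResult:
    """Full output of the caller: passing DMRs by direction plus an audit trail."""

    hyper: pd.DataFrame
    hypo: pd.DataFrame
    regions: pd.DataFrame  # every tested candidate, passing or not
    sites: pd.DataFrame  # site-level DM CpGs
    audit: dict[str, int] = field(default_factory=dict)


def call_dmrs(
    matrix: CpGCountMatrix,
    group_a: str,
    group_b: str,
    config: DmrCallerConfig | None = None,
) -> DmrCallResult:
    """Run the full site -> merge -> region procedure for one comparison.

    ``delta > 0`` (hyper) means higher methylation in ``group_b``.
    """
    config = config or DmrCallerConfig()
    scan = site_scan(matrix, group_a, group_b)
    dm_sites = call_dm_sites(scan, config)
    candidates = merge_dm_sites(dm_sites, config)
    regions = test_regions(candidates, matrix, group_a, group_b, config)
    passing = regions.loc[regions["passes"]]
    audit = {
        "sites_tested": len(scan),
        "sites_skipped_one_group": scan.attrs.get("n_skipped_one_group", 0),
        "dm_sites": len(dm_sites),
        "candidate_regions": len(candidates),
        "passing_dmrs": len(passing),
        "hyper_dmrs": int((passing["direction"] == "hyper").sum()),
        "hypo_dmrs": int((passing["direction"] == "hypo").sum()),
    }
    return DmrCallResult(
        hyper=passing.loc[passing["direction"] == "hyper"].reset_index(drop=True),
        hypo=passing.loc[passing["direction"] == "hypo"].reset_index(drop=True),
        regions=regions,
        sites=dm_sites,
        audit=audit,
    )
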