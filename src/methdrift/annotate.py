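"""Positional annotation of DMRs and overlap enrichment with matched controls."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "distance_to_nearest_tss",
    "generate_matched_controls",
    "overlap_enrichment",
    "hypergeometric_overlap_p",
    "OverlapEnrichment",
]


def distance_to_nearest_tss(dmrs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Signed distance from each DMR midpoint to the nearest TSS.

    Distance is 0 when a TSS falls inside the DMR.  The sign is relative
    to the nearest gene's orientation: positive when the DMR midpoint
    lies downstream of the TSS (rightward for '+' genes, leftward for
    '-' genes), negative upstream.  Equidistant TSSs are broken by
    gene_id.  DMRs on chromosomes without genes get NaN distance and
    ``no_gene_on_chrom = True``.
    """
    rows = []
    by_chrom = {c: g.sort_values(["tss", "gene_id"]) for c, g in genes.groupby("chrom")}
    for rec in dmrs.itertuples(index=False):
        cand = by_chrom.get(rec.chrom)
        if cand is None or cand.empty:
            rows.append({"distance": np.nan, "nearest_gene": None, "no_gene_on_chrom": True})
            continue
        mid = (rec.start + rec.end) // 2
        tss = cand["tss"].to_numpy()
        dist_abs = np.abs(tss - mid)
        inside = (tss >= rec.start) & (tss < rec.end)
        if inside.any():
            dist_abs = np.where(inside, 0, dist_abs)
        best = dist_abs.min()
        # tie-break by gene_id among the equidistant
        tied = cand.loc[dist_abs == best].sort_values("gene_id").iloc[0]
        if best == 0:
            signed = 0
        else:
            downstream = (mid > tied["tss"]) == (tied["strand"] == "+")
            signed = int(best) if downstream else -int(best)
        rows.append({"distance": signed, "nearest_gene": tied["gene_id"], "no_gene_on_chrom": False})
    out = pd.concat([dmrs.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    return out


def _merged_intervals(intervals: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union of possibly overlapping intervals per chromosome (sorted)."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in intervals.groupby("chrom"):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        order = np.argsort(s, kind="stable")
        s, e = s[order], e[order]
        out_s, out_e = [s[0]], [e[0]]
        for a, b in zip(s[1:], e[1:]):
            if a <= out_e[-1]:
                out_e[-1] = max(out_e[-1], b)
            else:
                out_s.append(a)
                out_e.append(b)
        merged[chrom] = (np.asarray(out_s), np.asarray(out_e))
    return merged


def _overlaps_any(regions: pd.DataFrame, merged: dict[str, tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """>= 1 bp intersection with the merged set, half-open coordinates."""
    hits = np.zeros(len(regions), dtype=bool)
    for i, rec in enumerate(regions.itertuples(index=False)):
        ivs = merged.get(rec.chrom)
        if ivs is None:
            continue
        s, e = ivs
        j = np.searchsorted(e, rec.start, side="right")
        hits[i] = j < s.size and s[j] < rec.end
    return hits


def generate_matched_controls(
    dmrs: pd.DataFrame,
    genome_sizes: dict[str, int],
    n_sets: int,
    seed: int = 0,
    max_tries: int = 10_000,
) -> list[pd.DataFrame]:
    """Length- and chromosome-matched random control region sets.

    Each control set contains one region per DMR with identical length on
    the same chromosome, uniformly repositioned and non-overlapping with
    every DMR.  Placement is seed-deterministic.
    """
    rng = np.random.default_rng(seed)
    dmr_merged = _merged_intervals(dmrs) if len(dmrs) else {}
    sets = []
    for _ in range(n_sets):
        rows = []
        for rec in dmrs.itertuples(index=False):
            length = rec.end - rec.start
            size = genome_sizes.get(rec.chrom)
            if size is None or size < length:
                raise ValueError(f"chromosome {rec.chrom} too short for a {length} bp control")
            for _try in range(max_tries):
                start = int(rng.integers(0, size - length + 1))
                probe = pd.DataFrame([{"chrom": rec.chrom, "start": start, "end": start + length}])
                if not _overlaps_any(probe, dmr_merged)[0]:
                    break
            else:
                raise ValueError(f"could not place a control on {rec.chrom} clear of DMRs")
            rows.append({"chrom": rec.chrom, "start": start, "end": start + length})
        sets.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return sets


def hypergeometric_overlap_p(k: int, universe: int, annotated: int, drawn: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for set-overlap significance."""
    return float(stats.hypergeom.sf(k - 1, universe, annotated, drawn))


@dataclass
class OverlapEnrichment:
    """Observed vs matched-control overlap of a region set with an annotation."""

    pct_dmrs: float
    mean_pct_controls: float
    empirical_p: float
    hypergeom_p: float
    n_dmrs_overlapping: int
    n_dmrs: int


def overlap_enrichment(
    dmrs: pd.DataFrame,
    annotation: pd.DataFrame,
    controls: list[pd.DataFrame],
) -> OverlapEnrichment:
    """Overlap percentage of DMRs vs matched controls, with two p values.

    A region overlaps when it shares >= 1 bp with the annotation.  The
    empirical p is ``(1 + #control sets with pct >= observed) / (1 + #sets)``;
    the hypergeometric p is the upper tail of the observed overlap count
    with the universe formed by the DMRs plus all control regions.
    """
    if annotation.empty:
        raise ValueError("annotation set is empty")
    if not controls:
        raise ValueError("need at least one control set for the empirical p")
    merged = _merged_intervals(annotation)
    dmr_hits = _overlaps_any(dmrs, merged)
    pct_dmrs = 100.0 * dmr_hits.mean() if len(dmrs) else 0.0
    control_hits = [_overlaps_any(c, merged) for c in controls]
    control_pcts = [100.0 * h.mean() if len(h) else 0.0 for h in control_hits]
    n_ge = sum(p >= pct_dmrs for p in control_pcts)
    empirical_p = (1 + n_ge) / (1 + len(controls))
    # hypergeometric universe: DMRs plus every control region
    M = len(dmrs) + sum(len(c) for c in controls)
    K = int(dmr_hits.sum()) + int(sum(h.sum() for h in control_hits))
    n_draw = len(dmrs)
    k = int(dmr_hits.sum())
    hyper_p = float(stats.hypergeom.sf(k - 1, M, K, n_draw))
    return OverlapEnrichment(
        pct_dmrs=float(pct_dmrs),
        mean_pct_controls=float(np.mean(control_pcts)),
        empirical_p=float(empirical_p),
        hypergeom_p=hyper_p,
        n_dmrs_overlapping=k,
        n_dmrs=len(dmrs),
    )
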