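"""BETA-style integration of DMRs with differential expression.

Each gene receives a regulatory potential

    S = sum over DMRs with center within 100 kb of the TSS of
        exp(-(0.5 + 4 * Delta)),      Delta = |center - TSS| / 100,000,

a distance-decayed sum that is 0 beyond the window, e^-0.5 at the TSS and
e^-4.5 at the window edge.  Genes classified up-/downregulated are then
tested for association with the potential two ways: a one-tailed
Kolmogorov-Smirnov comparison of the S-rank distributions of the UP (or
DOWN) class against the non-differential background, and a rank product
RP = (rank_S / N) * (rank_E / N) over the classified genes combining the
potential rank with the expression-evidence rank; genes below an RP
cutoff (0.001 by default) are called targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "regulatory_potential",
    "classify_de",
    "beta_function_test",
    "cumulative_rank_curves",
    "rank_product_targets",
    "dmr_gene_enrichment",
]

DEFAULT_WINDOW = 100_000


def regulatory_potential(
    genes: pd.DataFrame,
    dmrs: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.Series:
    """Distance-decayed regulatory potential of every gene, indexed by gene_id.

    Additive over DMRs; exactly 0 for genes with no DMR center within the
    window.  Monotone non-increasing in DMR-TSS distance.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    scores = np.zeros(len(genes))
    centers_by_chrom = {
        c: np.sort((g["start"].to_numpy() + g["end"].to_numpy()) // 2)
        for c, g in dmrs.groupby("chrom")
    }
    for i, rec in enumerate(genes.itertuples(index=False)):
        centers = centers_by_chrom.get(rec.chrom)
        if centers is None:
            continue
        lo = np.searchsorted(centers, rec.tss - window, side="left")
        hi = np.searchsorted(centers, rec.tss + window, side="right")
        near = centers[lo:hi]
        if near.size:
            delta = np.abs(near - rec.tss) / window
            scores[i] = np.sum(np.exp(-(0.5 + 4.0 * delta[delta <= 1.0])))
    return pd.Series(scores, index=genes["gene_id"].to_numpy(), name="regulatory_potential")


def classify_de(
    de: pd.DataFrame,
    p_max: float | None = 0.05,
    lfc_min: float = 0.0,
    p_col: str = "padj",
) -> pd.Series:
    """Assign UP / DOWN / NON expression classes from a DE table.

    With ``p_max`` set (the default), a gene is UP when ``log2fc > lfc_min``
    and its p column is below ``p_max`` (symmetric for DOWN) — the
    significance-based classes used for the activating/repressive function
    test.  With ``p_max=None`` the split is by fold-change sign alone
    (NON when ``|log2fc| <= lfc_min``), giving the broad directional
    universe over which the rank product is computed.
    """
    lfc = de["log2fc"]
    if p_max is None:
        cls = np.where(lfc > lfc_min, "UP", np.where(lfc < -lfc_min, "DOWN", "NON"))
    else:
        sig = de[p_col] < p_max
        cls = np.where(sig & (lfc > lfc_min), "UP", np.where(sig & (lfc < -lfc_min), "DOWN", "NON"))
    return pd.Series(cls, index=de.index, name="de_class")


def _s_ranks(S: pd.Series) -> pd.Series:
    """Ranks of the regulatory potential, 1 = highest S; ties share the mean."""
    return pd.Series(stats.rankdata(-S.to_numpy(), method="average"), index=S.index)


def beta_function_test(
    S: pd.Series, de_class: pd.Series
) -> dict[str, tuple[float, float]]:
    """One-tailed KS test of UP (and DOWN) S-rank distributions against NON.

    Genes are ranked by S descending over all genes; a class whose members
    concentrate at small ranks (high potential) relative to the background
    gives a small p.  Returns ``{class: (D, p)}`` for the classes present.
    """
    if not np.array_equal(S.index, de_class.index):
        raise ValueError("S and de_class must share an index")
    ranks = _s_ranks(S)
    non = ranks[de_class == "NON"].to_numpy()
    if non.size == 0:
        raise ValueError("empty NON background class")
    out: dict[str, tuple[float, float]] = {}
    for cls in ("UP", "DOWN"):
        grp = ranks[de_class == cls].to_numpy()
        if grp.size == 0:
            continue
        # 'greater': the class rank ECDF dominates the background, i.e. the
        # class sits at smaller ranks / higher potential
        res = stats.ks_2samp(grp, non, alternative="greater")
        out[cls] = (float(res.statistic), float(res.pvalue))
    return out


def cumulative_rank_curves(S: pd.Series, de_class: pd.Series) -> pd.DataFrame:
    """Cumulative fraction of each class along the S-descending rank axis."""
    order = np.argsort(_s_ranks(S).to_numpy(), kind="stable")
    classes = de_class.to_numpy()[order]
    frames = {}
    for cls in ("UP", "DOWN", "NON"):
        member = (classes == cls).astype(float)
        total = member.sum()
        frames[cls] = np.cumsum(member) / total if total else np.full(len(member), np.nan)
    return pd.DataFrame(frames, index=np.arange(1, len(classes) + 1))


def rank_product_targets(
    S: pd.Series,
    de_evidence: pd.Series,
    de_class: pd.Series,
    cutoff: float = 0.001,
) -> pd.DataFrame:
    """Rank-product target calling over the UP/DOWN genes.

    ``de_evidence`` is ranked ascending (smaller = stronger, e.g. the DE
    p value); S is ranked descending.  RP = (rank_S/N) * (rank_E/N) with
    ties sharing the mean rank; targets are genes with RP < ``cutoff``.
    """
    mask = de_class.isin(["UP", "DOWN"]).to_numpy()
    if not mask.any():
        raise ValueError("no UP/DOWN genes to rank")
    idx = S.index[mask]
    n = mask.sum()
    rank_s = stats.rankdata(-S.to_numpy()[mask], method="average")
    rank_e = stats.rankdata(de_evidence.to_numpy()[mask], method="average")
    rp = (rank_s / n) * (rank_e / n)
    return pd.DataFrame(
        {
            "gene_id": idx,
            "de_class": de_class.to_numpy()[mask],
            "rank_S": rank_s,
            "rank_E": rank_e,
            "rank_product": rp,
            "is_target": rp < cutoff,
        }
    ).set_index("gene_id")


def dmr_gene_enrichment(
    genes: pd.DataFrame,
    dmrs: pd.DataFrame,
    de_class: pd.Series,
    window: int = DEFAULT_WINDOW,
    mode: str = "count",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene near-DMR burden by expression class, with rank-sum p values.

    ``mode='count'`` scores each gene by the number of DMR centers within
    the window of its TSS; ``mode='potential'`` by the summed decayed
    potential.  Classes are compared against NON with a one-sided
    Mann-Whitney test (class > NON).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if mode not in ("count", "potential"):
        raise ValueError("mode must be 'count' or 'potential'")
    if mode == "potential":
        score = regulatory_potential(genes, dmrs, window).to_numpy()
    else:
        score = np.zeros(len(genes))
        centers_by_chrom = {
            c: np.sort((g["start"].to_numpy() + g["end"].to_numpy()) // 2)
            for c, g in dmrs.groupby("chrom")
        }
        for i, rec in enumerate(genes.itertuples(index=False)):
            centers = centers_by_chrom.get(rec.chrom)
            if centers is None:
                continue
            lo = np.searchsorted(centers, rec.tss - window, side="left")
            hi = np.searchsorted(centers, rec.tss + window, side="right")
            score[i] = hi - lo
    table = pd.DataFrame(
        {"gene_id": genes["gene_id"], "de_class": de_class.to_numpy(), "score": score}
    )
    pvals: dict[str, float] = {}
    non = table.loc[table["de_class"] == "NON", "score"].to_numpy()
    for cls in ("UP", "DOWN"):
        grp = table.loc[table["de_class"] == cls, "score"].to_numpy()
        if grp.size == 0 or non.size == 0:
            continue
        if dmrs.empty or (np.all(grp == grp[0]) and np.all(non == grp[0])):
            pvals[cls] = 1.0
            continue
        pvals[cls] = float(stats.mannwhitneyu(grp, non, alternative="greater").pvalue)
    return table, pvals
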