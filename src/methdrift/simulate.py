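"""Ground-truthed synthetic data with the statistical structure of the assay.

The generator emulates a replicated dietary-intervention WGBS design:
five animals per group, negative-binomial read coverage around 30x, a
sharply bimodal background methylation landscape (a lowly methylated
mode near 5 % for promoters/CpG islands and a highly methylated mode
near 94 % for the repetitive bulk), beta-binomial replicate counts whose
intra-group correlation rho captures biological variability between
animals — shared across ~1 kb blocks within each animal, as methylation
varies regionally rather than per CpG — and planted hyper-/hypo-
methylated regions of known location,
effect size and post-intervention persistence class.  Coupled expression
changes and a survival cohort driven by a latent gene-set activity score
complete the chain, so every downstream stage can be scored against known
truth.

Hyper-DMRs are planted on low-mode background and hypo-DMRs on high-mode
background, mirroring differential methylation arising at distal
regulatory elements; without this, clipping the shifted level into [0, 1]
would erase the planted effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CpGCountMatrix

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_methylome",
    "simulate_genes",
    "simulate_expression",
    "simulate_survival_cohort",
]


@dataclass
class SimulationConfig:
    """Knobs of the methylome generator; defaults are the study conditions.

    ``rho`` is the beta-binomial intra-class (per-read) correlation within
    a replicate; 0 means pure binomial sampling.  Persistence fractions
    apply to the post-intervention group and must sum to 1.
    """

    n_cpgs: int = 10_000
    n_replicates: int = 5
    groups: tuple[str, ...] = ("LF", "HF")  # add "HF-LF" for the 3-group design
    mean_coverage: float = 30.0
    coverage_dispersion: float = 15.0  # negative-binomial size parameter
    meth_low_mode: float = 0.05
    meth_high_mode: float = 0.94
    high_mode_weight: float = 0.7
    meth_concentration: float = 300.0  # beta concentration of background levels
    rho: float = 0.01
    corr_block_bp: int = 1_000  # length scale of shared replicate deviations
    corr_block_share: float = 0.6  # fraction of rho's copula variance that is regional
    n_hyper_dmrs: int = 25
    n_hypo_dmrs: int = 25
    dmr_width_range: tuple[int, int] = (1_500, 4_000)
    dmr_delta: float = 0.4
    retained_frac: float = 0.4
    lost_frac: float = 0.3
    intermediate_frac: float = 0.3
    retained_r: float = 1.0
    lost_r: float = 0.0
    intermediate_r: float = 0.5
    cpg_spacing_mean: float = 100.0
    min_dmr_separation: int = 10_000  # bp kept clear around each planted DMR
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        fr = self.retained_frac + self.lost_frac + self.intermediate_frac
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("persistence fractions must sum to 1")


@dataclass
class TruthTable:
    """Planted ground truth: DMR intervals and (optionally) coupled genes."""

    dmrs: pd.DataFrame  # dmr_id, chrom, start, end, direction, delta, persistence_class, r
    genes: pd.DataFrame | None = None  # gene_id, chrom, start, end, strand, tss, coupled, coupled_dmr
    config: SimulationConfig | None = None
    extras: dict = field(default_factory=dict)


def _beta_around(rng: np.random.Generator, mode: np.ndarray, conc: float) -> np.ndarray:
    mode = np.clip(mode, 1e-4, 1.0 - 1e-4)
    return rng.beta(mode * conc, (1.0 - mode) * conc)


def _place_dmrs(rng: np.random.Generator, pos: np.ndarray, config: SimulationConfig) -> pd.DataFrame:
    """Choose disjoint planted intervals, each padded by the separation gap."""
    n_total = config.n_hyper_dmrs + config.n_hypo_dmrs
    records: list[dict] = []
    taken: list[tuple[int, int]] = []
    directions = ["hyper"] * config.n_hyper_dmrs + ["hypo"] * config.n_hypo_dmrs
    span_end = int(pos[-1])
    max_tries = 200 * max(n_total, 1)
    tries = 0
    for direction in directions:
        width = int(rng.integers(config.dmr_width_range[0], config.dmr_width_range[1] + 1))
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    "could not place planted DMRs disjointly; "
                    "use fewer or narrower DMRs or a smaller separation"
                )
            start = int(rng.integers(0, max(span_end - width, 1)))
            end = start + width
            pad = config.min_dmr_separation
            if all(end + pad <= s or e + pad <= start for s, e in taken):
                lo = np.searchsorted(pos, start, side="left")
                hi = np.searchsorted(pos, end, side="left")
                if hi - lo >= 3:  # need a few CpGs inside to carry the signal
                    break
        taken.append((start, end))
        records.append({"chrom": config.chrom, "start": start, "end": end, "direction": direction})
    dmrs = pd.DataFrame(records, columns=["chrom", "start", "end", "direction"])
    if len(dmrs):
        dmrs = dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)
    dmrs["dmr_id"] = [f"true_dmr_{i + 1}" for i in range(len(dmrs))]
    return dmrs


def simulate_methylome(config: SimulationConfig) -> tuple[CpGCountMatrix, TruthTable]:
    """Draw a replicated methylome with planted DMRs of known truth.

    Background per-CpG methylation is shared across groups; inside a
    planted hyper-DMR the case-group level is background + delta (clipped
    to [0, 1]), hypo symmetric; the post-intervention level interpolates
    between control and case with the persistence ratio r of the DMR's
    class.  Identical configs (including seed) reproduce identical output.
    """
    rng = np.random.default_rng(config.seed)
    spacing = 2 + rng.poisson(max(config.cpg_spacing_mean - 2, 1), config.n_cpgs)
    pos = np.cumsum(spacing).astype(np.int64)
    chrom = np.full(config.n_cpgs, config.chrom, dtype=object)

    truth_dmrs = _place_dmrs(rng, pos, config)

    # persistence class per planted DMR
    n_dmrs = len(truth_dmrs)
    classes = np.array(["retained", "lost", "intermediate"], dtype=object)
    r_by_class = {
        "retained": config.retained_r,
        "lost": config.lost_r,
        "intermediate": config.intermediate_r,
    }
    probs = [config.retained_frac, config.lost_frac, config.intermediate_frac]
    cls = rng.choice(classes, size=n_dmrs, p=probs) if n_dmrs else np.array([], dtype=object)
    truth_dmrs["persistence_class"] = cls
    truth_dmrs["r"] = [r_by_class[c] for c in cls]
    truth_dmrs["delta"] = np.where(truth_dmrs["direction"] == "hyper", config.dmr_delta, -config.dmr_delta)

    # background modes; planted DMRs pin the mode so the shift survives clipping
    high = rng.random(config.n_cpgs) < config.high_mode_weight
    in_dmr = np.zeros(config.n_cpgs, dtype=bool)
    for rec in truth_dmrs.itertuples(index=False):
        inside = (pos >= rec.start) & (pos < rec.end)
        in_dmr |= inside
        high[inside] = rec.direction == "hypo"
    mode = np.where(high, config.meth_high_mode, config.meth_low_mode)
    background = _beta_around(rng, mode, config.meth_concentration)

    level = {g: background.copy() for g in config.groups}
    case_groups = [g for g in config.groups if g != "LF"]
    if "HF" in level:
        hf = background.copy()
        for rec in truth_dmrs.itertuples(index=False):
            inside = (pos >= rec.start) & (pos < rec.end)
            hf[inside] = np.clip(background[inside] + rec.delta, 0.0, 1.0)
        level["HF"] = hf
        if "HF-LF" in level:
            fo = background.copy()
            for rec in truth_dmrs.itertuples(index=False):
                inside = (pos >= rec.start) & (pos < rec.end)
                fo[inside] = background[inside] + rec.r * (hf[inside] - background[inside])
            level["HF-LF"] = fo
    elif case_groups:
        raise ValueError("the two-group design must include groups 'LF' and 'HF'")

    meth: dict[str, np.ndarray] = {}
    total: dict[str, np.ndarray] = {}
    size = config.coverage_dispersion
    p_nb = size / (size + config.mean_coverage)
    shape = (config.n_cpgs, config.n_replicates)
    for g in config.groups:
        tot = rng.negative_binomial(size, p_nb, shape).astype(np.int64)
        p_site = np.clip(level[g], 0.0, 1.0)[:, None]
        if config.rho == 0.0:
            m = rng.binomial(tot, np.broadcast_to(p_site, shape))
        else:
            # Beta-binomial replicate levels with exact per-site marginals and
            # regionally correlated deviations: a Gaussian copula shares a
            # block-level animal effect across CpGs within corr_block_bp, so
            # biological variability acts on methylation domains rather than
            # on isolated CpGs (as in real comethylated WGBS data).
            conc = 1.0 / config.rho - 1.0
            a = np.maximum(p_site * conc, 1e-9)
            b = np.maximum((1.0 - p_site) * conc, 1e-9)
            block_idx = pos // max(config.corr_block_bp, 1)
            block_idx = np.searchsorted(np.unique(block_idx), block_idx)
            n_blocks = block_idx.max() + 1
            phi = config.corr_block_share
            z_block = rng.standard_normal((n_blocks, config.n_replicates))
            z_site = rng.standard_normal(shape)
            z = np.sqrt(phi) * z_block[block_idx] + np.sqrt(1.0 - phi) * z_site
            u = stats.norm.cdf(z)
            p_rep = stats.beta.ppf(u, np.broadcast_to(a, shape), np.broadcast_to(b, shape))
            p_rep = np.where(p_site <= 0, 0.0, np.where(p_site >= 1, 1.0, p_rep))
            m = rng.binomial(tot, p_rep)
        meth[g] = m.astype(np.int64)
        total[g] = tot

    matrix = CpGCountMatrix(chrom, pos, meth, total)
    truth = TruthTable(dmrs=truth_dmrs, config=config)
    truth.extras["background"] = background
    truth.extras["level"] = level
    return matrix, truth


def simulate_genes(
    config: SimulationConfig,
    truth: TruthTable,
    n_genes: int = 2_000,
    coupled_per_dmr: int = 2,
    coupling_window: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Place gene models: coupled genes near planted DMRs, the rest far away.

    Each planted DMR receives ``coupled_per_dmr`` genes whose TSS lies
    within half the coupling window of the DMR center; uncoupled genes
    are laid out on a gene territory starting 150 kb past the methylome
    so no uncoupled gene sits within the window of any planted DMR.  The
    stratified placement reproduces, at desk scale, the sparsity of DMRs
    relative to genes in a mammalian genome.  The frame is stored on
    ``truth.genes``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    dmrs = truth.dmrs
    records = []
    gid = 0
    for rec in dmrs.itertuples(index=False):
        center = (rec.start + rec.end) // 2
        for _ in range(coupled_per_dmr):
            offset = int(rng.integers(-coupling_window // 2, coupling_window // 2 + 1))
            tss = max(center + offset, 0)
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = (tss, tss + 1_000) if strand == "+" else (max(tss - 999, 0), tss + 1)
            gid += 1
            records.append(
                {
                    "gene_id": f"gene_{gid:05d}",
                    "chrom": rec.chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": tss,
                    "coupled": True,
                    "coupled_dmr": rec.dmr_id,
                    "coupled_direction": rec.direction,
                }
            )
    n_far = n_genes - len(records)
    if n_far < 0:
        raise ValueError("n_genes smaller than the number of coupled genes")
    territory_start = int(dmrs["end"].max() if len(dmrs) else 0) + 150_000
    far_tss = territory_start + np.sort(rng.choice(n_far * 20_000, size=n_far, replace=False))
    for tss in far_tss:
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(tss)
        start, end = (tss, tss + 1_000) if strand == "+" else (tss - 999, tss + 1)
        gid += 1
        records.append(
            {
                "gene_id": f"gene_{gid:05d}",
                "chrom": config.chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "tss": tss,
                "coupled": False,
                "coupled_dmr": None,
                "coupled_direction": None,
            }
        )
    genes = pd.DataFrame(records).sort_values(["chrom", "tss"]).reset_index(drop=True)
    truth.genes = genes
    return genes


def simulate_expression(
    config: SimulationConfig,
    truth: TruthTable,
    coupling_strength: float = 1.5,
    lfc_se: float = 0.25,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a differential-expression table coupled to the planted DMRs.

    Genes coupled to hyper-DMRs are biased down (true log2 fold change
    ``-coupling_strength``), hypo-coupled genes up, uncoupled genes null.
    Observed log2fc = truth + N(0, lfc_se); the p value is the two-sided
    normal tail of log2fc / lfc_se, BH-adjusted into ``padj``.
    """
    if truth.genes is None:
        raise ValueError("truth lacks gene models; run simulate_genes first")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    genes = truth.genes
    mu = np.zeros(len(genes))
    mu[(genes["coupled"]) & (genes["coupled_direction"] == "hyper")] = -coupling_strength
    mu[(genes["coupled"]) & (genes["coupled_direction"] == "hypo")] = coupling_strength
    lfc = mu + rng.normal(0.0, lfc_se, len(genes))
    z = lfc / lfc_se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    from statsmodels.stats.multitest import multipletests

    padj = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "log2fc": lfc,
            "pvalue": pvalue,
            "padj": padj,
        }
    )


def simulate_survival_cohort(
    n_samples: int,
    n_genes: int,
    set_definitions: dict[str, set[str]],
    effect: float = 1.0,
    seed: int = 0,
    baseline_rate: float = 0.1,
    censor_max: float = 30.0,
    hazard_sets: list[str] | None = None,
    allow_negative_effect: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix plus clinical table driven by latent set activities.

    Every gene set gets an independent per-sample latent activity
    ~ N(0, 1) that shifts its member genes' expression by ``effect`` times
    the activity.  The event rate of the exponential survival times is
    ``baseline_rate * exp(-effect * activity)`` summed over
    ``hazard_sets`` (default: the first set), so samples with low activity
    of that set — e.g. depressed fatty-acid metabolism — die sooner.
    Censoring times are uniform on (0, ``censor_max``).

    Returns ``(expression genes x samples, clinical table)``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if effect < 0 and not allow_negative_effect:
        raise ValueError("negative effect needs allow_negative_effect=True")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i:05d}" for i in range(1, n_genes + 1)]
    sample_ids = [f"sample_{i:04d}" for i in range(1, n_samples + 1)]
    for name, members in set_definitions.items():
        missing = set(members) - set(gene_ids)
        if missing:
            raise ValueError(f"gene set {name!r} references unknown genes: {sorted(missing)[:3]}")
    expr = rng.normal(0.0, 1.0, (n_genes, n_samples))
    latent = {name: rng.normal(0.0, 1.0, n_samples) for name in set_definitions}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for name, members in set_definitions.items():
        rows = [gene_index[g] for g in sorted(members)]
        expr[rows, :] += effect * latent[name][None, :]
    hazard_sets = hazard_sets or [next(iter(set_definitions))]
    log_rate = np.log(baseline_rate) - effect * sum(latent[s] for s in hazard_sets)
    event_time = rng.exponential(1.0 / np.exp(log_rate))
    censor_time = rng.uniform(0.0, censor_max, n_samples)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": "tumor",
            "survival_time": observed,
            "event": event,
        }
    )
    for name in set_definitions:
        clinical[f"latent_{name}"] = latent[name]
    return expression, clinical
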