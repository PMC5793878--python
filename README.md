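# methdrift

Differential DNA methylation analysis for replicated whole-genome
bisulfite sequencing (WGBS), built around the question of whether a
dietary exposure leaves a lasting epigenetic mark: call differentially
methylated regions (DMRs) between replicate groups, link them to gene
expression changes, quantify which DMRs persist after an intervention,
and stratify a tumor cohort by gene-set activity for survival analysis.
A ground-truthed synthetic-data generator covers the whole chain, so
every stage is testable without external data.

Intended users: computational biologists analysing replicated
two- or three-group WGBS designs (e.g. diet studies in inbred mice) with
matched RNA-seq differential-expression tables and, downstream, clinical
expression cohorts.

## Methods at a glance

**Site test (Rao-Scott-corrected LRT).** At each CpG, replicate counts
are pooled per group and the binomial likelihood-ratio statistic

&nbsp;&nbsp;G² = 2·[ℓ(p̂₁) + ℓ(p̂₂) − ℓ(p̂₀)]

is deflated by a design effect estimated from the between-replicate
heterogeneity chi-square, X²ₕ = Σⱼ (mⱼ − tⱼp̂)² / (tⱼp̂(1−p̂)).  The
corrected statistic G²/d̄, with d̄ the pooled unclamped heterogeneity
ratio, is referred to F(1, df₁+df₂); with one replicate per group the
test reduces exactly to the uncorrected binomial G-test.  Per-group
clamped design effects dg = max(1, X²ₕ/(n−1)) define the *effective
coverage* Σg Tg/dg used by the coverage filter.

**DMR calling.** Sites with p < 0.05, |Δ| > 10 % and effective coverage
≥ 10 are merged (same direction, successive gaps ≤ 5,000 bp), candidate
regions are re-tested on summed member counts, and regions pass with
Benjamini-Hochberg-adjusted p < 0.01, |Δ| > 30 % or proportion fold
change > 5 (ε = 0.01 zero guard), and ≥ 2 member CpGs.

**DMR-expression integration (BETA-style).** Gene regulatory potential
S = Σ exp(−(0.5 + 4Δ)) over DMRs with centers within 100 kb of the TSS
(Δ = distance/100 kb); one-tailed KS tests of the up-/downregulated
classes against the non-differential background; rank product
RP = (rank_S/N)·(rank_E/N) with targets at RP < 0.001.

**Persistence.** Retention index r = (m_FO − m_LF)/(m_HF − m_LF) per
DMR (1 = change fully retained after the intervention, 0 = fully
reversed), thresholded into retained/lost/intermediate, plus a k-means
view (k = 6, clusters C1..C6 ordered by mean r).

**Cohort stratification.** Per-sample ssGSEA scores
ES = Σᵢ [P_in^w(i) − P_out(i)] with rank weights rank^0.25, 2×2
median-split strata, Kaplan-Meier curves and the log-rank test.

## Worked example

`examples/01_simulate_and_call_dmrs.py` simulates a 50,000-CpG
methylome for 5 control and 5 case replicates at 30× coverage with 50
planted DMRs (|Δ| = 0.4), runs the full caller and scores the calls:

```
stage counts: {'sites_tested': 50000, 'sites_skipped_one_group': 0, 'dm_sites': 1549,
               'candidate_regions': 143, 'passing_dmrs': 50, 'hyper_dmrs': 25, 'hypo_dmrs': 25}
  chrom   start     end direction  n_dm_cpgs     delta         p_adj
0  chr1  100956  108862     hyper         35  0.376349  8.378700e-09
...
recall=0.98 precision=0.98
```

Of 50,000 CpGs, 1,549 pass the site filters, merge into 143 candidate
regions, and 50 survive the region-level re-test; 49 of them match a
planted region at ≥ 50 % reciprocal overlap and the one miss is a
boundary extension over a planted region, not a spurious call.  The remaining examples cover annotation enrichment
(`02`), BETA target calling (`03`, recovering 100/100 planted
DMR-coupled genes at RP < 0.001), persistence after the intervention
(`04`), and cohort stratification with survival (`05`, where the
low-fatty-acid-metabolism stratum shows survival 0.35 vs 0.74 at t = 5,
log-rank p ≈ 9×10⁻¹⁶).

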