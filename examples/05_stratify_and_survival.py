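"""Stratify a tumor cohort by gene-set activity and compare survival.

Scores every sample with single-sample gene-set enrichment (ssGSEA) for
fatty-acid metabolism and glycolysis, splits the cohort 2x2 at the score
medians, and compares overall survival of low vs high fatty-acid
metabolism with Kaplan-Meier curves and the log-rank test.
"""

import numpy as np

from methdrift import clinical as mc
from methdrift.simulate import simulate_survival_cohort

gene_ids = [f"gene_{i:05d}" for i in range(1, 1001)]
gene_sets = {
    "FATTY_ACID_METABOLISM": set(gene_ids[:50]),
    "GLYCOLYSIS": set(gene_ids[50:100]),
}
expression, clinical = simulate_survival_cohort(
    n_samples=200, n_genes=1000, set_definitions=gene_sets, effect=1.0, seed=3
)

scores = mc.ssgsea_matrix(expression, gene_sets)
strata = mc.stratify_samples(scores)
print(strata.stratum.value_counts().to_string())

low = (strata["FATTY_ACID_METABOLISM_level"] == "low").to_numpy()
km_low = mc.km_estimate(clinical.survival_time[low], clinical.event[low])
km_high = mc.km_estimate(clinical.survival_time[~low], clinical.event[~low])
t = 5.0
s_low = km_low.loc[km_low.time <= t, "survival"].min()
s_high = km_high.loc[km_high.time <= t, "survival"].min()
stat, p = mc.logrank_test(
    clinical.survival_time[low], clinical.event[low],
    clinical.survival_time[~low], clinical.event[~low],
)
print(f"survival at t={t}: low-FA {s_low:.2f} vs high-FA {s_high:.2f}")
print(f"log-rank chi2={stat:.1f}, p={p:.2e}")
# a small p with lower survival in the low-FA stratum reproduces the
# association between depressed fatty-acid metabolism and poor outcome
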