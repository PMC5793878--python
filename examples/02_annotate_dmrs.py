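"""Annotate called DMRs: TSS distances and overlap enrichment.

Builds matched random control regions (same lengths, same chromosome)
and asks whether DMRs overlap an annotation set more often than chance,
with both an empirical and a hypergeometric p value.
"""

import pandas as pd

import methdrift as md
from methdrift.annotate import distance_to_nearest_tss, generate_matched_controls, overlap_enrichment
from methdrift.simulate import simulate_genes

config = md.SimulationConfig(n_cpgs=20_000, seed=3)
matrix, truth = md.simulate_methylome(config)
result = md.call_dmrs(matrix, "LF", "HF")
dmrs = pd.concat([result.hyper, result.hypo]).reset_index(drop=True)

genes = simulate_genes(config, truth, n_genes=300)
dist = distance_to_nearest_tss(dmrs, genes)
print(dist[["chrom", "start", "end", "distance", "nearest_gene"]].head())

# an annotation that tiles the planted regions should be enriched
annotation = truth.dmrs[["chrom", "start", "end"]]
genome = {"chr1": int(matrix.pos.max()) + 10_000}
controls = generate_matched_controls(dmrs, genome, n_sets=50, seed=1)
enr = overlap_enrichment(dmrs, annotation, controls)
print(
    f"DMRs overlapping annotation: {enr.pct_dmrs:.0f}% "
    f"(controls: {enr.mean_pct_controls:.0f}%), "
    f"empirical p={enr.empirical_p:.3g}, hypergeometric p={enr.hypergeom_p:.3g}"
)
# a small p says the called DMRs sit in the annotated intervals far more
# often than equally sized regions dropped at random on the same chromosome
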