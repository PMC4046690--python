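"""Run the whole analysis end to end on a synthetic bundle.

Stages: generate inputs -> adjacent pairs -> per-pair features (d, #CTCF,
ΔCpG_O/E, ExpD_1-r, ExpD_Euc, d_S, T_phy) -> stratified correlation tables
-> top-quartile #CTCF/d GO enrichment -> divergence-time re-test on the
enriched-GO pair subset.  Everything lands in an output directory as TSV
plus a manifest of every decision flag and filter count.
"""

import pandas as pd

from ctcf_divergence import GeneratorConfig, RunConfig, run_all

config = RunConfig(generator=GeneratorConfig(seed=7, n_chrom=4,
                                             genes_per_chrom=200))
manifest = run_all(config, "scratch_run")

print("filter counts:", manifest.counts)

paralog = pd.read_csv("scratch_run/assoc_paralog.tsv", sep="\t")
print("\nparalog stratum (each x controlling for the other two):")
cols = ["x", "y", "rho", "rho_partial", "p_partial"]
print(paralog[cols].to_string(index=False,
                              float_format=lambda v: f"{v:+.3f}"))

enr = pd.read_csv("scratch_run/enrichment.tsv", sep="\t")
hits = enr[enr.p_bonf < 0.05]
print(f"\nBonferroni-significant GO terms: "
      f"{list(zip(hits.term, hits.stratum, hits.direction))}")
# Expected pattern: #CTCF keeps a positive partial correlation with both
# divergence measures, the partial distance effect is null (it is mediated
# by #CTCF in the generator), and the planted GO term surfaces as enriched
# in the paralog stratum.
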