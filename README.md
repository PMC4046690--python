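# ctcf-divergence

Do insulator binding sites between adjacent genes drive those genes apart in
expression? CTCF, the only known human insulator protein, can block
enhancer–promoter crosstalk and stop heterochromatin spread; if its binding
sites accumulate between two neighbouring genes — in particular between a
tandemly duplicated gene and its progenitor — the two promoters can evolve
independent regulation. `ctcf-divergence` is a pipeline for testing that
hypothesis on gene annotation, multi-cell-type CTCF ChIP-seq peaks, tissue
expression matrices, upstream sequences, paralog tables and GO annotation,
and it ships a synthetic-data generator that plants the hypothesised causal
structure so every stage is testable end-to-end without external downloads.

For each adjacent gene pair the pipeline measures

* **d** — intergenic distance, nucleotides between the two transcription
  start sites;
* **#CTCF** — intervening CTCF-binding sites, counted on the *overlapping*
  consensus (binding regions present in all cell types) or the *joint*
  consensus (union across cell types), plus the density **#CTCF/d**;
* **ΔCpG_O/E** — absolute difference in the upstream CpG observed/expected
  ratio, `CpG_O/E = P_CpG / (P_C × P_G)` over the 500 nt upstream of each
  TSS (a germline DNA-methylation proxy);
* **ExpD_1-r** = 1 − Pearson r and **ExpD_Euc** = Euclidean distance of the
  tissue expression vectors (profile vs. level divergence);
* **d_S** and **T_phy** — synonymous divergence and ordinal phylogenetic age
  of paralog pairs (divergence-time proxies),

then runs Spearman rank correlations ρ and partial rank correlations ρ_p
(each covariate controlling for the other two) within relation and
orientation strata, and a top-quartile **#CTCF/d** GO-term
enrichment/depletion analysis (two-sided Fisher exact, Bonferroni within
stratum) with a divergence-time re-test on the enriched-GO pair subset.

## Worked example

```python
import pandas as pd
from ctcf_divergence import GeneratorConfig, RunConfig, run_all

config = RunConfig(generator=GeneratorConfig(seed=7, n_chrom=4,
                                             genes_per_chrom=200))
manifest = run_all(config, "scratch_run")
print(pd.read_csv("scratch_run/assoc_paralog.tsv", sep="\t")
        [["x", "y", "rho", "rho_partial", "p_partial"]])
```

prints (paralog stratum, each covariate controlling for the other two):

```
             x        y    rho  rho_partial  p_partial
             d  expd_1r +0.283       +0.017     +0.760
n_ctcf_overlap  expd_1r +0.754       +0.729     +0.000
     delta_cpg  expd_1r +0.028       -0.026     +0.640
             d expd_euc +0.108       -0.036     +0.510
n_ctcf_overlap expd_euc +0.345       +0.339     +0.000
     delta_cpg expd_euc +0.370       +0.375     +0.000
```

Read: distance correlates with profile divergence marginally (ρ = +0.28)
but its partial correlation is null once #CTCF and ΔCpG_O/E are controlled —
in this bundle the distance effect is entirely mediated by the intervening
sites, while #CTCF keeps a strong direct association with both divergence
measures. The run directory also contains the non-paralog and
per-orientation tables, the divergence-time table, `enrichment.tsv` (here
the planted GO term surfaces as specifically enriched in the paralog
stratum), the consensus BED files, and `manifest.json` recording every
decision flag and filter count.

The same analysis runs from the shell:

```sh
ctcf-divergence run-all --out runs/demo --seed 7
ctcf-divergence run-all --out runs/demo_joint --inputs runs/demo/inputs \
    --ctcf-dialect joint        # robustness re-run on the union consensus
```

`examples/` holds one short narrative script per capability (bundle
generation, consensus construction, divergence scores, partial correlation,
full pipeline).

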