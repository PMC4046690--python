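# Methods

## The analysis

`ctcf_divergence` tests whether insulator (CTCF) binding sites located
between adjacent human genes drive divergence of those genes' expression,
with tandemly duplicated (adjacent paralogous) genes as the case of interest.
The pipeline has six stages:

1. **Pair construction.** Genes are sorted by (chromosome, start); every
   consecutive couple on a chromosome forms an adjacent pair. A pair is
   *paralogous* iff its unordered id pair appears in the supplied paralog
   table — only directly adjacent paralogs, i.e. tandem neighbours, qualify;
   same-family paralogs separated by intervening genes are not paired.
   Orientation follows the strands of (left, right): `-/+` head-to-head
   (divergent), same strand head-to-tail, `+/-` tail-to-tail (convergent).
2. **Genomic covariates.** For each pair: intergenic distance
   `d = |TSS_left − TSS_right|` in bp; the intervening CTCF-site count
   `#CTCF` in two dialects (below); the density `#CTCF/d`; and
   `ΔCpG_O/E`, the absolute difference of the upstream CpG
   observed/expected ratios, a proxy for germline promoter methylation
   (methylated CpGs deaminate over evolutionary time, so a CpG-depleted
   upstream window marks a methylated-like promoter).
3. **Expression divergence.** Across the tissue panel,
   `ExpD_1-r = 1 − Pearson r` (profile-shape dissimilarity, in [0, 2]) and
   `ExpD_Euc` = Euclidean distance (level dissimilarity). They deliberately
   dissociate: scaling one vector leaves `ExpD_1-r` at 0 but moves
   `ExpD_Euc`.
4. **Divergence time.** For paralog pairs, `d_S` (synonymous substitutions
   per site, supplied in the paralog table, estimated externally) and
   `T_phy` (ordinal age rank of the annotated most recent common ancestor).
5. **Inference.** Spearman rank correlation ρ of each genomic covariate
   with each divergence measure, and partial Spearman ρ_p controlling for
   the other two covariates, computed within strata (relation, orientation)
   and on the divergence-time targets for paralogs.
6. **Enrichment.** Pairs in the top quartile of `#CTCF/d` versus the bottom
   three quartiles; per GO term, a two-sided Fisher exact test on the 2×2
   (term × top/rest) table over member genes, Bonferroni-corrected within
   the stratum's family; paralog and non-paralog strata are independent
   families, and a term is *specifically* enriched when significant in one
   and not in the other. Pairs carrying a specifically enriched term feed a
   repeat of the divergence-time correlations on that subset.

## Definitions and numerical choices

**Coordinates.** Gene coordinates are 1-based inclusive (GTF convention);
peaks are 0-based half-open (BED convention); all comparisons convert to
0-based half-open once. The TSS of a minus-strand gene is its annotated
`end`.

**CpG_O/E.** Computed on the 500 nt upstream of the TSS:
`CpG_O/E = P_CpG / (P_C × P_G)` with `P_CpG` the count of overlapping CpG
dinucleotides divided by `L − 1` (the number of dinucleotide positions) and
`P_C`, `P_G` mononucleotide frequencies over the `L` unambiguous bases. The
formula is denominator-convention sensitive; the `L − 1` choice is the exact
dinucleotide-frequency denominator and is echoed in the run manifest.
Ambiguity characters (N) are excluded from `L` and dinucleotides spanning an
N are skipped. `CpG_O/E` is not estimable when C or G is absent; such genes
drop their pairs. Upstream windows are clipped at the chromosome origin.

**Consensus dialects.** `overlapping` = base-wise intersection across all
cell types, re-segmented into maximal intervals (each maximal segment is one
site); `joint` = merged union, touching intervals coalescing. Counting is by
≥ 1 bp overlap of a consensus interval with the inter-TSS window
`[min(TSS), max(TSS))` — the window that covers exactly `d` bases, matching
the distance definition. Both dialects are computed on every pair so the
robustness re-run is a single flag. Segment counting is the default; the
open alternative (projecting original per-cell-type peaks) was rejected
because it makes the count depend on an arbitrary reference cell type.

**Rank statistics.** Ties get average (fractional) ranks. Spearman p-values
use `t = ρ·sqrt((n−2)/(1−ρ²))` on `n−2` df, two-sided. The partial
estimator regresses the ranks of x and of y on the control ranks (with
intercept) and correlates the residuals; p from `t` on `n−2−k` df. With zero
controls it reduces exactly to plain Spearman. Rows missing any variable of
an analysis are dropped listwise per analysis, with `n` reported per cell;
d_S values above 10 (the usual saturation convention) are excluded from rank
correlations. A stratum below `min_n` complete rows is flagged rather than
estimated. Permutation null envelopes (for "is this partial correlation
distinguishable from no association") permute y and take the 95th percentile
of |ρ_p| over 200 permutations, vectorised through the QR residual-maker of
the fixed design.

**Quartile split.** Top `⌈n/4⌉` pairs by density; ties spanning the cut
break by stable pair-id order and are logged, so a permuted input order
changes nothing but the log. Zero-distance pairs have density 0 when they
have no sites and are otherwise flagged and excluded from density analyses.

**GO level.** Ontology depth is an explicit per-term input column (depth 4
is tested by default); `term_depths_from_obo` derives min-depths from an OBO
file when only the ontology graph is available. Making depth an input keeps
the statistic reproducible across annotation releases.

**Age map.** The shipped ancestor→rank ladder (Homo sapiens 0 …
Opisthokonta 14) is the standard Ensembl human ancestor ladder and is a
synthetic stand-in for any study-specific table; it is override-able per run
and its provenance is recorded in the manifest.

**Detectable expression** = signal > 0 in at least one tissue (the simplest
reproducible rule; configurable). A constant expression vector leaves
Pearson r undefined, so such pairs get `ExpD_1-r = NaN` and drop from
profile analyses only. Expression signals are used raw by default;
`log2(x+1)` is available — the literal divergence formulas apply to whatever
scale is chosen, and the choice is recorded in the manifest.

## The synthetic-data generator

The generator emits a complete input bundle with the causal structure the
analysis is meant to detect, so every stage is testable without downloads.

* Each adjacent pair carries a latent divergence time `t ~ U(0,1)`. For
  paralog pairs `d_S = 2t·exp(ε)`, ε ~ N(0, 0.15²) (so d_S spans ~0–2.4
  substitutions/site) and `T_phy` is `t` binned onto the 15-rung ancestor
  ladder.
* Site accumulation is Poisson in latent time:
  `#core ~ Poisson(2 + 3·d_S-scale·t)` — the simplest process consistent
  with gradual accumulation of binding sites after duplication (a
  birth–death alternative was considered and left out of scope).
* The core sites (200 bp) are written into all 13 cell types' peak files;
  each pair's gap additionally receives private 100 bp peaks (Poisson mean
  2) assigned to single cell types in disjoint slots, which guarantees
  per-base that the overlapping consensus equals the planted core exactly
  and the joint consensus strictly contains it.
* In the default `d_through_ctcf` mediation mode, the inter-gene gap is
  `500 + 250·#core + U(0, 800)` bp: distance grows with the site count but
  has no direct expression effect. The `independent` mode draws the gap from
  `U(1000, 25000)` with a capacity floor.
* Upstream 500-mers come from a first-order Markov chain whose C→G
  transition is tuned (with adaptive rejection, tolerance ±0.1) to per-gene
  target CpG_O/E values drawn from U(0.2, 1.4) — methylated-like to
  unmethylated-like.
* Expression profiles form a chain along each chromosome: the next gene's
  tissue profile is a mixture of its neighbour's and a fresh Dirichlet-like
  profile with weight `clip(0.08·#core + ε, 0.02, 0.95)` (profile
  divergence), and its log-level follows an AR(0.8) mean-reverting walk with
  an offset of magnitude `0.8·ΔCpG_target` (level divergence). Mean
  reversion keeps the dynamic range biological over hundreds of genes.
* One designated GO term is assigned at 5× the 0.08 background rate to
  member genes of top-quartile-`#CTCF/d` paralog pairs; 30 background terms
  plus two off-level decoys exercise the level filter.
  `redraw_ontology` re-runs only this step on an existing bundle for
  replicated calibration/power studies.

All randomness flows from one seed through named substreams (one per file
kind), so adding a file kind never perturbs existing outputs and a fixed
seed yields byte-identical bundles.

**Default size.** 10 chromosomes × 500 genes gives 4,990 adjacent pairs
with 45% paralogous (≈ 2,240 paralog pairs) — large enough for well-powered
stratified partial correlations while a full generate-and-analyze cycle
stays around two seconds; genome-scale proportions (≈ 4% of pairs
paralogous) remain one config change away. Replicated studies (the
zero-accumulation null calibration, enrichment calibration/power) reuse the
in-memory feature path at this default size.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: real chromosome lengths and gene density, CTCF
motif sequence content, shared enhancers and 3-D contact structure,
read-level measurement noise in expression signals, correlated GO
annotation structure (term–term dependence), and alignment/assembly
artefacts. Recovery of the planted signatures demonstrates that the
statistical machinery detects the hypothesised structure when present and
stays calibrated when absent — not that the structure is present in any
particular real dataset.

## Known limitations

* The intersection consensus treats each maximal intersected segment as one
  site; fragmented peaks in one cell type can split a site into several.
* Partial Spearman removes only rank-linear control effects; strongly
  nonlinear confounding on heavily tied controls can leave residual
  association (visible as small but non-zero partials in extreme toy
  settings).
* Bonferroni across a stratum's terms is deliberately conservative; no FDR
  alternative is offered.
* The ordinal age map compresses unknown branch lengths; `T_phy` supports
  rank analyses only.
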