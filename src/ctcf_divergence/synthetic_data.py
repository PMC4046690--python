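"""Synthetic input bundles with planted effects.

The generator emits every file format the readers consume — gene annotation,
per-cell-type peak BEDs, upstream FASTA, tissue expression matrix, paralog
table, GO annotation — plus the ground truth, with the causal structure the
analysis is designed to detect:

* each adjacent pair carries a latent divergence time ``t ~ U(0,1)``; for
  paralog pairs ``d_S`` is a noisy multiple of ``t`` and ``T_phy`` is its
  binned ordinal image on the shipped ancestor ladder;
* intervening CTCF sites accumulate over time: the planted core-site count is
  Poisson(lam0 + b_ctcf_per_ds * d_S-scale * t).  The core sites are written
  into *every* cell type's peak file, and each cell type additionally gets
  private peaks placed in per-pair slots that never share a base across cell
  types — so the overlapping (intersection) consensus recovers the planted
  core exactly and the joint (union) consensus strictly contains it;
* in ``mediation_mode='d_through_ctcf'`` the intergenic gap grows with the
  planted site count but has no direct expression effect, so the marginal
  distance/divergence correlation vanishes once #CTCF is controlled;
* upstream sequences are sampled from a first-order dinucleotide chain tuned
  to per-gene target CpG_O/E values;
* expression profiles form a chain along each chromosome: the next gene's
  tissue profile is a mixture of its neighbour's profile and a fresh one with
  mixing weight increasing in the planted #CTCF (profile divergence), and its
  level gets a log-offset whose magnitude increases with the pair's planted
  ΔCpG_O/E (level divergence);
* one designated GO term is assigned at an elevated rate to member genes of
  top-quartile-#CTCF/d paralog pairs.

All randomness flows from one seed through named substreams (one per file
kind), so adding a file kind never perturbs existing outputs, and a fixed
seed yields byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import genome_io
from .divergence_time import AgeMap
from .genome_io import ExpressionMatrix, GeneRecord, ParalogTable, make_gene

__all__ = ["GeneratorConfig", "Bundle", "generate", "redraw_ontology",
           "tune_sequence_cpg"]

# fixed substream ids: appending new kinds must not renumber existing ones
_STREAMS = {"latent": 0, "coords": 1, "peaks": 2, "sequence": 3,
            "expression": 4, "ontology": 5}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic bundle.

    Defaults give ~5,000 genes in ~4,990 adjacent pairs of which ~45% are
    paralogous (>= 2,000 paralog pairs, enough for well-powered stratified
    rank correlations); 13 cell types and 6 tissues mirror the CTCF ChIP-seq
    panel and the adult-tissue RNA-seq panel the analysis design assumes.
    """

    seed: int = 0
    n_chrom: int = 10
    genes_per_chrom: int = 500
    frac_paralog: float = 0.45
    n_cell_types: int = 13
    n_tissues: int = 6
    # site accumulation: Poisson(lam0 + b_ctcf_per_ds * ds) with ds = ds_scale * t
    lam0: float = 2.0
    b_ctcf_per_ds: float = 3.0
    ds_scale: float = 2.0
    # couplings into expression divergence
    w_profile: float = 0.08   # mixing weight per planted site
    w_level: float = 0.8      # log-level offset per unit planted ΔCpG_O/E
    mediation_mode: str = "d_through_ctcf"  # or "independent"
    # geometry
    peak_width: int = 200
    private_rate: float = 2.0  # mean private peaks per pair gap
    gene_len_min: int = 500
    gene_len_max: int = 3000
    flank: int = 500
    # upstream CpG depletion range (methylated-like 0.2 ... unmethylated-like 1.4)
    cpg_min: float = 0.2
    cpg_max: float = 1.4
    # ontology planting
    n_background_terms: int = 30
    p_background: float = 0.08
    planted_factor: float = 5.0

    def validate(self) -> None:
        if not (0.0 <= self.frac_paralog <= 1.0):
            raise ValueError("frac_paralog must be in [0,1]")
        if self.n_cell_types < 2:
            raise ValueError("need >= 2 cell types for a meaningful intersection")
        if self.genes_per_chrom < 2 or self.n_chrom < 1:
            raise ValueError("need >= 2 genes per chromosome")
        if self.n_tissues < 3:
            raise ValueError("need >= 3 tissues for Pearson-based divergence")
        if not (0 < self.cpg_min <= self.cpg_max <= 4.0):
            raise ValueError("CpG_O/E targets must lie in (0, 4]")
        if self.mediation_mode not in ("d_through_ctcf", "independent"):
            raise ValueError(f"unknown mediation_mode {self.mediation_mode!r}")
        if self.gene_len_min < 2 or self.gene_len_max < self.gene_len_min:
            raise ValueError("invalid gene length range")
        if self.peak_width < 10:
            raise ValueError("peak_width too small")


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],)))


@dataclass
class Bundle:
    """An in-memory synthetic bundle (use :meth:`save` to write all files)."""

    config: GeneratorConfig
    genes: list[GeneRecord]
    peaks: dict[str, dict[str, list[tuple[int, int]]]]  # cell -> chrom -> ivs
    upstream: dict[str, str]
    expression: ExpressionMatrix
    paralogs: ParalogTable
    go_map: dict[str, set[str]]
    term_depths: dict[str, int]
    age_map: AgeMap
    ground_truth: pd.DataFrame
    ground_truth_terms: pd.DataFrame
    planted_core: dict[str, list[tuple[int, int]]]

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "peaks").mkdir(exist_ok=True)
        paths: dict[str, Path] = {}

        paths["genes"] = outdir / "genes.tsv"
        genome_io.write_gene_table(self.genes, paths["genes"])

        peak_paths = []
        for cell, ivs in self.peaks.items():
            p = outdir / "peaks" / f"{cell}.bed"
            genome_io.write_bed(ivs, p)
            peak_paths.append(p)
        paths["peaks"] = peak_paths  # type: ignore[assignment]

        paths["upstream"] = outdir / "upstream.fa"
        genome_io.write_upstream_fasta(self.upstream, paths["upstream"])

        paths["expression"] = outdir / "expression.tsv"
        self.expression.df.to_csv(paths["expression"], sep="\t",
                                  float_format="%.6g")

        paths["paralogs"] = outdir / "paralogs.tsv"
        gt = self.ground_truth
        with open(paths["paralogs"], "w") as fh:
            fh.write("gene_a\tgene_b\tds\tancestor\n")
            for row in gt[gt.relation == "paralog"].itertuples():
                fh.write(f"{row.left_id}\t{row.right_id}\t{row.ds:.6g}\t"
                         f"{row.ancestor}\n")

        paths["go"] = outdir / "go_annotation.tsv"
        with open(paths["go"], "w") as fh:
            fh.write("gene_id\tterm\n")
            for gene in sorted(self.go_map):
                for term in sorted(self.go_map[gene]):
                    fh.write(f"{gene}\t{term}\n")

        paths["go_levels"] = outdir / "go_levels.tsv"
        with open(paths["go_levels"], "w") as fh:
            fh.write("term\tdepth\n")
            for term in sorted(self.term_depths):
                fh.write(f"{term}\t{self.term_depths[term]}\n")

        paths["age_map"] = outdir / "age_map.tsv"
        with open(paths["age_map"], "w") as fh:
            fh.write("ancestor\trank\n")
            for label in self.age_map.labels:
                fh.write(f"{label}\t{self.age_map[label]}\n")

        paths["ground_truth"] = outdir / "ground_truth.tsv"
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False,
                                 float_format="%.6g")
        paths["ground_truth_terms"] = outdir / "ground_truth_terms.tsv"
        self.ground_truth_terms.to_csv(paths["ground_truth_terms"], sep="\t",
                                       index=False, float_format="%.6g")

        with open(outdir / "generator_config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# sequence tuning
# ---------------------------------------------------------------------------

def _sample_markov_batch(tau: np.ndarray, length: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample first-order chains (codes 0..3 = ACGT) with P(G | prev=C)=tau.

    The non-CpG transition mass is spread so the stationary composition stays
    near uniform (each base ~ 0.25), giving CpG_O/E ~= 4*tau in expectation.
    """
    m = len(tau)
    g_other = (1.0 - tau) / 3.0  # P(G | prev != C), keeps P(G) ~ 0.25
    seqs = np.empty((m, length), dtype=np.uint8)
    prev = rng.integers(0, 4, size=m).astype(np.uint8)
    for pos in range(length):
        p_g = np.where(prev == 1, tau, g_other)
        is_g = rng.random(m) < p_g
        # A/C/T uniformly when not G
        other = np.array([0, 1, 3], dtype=np.uint8)[rng.integers(0, 3, size=m)]
        base = np.where(is_g, np.uint8(2), other)
        seqs[:, pos] = base
        prev = base
    return seqs


def _measure_batch(seqs: np.ndarray) -> np.ndarray:
    length = seqs.shape[1]
    n_c = (seqs == 1).sum(axis=1)
    n_g = (seqs == 2).sum(axis=1)
    n_cpg = ((seqs[:, :-1] == 1) & (seqs[:, 1:] == 2)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = (n_cpg / (length - 1)) / ((n_c / length) * (n_g / length))
    oe[(n_c == 0) | (n_g == 0)] = np.nan
    return oe


def tune_sequences_batch(targets: np.ndarray, length: int,
                         rng: np.random.Generator, tol: float = 0.1,
                         max_attempts: int = 40) -> list[str]:
    """Sequences whose measured CpG_O/E is within ``tol`` of each target."""
    targets = np.asarray(targets, dtype=float)
    if np.any((targets <= 0) | (targets > 4.0)):
        raise ValueError("CpG_O/E targets must lie in (0, 4]")
    if length < 100:
        raise ValueError("sequence length must be >= 100")
    m = len(targets)
    tau = np.clip(targets / 4.0, 1e-4, 1.0)
    out = np.empty((m, length), dtype=np.uint8)
    active = np.arange(m)
    for _ in range(max_attempts):
        seqs = _sample_markov_batch(tau[active], length, rng)
        measured = _measure_batch(seqs)
        ok = np.isfinite(measured) & (np.abs(measured - targets[active]) <= tol)
        out[active[ok]] = seqs[ok]
        # adapt the CpG transition of the failures toward the target
        bad = ~ok
        scale = np.ones(int(bad.sum()))
        usable = np.isfinite(measured[bad]) & (measured[bad] > 0)
        scale[usable] = targets[active[bad]][usable] / measured[bad][usable]
        tau[active[bad]] = np.clip(tau[active[bad]] * scale, 1e-4, 1.0)
        active = active[bad]
        if active.size == 0:
            break
    else:
        raise RuntimeError(
            f"CpG_O/E target unreachable for {active.size} sequence(s) "
            f"after {max_attempts} attempts")
    ascii_rows = _BASES[out]
    return [row.tobytes().decode("ascii") for row in ascii_rows]


def tune_sequence_cpg(target_cpg_oe: float, length: int,
                      rng: np.random.Generator | int | None = None,
                      tol: float = 0.1) -> str:
    """One nucleotide string with measured CpG_O/E within ``tol`` of target."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return tune_sequences_batch(np.array([target_cpg_oe]), length, rng, tol)[0]


# ---------------------------------------------------------------------------
# ontology planting
# ---------------------------------------------------------------------------

def _plant_ontology(ground_truth: pd.DataFrame, gene_ids: list[str],
                    rng: np.random.Generator, config: GeneratorConfig,
                    ) -> tuple[dict[str, set[str]], dict[str, int], pd.DataFrame]:
    """Assign GO terms: background rate everywhere, the designated term at an
    elevated rate on member genes of top-quartile-#CTCF/d paralog pairs."""
    planted_term = "GO:0000001"
    background_terms = [f"GO:{k + 2:07d}"
                        for k in range(config.n_background_terms)]
    decoy_terms = {f"GO:{config.n_background_terms + 2:07d}": 3,
                   f"GO:{config.n_background_terms + 3:07d}": 5}
    term_depths = {planted_term: 4, **{t: 4 for t in background_terms},
                   **decoy_terms}

    par = ground_truth[ground_truth.relation == "paralog"]
    dens = (par.n_core / par.d.replace(0, np.nan)).to_numpy()
    order = np.lexsort((par.pair_id.to_numpy(), -dens))
    k_top = int(np.ceil(len(par) / 4)) if len(par) >= 4 else 0
    top_pairs = par.iloc[order[:k_top]]
    high_genes = set(top_pairs.left_id) | set(top_pairs.right_id)

    go_map: dict[str, set[str]] = {}
    p0 = config.p_background
    p1 = min(1.0, config.planted_factor * p0)
    all_terms = background_terms + list(decoy_terms)
    draws = rng.random((len(gene_ids), len(all_terms)))
    planted_draws = rng.random(len(gene_ids))
    for i, gid in enumerate(gene_ids):
        terms = {all_terms[k] for k in np.nonzero(draws[i] < p0)[0]}
        if planted_draws[i] < (p1 if gid in high_genes else p0):
            terms.add(planted_term)
        if terms:
            go_map[gid] = terms

    gt_terms = pd.DataFrame(
        [{"term": planted_term, "planted_factor": config.planted_factor,
          "depth": 4}]
        + [{"term": t, "planted_factor": 1.0, "depth": term_depths[t]}
           for t in all_terms])
    return go_map, term_depths, gt_terms


def redraw_ontology(bundle: Bundle, seed: int,
                    planted_factor: float | None = None,
                    ) -> tuple[dict[str, set[str]], str]:
    """Re-run only the GO-planting step of a bundle with a fresh seed.

    Supports replicated enrichment calibration/power studies without
    regenerating the genome: ``planted_factor=1.0`` gives a fully random
    (null) assignment, the default keeps the bundle's planted
    overrepresentation.  Returns the new mapping and the designated term id.
    """
    cfg = bundle.config if planted_factor is None else dataclasses.replace(
        bundle.config, planted_factor=planted_factor)
    rng = _stream(seed, "ontology")
    go_map, _, _ = _plant_ontology(bundle.ground_truth,
                                   [g.gene_id for g in bundle.genes], rng, cfg)
    return go_map, "GO:0000001"


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig) -> Bundle:
    """Generate one internally consistent bundle from the config."""
    config.validate()
    age_map = AgeMap.default()
    ladder = age_map.labels
    n_bins = len(ladder)

    rng_lat = _stream(config.seed, "latent")
    rng_coo = _stream(config.seed, "coords")
    rng_pk = _stream(config.seed, "peaks")
    rng_seq = _stream(config.seed, "sequence")
    rng_exp = _stream(config.seed, "expression")
    rng_go = _stream(config.seed, "ontology")

    n_chrom, g_per = config.n_chrom, config.genes_per_chrom
    n_genes = n_chrom * g_per
    n_pairs = n_chrom * (g_per - 1)

    # --- pair latents -----------------------------------------------------
    is_paralog = rng_lat.random(n_pairs) < config.frac_paralog
    t_latent = rng_lat.random(n_pairs)
    ds = config.ds_scale * t_latent * np.exp(rng_lat.normal(0.0, 0.15, n_pairs))
    tphy_bin = np.minimum((t_latent * n_bins).astype(int), n_bins - 1)
    lam = config.lam0 + config.b_ctcf_per_ds * config.ds_scale * t_latent
    n_core = rng_lat.poisson(lam)

    # --- coordinates ------------------------------------------------------
    lengths = rng_coo.integers(config.gene_len_min, config.gene_len_max + 1,
                               size=n_genes)
    strands = np.where(rng_coo.random(n_genes) < 0.5, "+", "-")
    slot = (config.peak_width + 50) * n_core
    if config.mediation_mode == "d_through_ctcf":
        gaps = 500 + slot + rng_coo.integers(0, 801, size=n_pairs)
    else:
        gaps = np.maximum(500 + slot,
                          rng_coo.integers(1000, 25001, size=n_pairs))

    genes: list[GeneRecord] = []
    pair_rows: list[dict] = []
    core: dict[str, list[tuple[int, int]]] = {}
    per_cell: dict[str, dict[str, list[tuple[int, int]]]] = {
        f"cell{k:02d}": {} for k in range(config.n_cell_types)
    }
    cell_names = list(per_cell)

    gidx = 0
    pidx = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        core[chrom] = []
        for cell in cell_names:
            per_cell[cell][chrom] = []
        start = 1001
        chrom_genes: list[GeneRecord] = []
        for i in range(g_per):
            end = start + int(lengths[gidx]) - 1
            gene = make_gene(f"g{c:02d}_{i:04d}", chrom, str(strands[gidx]),
                             start, end)
            chrom_genes.append(gene)
            genes.append(gene)
            if i < g_per - 1:
                start = end + int(gaps[pidx + i]) + 1
            gidx += 1
        # core + private peaks in each inter-gene gap
        for i in range(g_per - 1):
            j = pidx + i
            left, right = chrom_genes[i], chrom_genes[i + 1]
            gap_lo, gap_hi = left.end, right.start - 1  # 0-based half-open
            cursor = gap_lo + 4
            for _ in range(int(n_core[j])):
                s, e = cursor, cursor + config.peak_width
                core[chrom].append((s, e))
                cursor = s + config.peak_width + 10
            cursor += 2
            n_priv = rng_pk.poisson(config.private_rate)
            priv_cells = rng_pk.integers(0, config.n_cell_types, size=n_priv)
            for cell_idx in priv_cells:
                if cursor + 100 > gap_hi - 2:
                    break
                per_cell[cell_names[cell_idx]][chrom].append((cursor, cursor + 100))
                cursor += 102
            pair_rows.append({
                "pair_id": f"{left.gene_id}|{right.gene_id}",
                "left_id": left.gene_id, "right_id": right.gene_id,
                "chrom": chrom,
                "relation": "paralog" if is_paralog[j] else "non_paralog",
                "t_latent": t_latent[j],
                "ds": ds[j] if is_paralog[j] else np.nan,
                "ancestor": ladder[tphy_bin[j]] if is_paralog[j] else "",
                "t_phy": tphy_bin[j] if is_paralog[j] else np.nan,
                "n_core": int(n_core[j]),
                "gap": int(gaps[j]),
                "d": abs(left.tss - right.tss),
            })
        pidx += g_per - 1
    for cell in cell_names:
        for chrom in per_cell[cell]:
            per_cell[cell][chrom] = sorted(per_cell[cell][chrom] + core[chrom])

    gt = pd.DataFrame(pair_rows)

    # --- upstream sequences ----------------------------------------------
    cpg_targets = rng_seq.uniform(config.cpg_min, config.cpg_max, size=n_genes)
    seqs = tune_sequences_batch(cpg_targets, config.flank, rng_seq)
    upstream = {g.gene_id: s for g, s in zip(genes, seqs)}

    target_by_gene = {g.gene_id: cpg_targets[i] for i, g in enumerate(genes)}
    delta_target = np.array([
        abs(target_by_gene[row["left_id"]] - target_by_gene[row["right_id"]])
        for row in pair_rows
    ])
    gt["delta_cpg_target"] = delta_target

    # --- expression chain -------------------------------------------------
    tissues = [f"tissue{k + 1}" for k in range(config.n_tissues)]
    signal = np.empty((n_genes, config.n_tissues))
    mu_level, ar = 2.0, 0.8
    m_used = np.full(n_pairs, np.nan)
    offset_used = np.full(n_pairs, np.nan)
    gidx = 0
    pidx = 0
    for c in range(n_chrom):
        shape = rng_exp.gamma(1.0, size=config.n_tissues)
        shape /= shape.sum()
        loglevel = rng_exp.normal(mu_level, 1.0)
        signal[gidx] = shape * np.exp(loglevel) * config.n_tissues
        for i in range(g_per - 1):
            j = pidx + i
            m = float(np.clip(config.w_profile * n_core[j]
                              + rng_exp.normal(0.0, 0.03), 0.02, 0.95))
            fresh = rng_exp.gamma(1.0, size=config.n_tissues)
            fresh /= fresh.sum()
            shape = (1.0 - m) * shape + m * fresh
            shape /= shape.sum()
            sign = 1.0 if rng_exp.random() < 0.5 else -1.0
            offset = (config.w_level * delta_target[j] * sign
                      + rng_exp.normal(0.0, 0.05))
            loglevel = mu_level + ar * (loglevel - mu_level) + offset
            signal[gidx + i + 1] = shape * np.exp(loglevel) * config.n_tissues
            m_used[j] = m
            offset_used[j] = offset
        gidx += g_per
        pidx += g_per - 1
    gt["m_profile"] = m_used
    gt["level_offset"] = offset_used
    expression = ExpressionMatrix(pd.DataFrame(
        signal, index=[g.gene_id for g in genes], columns=tissues))

    # --- GO planting ------------------------------------------------------
    go_map, term_depths, gt_terms = _plant_ontology(
        gt, [g.gene_id for g in genes], rng_go, config)

    paralogs = ParalogTable([
        (row["left_id"], row["right_id"], float(row["ds"]), row["ancestor"])
        for row in pair_rows if row["relation"] == "paralog"
    ])

    return Bundle(
        config=config, genes=genes, peaks=per_cell, upstream=upstream,
        expression=expression, paralogs=paralogs, go_map=go_map,
        term_depths=term_depths, age_map=age_map, ground_truth=gt,
        ground_truth_terms=gt_terms, planted_core=core,
    )
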