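"""Partial Spearman correlation separates direct from mediated effects.

In the synthetic bundle, intervening CTCF sites drive expression divergence
between adjacent paralogs, while intergenic distance merely tracks the site
count (sites take up room between the TSSs).  The marginal rank correlation
of distance with divergence is therefore positive, but controlling for
#CTCF and ΔCpG_O/E removes it — the signature of a mediated effect.
"""

from ctcf_divergence import (GeneratorConfig, bundle_features, generate,
                             partial_spearman, spearman)

bundle = generate(GeneratorConfig(seed=42, n_chrom=5, genes_per_chrom=300))
features = bundle_features(bundle)
par = features[features.relation == "paralog"]
sub = par[["d", "n_ctcf_overlap", "delta_cpg", "expd_1r"]].dropna()
print(f"{len(sub)} adjacent paralog pairs")

rho_d, p_d = spearman(sub.d, sub.expd_1r)
rho_dp, p_dp = partial_spearman(sub.d, sub.expd_1r,
                                [sub.n_ctcf_overlap, sub.delta_cpg])
rho_c, p_c = partial_spearman(sub.n_ctcf_overlap, sub.expd_1r,
                              [sub.d, sub.delta_cpg])

print(f"rho(d, ExpD_1-r)                       = {rho_d:+.3f} (p={p_d:.1e})")
print(f"rho_p(d, ExpD_1-r | #CTCF, dCpG)       = {rho_dp:+.3f} (p={p_dp:.2f})")
print(f"rho_p(#CTCF, ExpD_1-r | d, dCpG)       = {rho_c:+.3f} (p={p_c:.1e})")
# The marginal distance effect is explained away by #CTCF (its partial
# correlation is null), while the #CTCF partial stays strongly positive:
# distance does not directly shape profile divergence here, the insulator
# sites between the two promoters do.
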