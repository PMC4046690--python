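"""The three per-pair scores: CpG_O/E (methylation proxy) and the two
expression divergences.

CpG_O/E = P_CpG / (P_C x P_G) on the 500 nt upstream of the TSS; germline
methylation depletes CpGs, so low values mean a methylated-like promoter.
ExpD_1-r = 1 - Pearson r across tissues (profile shape); ExpD_Euc is the
Euclidean distance (expression level).
"""

import numpy as np

from ctcf_divergence import cpg_oe, expd_1r, expd_euc

for seq in ("CGCGCG", "CG", "ACGTACGTAA"):
    prof = cpg_oe(seq)
    print(f"{seq:>10}: P_CpG={prof.p_cpg:.3f} P_C={prof.p_c:.3f} "
          f"P_G={prof.p_g:.3f} CpG_O/E={prof.cpg_oe:.3f}")

x = np.array([1.0, 2, 3, 4, 5, 6])       # six-tissue signal of gene A
print("\nsame profile, doubled level (gene B = 2 x gene A):")
print(f"  ExpD_1-r = {expd_1r(x, 2 * x):.3f}   (profiles identical)")
print(f"  ExpD_Euc = {expd_euc(x, 2 * x):.3f}  (levels diverged, sqrt(91))")

y = x[::-1].copy()                        # reversed preference across tissues
print("reversed profile, same total level:")
print(f"  ExpD_1-r = {expd_1r(x, y):.3f}   (maximal profile divergence)")
print(f"  ExpD_Euc = {expd_euc(x, y):.3f}")
# The two measures deliberately dissociate: one sees shape, one sees
# abundance — which is why both are carried through every analysis.
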