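"""Build the two CTCF consensus dialects from per-cell-type peak sets.

'Overlapping' sites are binding regions present in every examined cell type
(base-wise intersection); 'joint' sites are the merged union.  Counting is by
>= 1 bp overlap with a window, here an inter-TSS window.
"""

from ctcf_divergence import count_in_window, intersect_all, union_all

cell_a = {"chr1": [(100, 250), (400, 520), (900, 1000)]}
cell_b = {"chr1": [(150, 300), (400, 520)]}
cell_c = {"chr1": [(120, 260), (450, 700)]}
sets = [cell_a, cell_b, cell_c]

overlapping = intersect_all(sets)
joint = union_all(sets)
print("overlapping consensus:", overlapping["chr1"])
print("joint consensus:      ", joint["chr1"])

window = (0, 600)  # e.g. the span between two neighbouring TSSs
n_over = count_in_window(overlapping, "chr1", *window)
n_joint = count_in_window(joint, "chr1", *window)
print(f"#CTCF in window {window}: overlapping={n_over}, joint={n_joint}")
# Only regions bound in all three cell types survive the intersection, so
# the overlapping count is conservative; the joint count credits any cell
# type's binding.
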