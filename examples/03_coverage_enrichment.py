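"""Meta-coverage enrichment between two exon sets (volcano-style test).

Plants a 1.5-fold binding enrichment in the 500-nt upstream introns of one
exon set, builds strand-aware coverage matrices (50 upstream + 10 body + 50
downstream bins), and tests each region by median fold-change and the exact
Wilcoxon signed-rank test against the conventional cutoff
(log2 FC > 0.4 and -log10 p > 6).
"""

import numpy as np

from exon5uc.coverage import build_coverage_matrix, volcano_table
from exon5uc.simulate import simulate_enrichment_pair

rng = np.random.default_rng(1)
track, bound_exons, background_exons = simulate_enrichment_pair(
    n_exons=300, fold=1.5, rng=rng
)
matrix_bound = build_coverage_matrix(track, bound_exons)
matrix_bg = build_coverage_matrix(track, background_exons)

table = volcano_table(matrix_bound, matrix_bg, factor="synthetic_RBP")
print(table.round(4).to_string(index=False))
print(
    "\nOnly the UPSTREAM region clears the cutoff: the planted enrichment "
    "sits in the upstream intron, exactly where a splicing repressor that "
    "binds ahead of the exon would accumulate."
)
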