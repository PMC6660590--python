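"""Annotating DMRs against chromatin states and gene models.

Uses the engineered annotation fixtures: an 18-state segmentation covering
the synthetic chromosome and a small gene table with promoter/body
conflicts, a minus-strand gene and a lexicographic tie.  Enhancer overlap
sums segments in states 3/8/9/10 and flags DMRs reaching 50 bp total;
gene assignment prefers the promoter window, then the gene body, with
protein-coding priority.
"""

from updmr import annotate_dmrs, generate_annotation_fixtures
from updmr.filters import Dmr
import numpy as np

segments, genes = generate_annotation_fixtures(seed=0)


def dmr(start_pos, end_pos, pmd):
    pos = np.linspace(start_pos, end_pos, 6).astype(np.int64)
    return Dmr(chrom="chrS", pos=pos, p=np.full(6, 0.01), pmd=np.full(6, pmd), up_p=1e-5)


dmrs = [
    dmr(24_001, 24_500, 35.0),    # in ALPHA's promoter window
    dmr(32_001, 33_000, -28.0),   # in ALPHA's gene body (over the ncRNA)
    dmr(68_001, 69_000, 41.0),    # minus-strand BETA promoter (TSS at tx end)
    dmr(118_001, 122_000, 22.0),  # EPSILON promoter beats DELTA body
]
table = annotate_dmrs(dmrs, segments=segments, gene_models=genes)
print(table[["chrom", "start", "end", "direction", "gene_name", "gene_category",
             "gene_overlap_bp", "enh_overlap_bp", "is_enhancer_dmr"]].to_string(index=False))
print("\nis_enhancer_dmr is true when total overlap with enhancer states"
      " (3, 8, 9, 10) reaches 50 bp")
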