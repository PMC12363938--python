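"""Select NMD-sensitive genes from differential-expression tables.

Genes are selected when upregulated strictly more than 2-fold in the
NMD-deficient condition with padj < 1% (ORF counts) or < 5% (intron
counts); intron selection additionally flags the gene as a retained-
intron candidate.  Boundary rows (log2fc exactly 1, padj exactly at a
cutoff) are rejected: all inequalities are strict.
"""

import pandas as pd

import ribopeak as rp

de_orf = pd.DataFrame(
    [
        {"gene_id": "GENE_A", "feature": "orf", "log2fc": 1.5, "padj": 1e-3, "mean_expression": 200},
        {"gene_id": "GENE_B", "feature": "orf", "log2fc": 1.0, "padj": 1e-6, "mean_expression": 150},
        {"gene_id": "GENE_C", "feature": "orf", "log2fc": 2.2, "padj": 0.01, "mean_expression": 90},
        {"gene_id": "GENE_D", "feature": "orf", "log2fc": 0.1, "padj": 0.8, "mean_expression": 500},
    ]
)
de_intron = pd.DataFrame(
    [
        {"gene_id": "GENE_D", "feature": "intron", "log2fc": 2.0, "padj": 0.03, "mean_expression": 40},
    ]
)

selected = rp.select_nmd_genes(de_orf, de_intron)
print(selected.to_string(index=False))
# GENE_A passes (2^1.5 = 2.8-fold, padj 0.1%); GENE_B fails on the
# fold-change boundary; GENE_C fails on the padj boundary; GENE_D is
# selected through its intron (padj 3% < 5%) and flagged retained_intron.
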