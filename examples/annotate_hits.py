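"""Map a significant CNVR to its proximal genes.

A gene is proximal when it intersects the region extended 50 kb up- and
downstream (a 100 kb flanking window). Demonstrated on a hand-made gene
set around a loss region on chromosome 4.
"""

from cnvrgwas import Cnvr, CnvrType, GeneModel, proximal_genes

region = Cnvr("DEL00035578", "4", 80_144_379, 80_145_908, CnvrType.LOSS)
genes = [
    GeneModel("geneA", "4", 80_100_000, 80_130_000),  # flank only
    GeneModel("geneB", "4", 80_140_000, 80_160_000),  # overlaps the CNVR
    GeneModel("geneC", "4", 80_144_500, 80_145_000),  # inside the CNVR
    GeneModel("geneD", "4", 80_000_000, 80_094_378),  # 1 bp outside the window
    GeneModel("geneE", "7", 80_144_379, 80_145_908),  # wrong chromosome
]

ann = proximal_genes(region, genes, flank=50_000)
print(f"CNVR {ann.cnvr_id}: window {ann.window_start:,}-{ann.window_end:,}")
for gene, klass in ann.genes:
    print(f"  {gene.gene_id}  {gene.start:,}-{gene.end:,}  [{klass}]")
# geneD ends one base before the window opens and geneE is on another
# chromosome, so exactly three genes are reported, classified by whether
# they sit inside the CNVR, straddle it, or touch only the flank.
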