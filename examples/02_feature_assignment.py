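"""Assign CLIP binding clusters to genomic features by the binding hierarchy.

Each cluster is labelled with the highest-priority feature it overlaps on
its own strand: CDS > 3'UTR > 5'UTR > intron > ncRNA, else intergenic.
"""

from splicereg.annotation import derive_features
from splicereg.clip import ClipCluster, assign_feature, gene_3utr_bound
from splicereg.synthetic import generate_annotation

ann = generate_annotation(n_genes=30, seed=2)
idx = derive_features(ann)

gene = next(g for g in ann.genes if g.transcripts[0].is_coding)
tx = gene.transcripts[0]
cds_lo = min(s for s, _ in tx.cds)

cluster = ClipCluster(tx.chrom, cds_lo + 5, cds_lo + 25, tx.strand, name="demo")
assignment = assign_feature(cluster, idx)
print(f"cluster {cluster.chrom}:{cluster.start}-{cluster.end}({cluster.strand}) "
      f"-> gene {assignment.gene_id}, feature {assignment.feature_kind}")

bound, support = gene_3utr_bound(gene.id, [cluster], idx)
print(f"gene {gene.id} 3'UTR-bound by this cluster: {bound}")
# A CDS-contained cluster never flags the gene as 3'UTR-bound: the flag
# requires overlap with the 3'UTR of at least one transcript of the gene.
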