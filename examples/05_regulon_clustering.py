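"""Extract genotype-specific regulons by z-score hierarchical clustering.

Rows (genes or events) are z-scored across the 15 libraries, clustered by
complete linkage on Euclidean distance, cut into 4 clusters, and each
cluster is labelled by its genotype pattern of mean z-scores.
"""

from sklearn.metrics import adjusted_rand_score

from splicereg.regulon import call_cluster_patterns, cluster_rows, zscore_rows
from splicereg.synthetic import StudyDesign, generate_pattern_matrix

matrix, planted_labels, expected = generate_pattern_matrix(
    n_per_group=10, noise_sd=0.3, seed=4
)
result = cluster_rows(zscore_rows(matrix), n_clusters=4)
patterns = call_cluster_patterns(result, StudyDesign().genotype_of, margin=0.5)

print(patterns[["cluster_id", "n_rows", "pattern"]].to_string(index=False))
ari = adjusted_rand_score(planted_labels, result.row_labels)
print(f"adjusted Rand index vs planted groups: {ari:.3f}")
# An ARI of 1.0 means the four planted genotype patterns were recovered
# exactly; the pattern column shows which genotype drives each cluster.
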