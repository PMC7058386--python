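"""Z-score clustering of expression / inclusion matrices into regulons.

Rows (genes or splicing events, one column per library) are z-scored, then
clustered by complete-linkage agglomerative clustering on Euclidean
distances and cut to a fixed number of clusters.  Each cluster is labelled
by its genotype pattern — e.g. "dKO-up" when the double-knockout libraries
sit above both other genotypes by a margin — to extract genotype-specific
gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores using the sample (n-1) standard deviation.

    Constant rows map to all-zero.  Non-finite input raises, naming a row.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite values in row {matrix.index[bad.argmax()]!r}")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class RegulonResult:
    z_matrix: pd.DataFrame
    linkage: np.ndarray
    row_labels: pd.Series  # cluster id per row, 1..n_clusters
    cluster_patterns: pd.DataFrame | None = None

    def members(self, cluster_id: int) -> list:
        return list(self.row_labels.index[self.row_labels == cluster_id])


def cluster_rows(z_matrix: pd.DataFrame, n_clusters: int = 4) -> RegulonResult:
    """Complete-linkage hierarchical clustering of rows on Euclidean distance.

    The dendrogram is cut to exactly ``n_clusters``.  The procedure has no
    randomness: a fixed input yields a fixed partition.
    """
    n = len(z_matrix)
    if not (2 <= n_clusters <= n):
        raise ValueError(f"n_clusters={n_clusters} out of range [2, {n}]")
    lk = linkage(z_matrix.to_numpy(dtype=float), method="complete", metric="euclidean")
    labels = fcluster(lk, t=n_clusters, criterion="maxclust")
    return RegulonResult(
        z_matrix=z_matrix,
        linkage=lk,
        row_labels=pd.Series(labels, index=z_matrix.index, name="cluster_id"),
    )


def call_cluster_patterns(
    result: RegulonResult,
    genotype_of: dict[str, str],
    margin: float = 0.5,
    target: str = "dKO",
    other: str = "sKO",
) -> pd.DataFrame:
    """Label each cluster by its genotype pattern of mean z-scores.

    A cluster is "<target>-up" when the target genotype's mean z exceeds
    both other genotypes' means by ``margin`` z-units ("-down" symmetric);
    "<other>-specific" when the second knockout genotype is the outlier in
    either direction by the same margin; otherwise "mixed".  Any genotype
    can be the outlier; non-target outliers are labelled "<genotype>-specific".
    """
    unmapped = [c for c in result.z_matrix.columns if c not in genotype_of]
    if unmapped:
        raise ValueError(f"libraries without genotype label: {unmapped}")
    geno = pd.Series({c: genotype_of[c] for c in result.z_matrix.columns})
    rows = []
    for cid in sorted(result.row_labels.unique()):
        sub = result.z_matrix.loc[result.row_labels == cid]
        means = sub.mean(axis=0).groupby(geno).mean()
        call = _pattern_call(means, margin, target, other)
        rows.append({"cluster_id": cid, "n_rows": len(sub), "pattern": call,
                     **{f"mean_z_{g}": means[g] for g in means.index}})
    patterns = pd.DataFrame(rows)
    result.cluster_patterns = patterns
    return patterns


def _pattern_call(means: pd.Series, margin: float, target: str, other: str) -> str:
    # the knockout genotypes take precedence over control when several
    # genotypes clear the margin (a dKO-up cluster also has a low ctrl mean)
    ordered = [g for g in (target, other) if g in means.index]
    ordered += [g for g in means.index if g not in ordered]
    for g in ordered:
        others = means.drop(g)
        if (means[g] >= others + margin).all():
            return f"{g}-up" if g == target else f"{g}-specific"
        if (means[g] <= others - margin).all():
            return f"{g}-down" if g == target else f"{g}-specific"
    return "mixed"


def membership_frame(result: RegulonResult) -> pd.DataFrame:
    """Cluster membership table: row_id, cluster_id and (if called) pattern."""
    out = result.row_labels.rename_axis("row_id").reset_index()
    if result.cluster_patterns is not None:
        out = out.merge(
            result.cluster_patterns[["cluster_id", "pattern"]], on="cluster_id", how="left"
        )
    return out
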