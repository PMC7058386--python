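"""Expression summaries and the differential-abundance gene filter.

TPM and FPKM are computed from a gene x library count matrix; FPKM library
normalisation uses median-of-ratios size factors (the geometric method
family).  The differential filter keeps genes with padj < 0.05,
|log2FC| > 0.5 and a mean expression of at least 1 FPKM (mean of the five
replicates) in at least one genotype, split into increased and decreased
sets by the sign of the fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: rate_g = count_g / length_g, scaled so each
    library column sums to 1e6.

    Raises ValueError naming any library with zero total count.
    """
    counts, lengths = _check_counts(counts, lengths)
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total count in library {zero.index[0]!r}")
    return rate.div(totals, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style geometric normalisation).

    For each gene with all-positive counts, the ratio of each library's
    count to the gene's geometric mean is formed; the size factor is the
    median ratio per library.
    """
    logc = np.log(counts.where(counts > 0))
    loggeo = logc.mean(axis=1)
    finite = np.isfinite(loggeo)
    if not finite.any():
        raise ValueError("no gene has positive counts in every library")
    logratios = logc.loc[finite].sub(loggeo[finite], axis=0)
    return np.exp(logratios.median(axis=0))


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million, on size-factor-normalised counts.

    FPKM_g = (count_g / sf) / (total normalised reads / 1e6) / (length_g / 1e3).
    Size factors are computed internally (median-of-ratios) when absent.
    """
    counts, lengths = _check_counts(counts, lengths)
    if factors is None:
        factors = size_factors(counts)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    norm = counts.div(factors, axis=1)
    totals = norm.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total count in library {zero.index[0]!r}")
    return norm.div(totals / 1e6, axis=1).div(lengths / 1e3, axis=0)


def _check_counts(counts: pd.DataFrame, lengths: pd.Series):
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    return counts.astype(float), lengths.astype(float)


def genotype_means(values: pd.DataFrame, genotype_of: dict[str, str]) -> pd.DataFrame:
    """Collapse a gene x library matrix to per-genotype replicate means."""
    missing = [lib for lib in values.columns if lib not in genotype_of]
    if missing:
        raise ValueError(f"libraries without genotype label: {missing}")
    return values.T.groupby(pd.Series(genotype_of)).mean().T


@dataclass
class DiffExprThresholds:
    padj: float = 0.05        # strict <
    log2fc: float = 0.5       # strict > on |log2FC|
    fpkm_floor: float = 1.0   # >= in at least one genotype


@dataclass
class DiffExprResult:
    up: pd.DataFrame
    down: pd.DataFrame
    n_missing_padj: int = 0
    excluded_unexpressed: set = field(default_factory=set)

    @property
    def gene_ids(self) -> set:
        return set(self.up["gene_id"]) | set(self.down["gene_id"])


def filter_differential_genes(
    de_table: pd.DataFrame,
    mean_fpkm: pd.DataFrame,
    thresholds: DiffExprThresholds | None = None,
) -> DiffExprResult:
    """Apply the three-condition differential-abundance filter.

    A gene survives iff padj < `padj`, |log2FoldChange| > `log2fc`, and its
    mean FPKM reaches `fpkm_floor` in at least one genotype.  Genes with
    missing padj are excluded (count logged).  Survivors are partitioned
    into increased (log2FC > 0) and decreased sets.

    Parameters
    ----------
    de_table
        DESeq2-style results with gene_id, log2FoldChange, padj columns.
    mean_fpkm
        Per-genotype mean FPKM, indexed by gene_id.
    """
    thresholds = thresholds or DiffExprThresholds()
    t = de_table.copy()
    n_missing = int(t["padj"].isna().sum())
    if n_missing:
        log.info("excluding %d genes with missing padj", n_missing)
    t = t.dropna(subset=["padj", "log2FoldChange"])

    max_fpkm = mean_fpkm.max(axis=1)
    expressed = max_fpkm[max_fpkm >= thresholds.fpkm_floor].index
    in_table = t["gene_id"].isin(set(expressed))
    excluded_unexpr = set(t.loc[~in_table, "gene_id"])

    sig = t[
        in_table
        & (t["padj"] < thresholds.padj)
        & (t["log2FoldChange"].abs() > thresholds.log2fc)
    ]
    return DiffExprResult(
        up=sig[sig["log2FoldChange"] > 0].reset_index(drop=True),
        down=sig[sig["log2FoldChange"] < 0].reset_index(drop=True),
        n_missing_padj=n_missing,
        excluded_unexpressed=excluded_unexpr,
    )


def spearman_log_tpm(
    tpm_a: pd.Series,
    tpm_b: pd.Series,
    pseudocount: float = 0.01,
) -> float:
    """Spearman rank correlation of log10(mean TPM + pseudocount).

    Computed on the intersection of gene ids; fewer than 3 shared genes is
    an error.  (The log transform is monotone, so the pseudocount and base
    do not change the rank correlation; they are exposed for plotting
    parity with log-scale comparisons.)
    """
    shared = tpm_a.index.intersection(tpm_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    a = np.log10(tpm_a.loc[shared].astype(float) + pseudocount)
    b = np.log10(tpm_b.loc[shared].astype(float) + pseudocount)
    rho, _p = stats.spearmanr(a, b)
    return float(rho)


def read_deseq_table(path) -> pd.DataFrame:
    """Read a DESeq2-format results TSV (gene_id, baseMean, log2FoldChange,
    lfcSE, pvalue, padj); extra columns pass through."""
    t = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "log2FoldChange", "padj"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"DE table {path} missing columns: {sorted(missing)}")
    return t
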