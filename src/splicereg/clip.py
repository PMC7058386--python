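"""iCLIP binding clusters and crosslink sites: loading and feature assignment.

Clusters and single-nucleotide crosslink (xlink) sites are assigned to the
genomic feature they overlap, resolved by the hierarchy
CDS > 3'UTR > 5'UTR > intron > ncRNA; targets overlapping nothing on their
strand are intergenic.  A gene is "3'UTR-bound" when at least one cluster
overlaps the 3'UTR of any of its transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import FEATURE_PRIORITY, FeatureIndex, FeatureInterval


class BedFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ClipCluster:
    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."
    score: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise BedFormatError(f"cluster {self.name}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise BedFormatError(f"cluster {self.name}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class XlinkSite:
    chrom: str
    position: int
    strand: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"xlink site at {self.chrom}:{self.position}: count < 1")

    @property
    def start(self) -> int:
        return self.position

    @property
    def end(self) -> int:
        return self.position + 1


@dataclass(frozen=True)
class FeatureAssignment:
    target_id: str
    gene_id: str | None
    feature_kind: str  # CDS | UTR3 | UTR5 | intron | ncRNA | intergenic


def load_clusters(path) -> list[ClipCluster]:
    """Read BED6 clusters; duplicates collapsed, sorted by (chrom, start).

    BED is 0-based half-open; strand is column 6.  Fewer than 6 columns or
    start >= end raise :class:`BedFormatError`.
    """
    clusters: set[ClipCluster] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise BedFormatError(f"line {lineno}: BED6 requires >=6 columns, got {len(parts)}")
            chrom, start_s, end_s, name, score_s, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise BedFormatError(f"line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise BedFormatError(f"line {lineno}: start {start} >= end {end}")
            score = None if score_s in (".", "") else float(score_s)
            clusters.add(ClipCluster(chrom, start, end, strand, name=name, score=score))
    return sorted(clusters, key=lambda c: (c.chrom, c.start, c.end, c.strand))


def write_clusters(clusters: list[ClipCluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            score = "." if c.score is None else f"{c.score:g}"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.name}\t{score}\t{c.strand}\n")


def load_xlink_sites(path) -> list[XlinkSite]:
    """Read xlink sites from BED6 (single-nt intervals; score = read count)."""
    sites = []
    for c in load_clusters(path):
        if c.end - c.start != 1:
            raise BedFormatError(f"xlink site {c.name} spans {c.end - c.start} nt, expected 1")
        sites.append(XlinkSite(c.chrom, c.start, c.strand, count=int(c.score or 1)))
    return sites


def _target_id(target) -> str:
    if isinstance(target, ClipCluster) and target.name != ".":
        return target.name
    return f"{target.chrom}:{target.start}-{target.end}:{target.strand}"


def assign_feature(target, idx: FeatureIndex) -> FeatureAssignment:
    """Assign a cluster or xlink site to its highest-priority feature.

    Overlap is strand-matched with a 1-nt minimum.  Among all overlapped
    transcript features the kind ranking highest in
    CDS > UTR3 > UTR5 > intron > ncRNA wins; the gene of the winning
    feature is reported.  Ties across genes at equal priority are broken
    by larger overlap length, then lexicographic gene_id, so assignment is
    deterministic and independent of transcript input order.
    """
    hits = idx.overlapping(target.chrom, target.start, target.end, target.strand)
    if not hits:
        return FeatureAssignment(_target_id(target), None, "intergenic")

    def sort_key(fi: FeatureInterval):
        ov = min(fi.end, target.end) - max(fi.start, target.start)
        return (FEATURE_PRIORITY[fi.kind], -ov, fi.gene_id)

    best = min(hits, key=sort_key)
    return FeatureAssignment(_target_id(target), best.gene_id, best.kind)


def gene_3utr_bound(
    gene_id: str, clusters: list[ClipCluster], idx: FeatureIndex
) -> tuple[bool, list[str]]:
    """Whether any cluster overlaps any annotated 3'UTR of the gene.

    The union over all the gene's transcripts is used, so a cluster in the
    3'UTR of a minor isoform counts.  Partial (>=1 nt, same-strand)
    overlap suffices.  Returns the flag and the supporting cluster ids.

    Raises KeyError for a gene absent from the annotation.
    """
    utr3s = idx.gene_features(gene_id, kind="UTR3")
    supporting = []
    for c in clusters:
        for fi in utr3s:
            if (
                c.chrom == fi.chrom
                and c.strand == fi.strand
                and c.start < fi.end
                and fi.start < c.end
            ):
                supporting.append(_target_id(c))
                break
    return bool(supporting), supporting


def assignments_frame(targets, idx: FeatureIndex) -> pd.DataFrame:
    """Assign every target and tabulate: one row per cluster/site."""
    rows = []
    for t in targets:
        a = assign_feature(t, idx)
        rows.append(
            (a.target_id, t.chrom, t.start, t.end, t.strand, a.gene_id or ".", a.feature_kind)
        )
    return pd.DataFrame(
        rows, columns=["target_id", "chrom", "start", "end", "strand", "gene_id", "feature_kind"]
    )
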