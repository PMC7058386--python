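"""Genome annotation: GTF I/O, derived features and receptor-gene exclusion.

All coordinates are 0-based half-open internally.  GTF is 1-based closed;
conversion happens only at the I/O boundary.  Feature derivation splits each
transcript into CDS / 5'UTR / 3'UTR / intron intervals (or ncRNA for
non-coding transcripts), which downstream modules use to annotate RBP
crosslink clusters by the hierarchy CDS > 3'UTR > 5'UTR > intron > ncRNA.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

Interval = tuple[int, int]

#: Ensembl biotypes of antigen-receptor genes (immunoglobulin and T-cell
#: receptor segments, constant/joining/variable/diversity genes and their
#: pseudogene variants).  Matched by prefix.
RECEPTOR_BIOTYPE_PREFIXES = ("IG_", "TR_")

FEATURE_PRIORITY = {"CDS": 0, "UTR3": 1, "UTR5": 2, "intron": 3, "ncRNA": 4}


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def validate(self) -> None:
        for s, e in self.exons + self.cds:
            if not (0 <= s < e):
                raise ValueError(
                    f"transcript {self.id}: invalid interval [{s}, {e})"
                )
        for i in range(len(self.exons) - 1):
            if self.exons[i][1] > self.exons[i + 1][0]:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or are unsorted"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(
                    f"transcript {self.id}: CDS [{cs}, {ce}) outside exons"
                )


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    name: str = ""
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_gene = {g.id: g for g in self.genes}

    def gene(self, gene_id: str) -> Gene:
        return self._by_gene[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    @property
    def transcripts(self) -> list[Transcript]:
        return [t for g in self.genes for t in g.transcripts]

    def validate(self) -> None:
        for t in self.transcripts:
            t.validate()


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path) -> GenomeAnnotation:
    """Parse a GTF file into a :class:`GenomeAnnotation`.

    Recognises gene / transcript / exon / CDS / stop_codon records.
    stop_codon intervals are merged into the CDS (Ensembl places the stop
    codon outside the CDS; leaving it out would shift the 3'UTR start by
    3 nt).  Genes or transcripts not declared by their own records are
    inferred from exon lines.

    Raises
    ------
    GtfParseError
        On a record missing gene_id/transcript_id or with start > end;
        the message carries the 1-based line number.
    """
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields, got {len(parts)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if start1 > end1:
                raise GtfParseError(f"line {lineno}: start {start1} > end {end1}")
            # GTF 1-based closed -> 0-based half-open
            start, end = start1 - 1, end1
            attrs = _parse_attrs(attrs_s)
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]

            if ftype == "gene":
                genes.setdefault(
                    gid,
                    Gene(gid, chrom, strand,
                         biotype=attrs.get("gene_biotype", "protein_coding"),
                         name=attrs.get("gene_name", "")),
                )
                genes[gid].biotype = attrs.get("gene_biotype", genes[gid].biotype)
                genes[gid].name = attrs.get("gene_name", genes[gid].name)
                continue

            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
            tid = attrs["transcript_id"]
            if gid not in genes:
                genes[gid] = Gene(gid, chrom, strand,
                                  biotype=attrs.get("gene_biotype", "protein_coding"),
                                  name=attrs.get("gene_name", ""))
            if tid not in transcripts:
                transcripts[tid] = Transcript(
                    tid, gid, chrom, strand,
                    biotype=attrs.get("transcript_biotype", "protein_coding"),
                )
                genes[gid].transcripts.append(transcripts[tid])
            tx = transcripts[tid]
            if ftype == "exon":
                tx.exons.append((start, end))
            elif ftype in ("CDS", "stop_codon"):
                tx.cds.append((start, end))
            elif ftype == "transcript":
                tx.biotype = attrs.get("transcript_biotype", tx.biotype)

    for tx in transcripts.values():
        tx.exons.sort()
        tx.cds = _merge_adjacent(sorted(tx.cds))
    ann = GenomeAnnotation(list(genes.values()))
    ann.validate()
    return ann


def _merge_adjacent(ivs: list[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def write_gtf(ann: GenomeAnnotation, path) -> None:
    """Write annotation as GTF (gene/transcript/exon/CDS records)."""
    with open(path, "w") as fh:
        for g in ann.genes:
            if g.transcripts:
                gs = min(t.start for t in g.transcripts)
                ge = max(t.end for t in g.transcripts)
            else:
                gs, ge = 0, 1
            gattr = f'gene_id "{g.id}"; gene_biotype "{g.biotype}";'
            if g.name:
                gattr += f' gene_name "{g.name}";'
            fh.write(f"{g.chrom}\tsplicereg\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{gattr}\n")
            for t in g.transcripts:
                tattr = (
                    f'gene_id "{g.id}"; transcript_id "{t.id}"; '
                    f'gene_biotype "{g.biotype}"; transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\tsplicereg\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{tattr}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\tsplicereg\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{tattr}\n"
                    )
                for s, e in t.cds:
                    fh.write(
                        f"{t.chrom}\tsplicereg\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t{tattr}\n"
                    )


@dataclass(frozen=True)
class FeatureInterval:
    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # CDS | UTR3 | UTR5 | intron | ncRNA


class FeatureIndex:
    """Strand-aware interval lookup over derived transcript features."""

    def __init__(self, features: list[FeatureInterval], gene_ids: set[str]):
        self.features = features
        self.gene_ids = gene_ids
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for fi in features:
            key = (fi.chrom, fi.strand)
            self._trees.setdefault(key, IntervalTree())
            self._trees[key].addi(fi.start, fi.end, fi)

    def overlapping(self, chrom: str, start: int, end: int, strand: str) -> list[FeatureInterval]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def gene_features(self, gene_id: str, kind: str | None = None) -> list[FeatureInterval]:
        if gene_id not in self.gene_ids:
            raise KeyError(f"unknown gene_id {gene_id!r}")
        return [
            fi for fi in self.features
            if fi.gene_id == gene_id and (kind is None or fi.kind == kind)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (fi.transcript_id, fi.gene_id, fi.chrom, fi.start, fi.end, fi.strand, fi.kind)
                for fi in self.features
            ],
            columns=["transcript_id", "gene_id", "chrom", "start", "end", "strand", "feature_kind"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _clip_to_exons(exons: list[Interval], lo: int, hi: int) -> list[Interval]:
    """Exonic sequence intersected with genomic range [lo, hi)."""
    out = []
    for s, e in exons:
        cs, ce = max(s, lo), min(e, hi)
        if cs < ce:
            out.append((cs, ce))
    return out


def transcript_features(tx: Transcript) -> list[FeatureInterval]:
    """Split one transcript into labelled feature intervals.

    For a coding transcript the 5'UTR is the exonic sequence upstream
    (in transcription direction) of the first CDS base and the 3'UTR the
    exonic sequence downstream of the last CDS base; introns are exon gaps.
    A transcript without CDS contributes ncRNA exons and introns only.
    """
    feats: list[FeatureInterval] = []

    def add(kind: str, ivs: list[Interval]) -> None:
        for s, e in ivs:
            feats.append(FeatureInterval(tx.id, tx.gene_id, tx.chrom, s, e, tx.strand, kind))

    add("intron", tx.introns())
    if not tx.is_coding:
        add("ncRNA", tx.exons)
        return feats

    cds_lo = min(s for s, _ in tx.cds)
    cds_hi = max(e for _, e in tx.cds)
    add("CDS", tx.cds)
    left = _clip_to_exons(tx.exons, tx.start, cds_lo)
    right = _clip_to_exons(tx.exons, cds_hi, tx.end)
    if tx.strand == "+":
        add("UTR5", left)
        add("UTR3", right)
    else:
        add("UTR3", left)
        add("UTR5", right)
    return feats


def derive_features(ann: GenomeAnnotation) -> FeatureIndex:
    """Build the feature index for all transcripts of an annotation."""
    ann.validate()
    feats: list[FeatureInterval] = []
    for tx in ann.transcripts:
        feats.extend(transcript_features(tx))
    return FeatureIndex(feats, {g.id for g in ann.genes})


def is_receptor_biotype(biotype: str, prefixes=RECEPTOR_BIOTYPE_PREFIXES) -> bool:
    return biotype.startswith(tuple(prefixes))


def exclude_receptor_genes(
    gene_table: pd.DataFrame,
    ann: GenomeAnnotation,
    prefixes=RECEPTOR_BIOTYPE_PREFIXES,
) -> tuple[pd.DataFrame, set[str]]:
    """Drop immunoglobulin / T-cell-receptor genes from a gene table.

    Genes are classified by Ensembl biotype prefix (IG_*, TR_* families,
    including pseudogene variants).  Genes absent from the annotation
    cannot be classified: they are retained with a warning.

    Returns the filtered table and the set of removed gene ids.
    """
    if "gene_id" not in gene_table.columns:
        raise ValueError("gene table must have a gene_id column")
    removed: set[str] = set()
    unknown = []
    keep_mask = []
    for gid in gene_table["gene_id"]:
        if gid not in ann:
            unknown.append(gid)
            keep_mask.append(True)
            continue
        if is_receptor_biotype(ann.gene(gid).biotype, prefixes):
            removed.add(gid)
            keep_mask.append(False)
        else:
            keep_mask.append(True)
    if unknown:
        warnings.warn(
            f"{len(unknown)} gene id(s) absent from annotation; retained unclassified",
            stacklevel=2,
        )
    return gene_table.loc[keep_mask].reset_index(drop=True), removed
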