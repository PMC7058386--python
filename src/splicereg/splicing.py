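"""rMATS-style alternative-splicing events: I/O, filters, deduplication, NMD.

Event tables follow the rMATS junction-count (JC) layout, one TSV per event
type (SE, MXE, A5SS, A3SS, RI), with per-replicate inclusion levels (PSI)
and inclusion/skipping junction counts as comma-separated lists.  rMATS
coordinates are 0-based starts with exclusive ends and are kept as-is.

The significance filter keeps events with FDR < 0.05, |ΔPSI| > 0.1, a host
gene expressed at >= 1 FPKM (mean over replicates) in at least one genotype,
and at least 80 junction reads summed over the five replicates on either
the inclusion or the skipping form in at least one condition.  Events
sharing the same event-defining coordinates are deduplicated to the one
with the largest |ΔPSI|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotation import GenomeAnnotation, Transcript

log = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

#: per-type rMATS coordinate columns, in file order
COORD_COLUMNS = {
    "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "MXE": ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd",
            "upstreamES", "upstreamEE", "downstreamES", "downstreamEE"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
}

#: columns whose coordinates define the alternative segment itself
#: (flanking exons excluded) — the deduplication key
EVENT_DEFINING_COLUMNS = {
    "SE": ["exonStart_0base", "exonEnd"],
    "MXE": ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE"],
    "RI": ["riExonStart_0base", "riExonEnd"],
}

FIXED_COLUMNS = ["ID", "GeneID", "chr", "strand"]
TAIL_COLUMNS = ["IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
                "IncFormLen", "SkipFormLen", "PValue", "FDR",
                "IncLevel1", "IncLevel2", "IncLevelDifference"]


class EventFormatError(ValueError):
    pass


def _parse_float_list(text: str) -> list[float | None]:
    out: list[float | None] = []
    for tok in str(text).split(","):
        tok = tok.strip()
        out.append(None if tok in ("NA", "", "nan") else float(tok))
    return out


def _parse_int_list(text: str) -> list[int]:
    return [int(tok) for tok in str(text).split(",")]


@dataclass
class SpliceEvent:
    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    coords: dict[str, int]
    ijc1: list[int]
    sjc1: list[int]
    ijc2: list[int]
    sjc2: list[int]
    inc_form_len: int
    skip_form_len: int
    pvalue: float
    fdr: float
    inc1: list[float | None]
    inc2: list[float | None]
    inc_level_difference: float
    raw: dict[str, str] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise EventFormatError(f"unknown event type {self.event_type!r}")
        for psi in self.inc1 + self.inc2:
            if psi is not None and not (0.0 <= psi <= 1.0):
                raise EventFormatError(f"event {self.event_id}: PSI {psi} outside [0, 1]")
        if not (-1.0 <= self.inc_level_difference <= 1.0):
            raise EventFormatError(
                f"event {self.event_id}: inclusion-level difference outside [-1, 1]"
            )
        for col in COORD_COLUMNS[self.event_type]:
            if col not in self.coords:
                raise EventFormatError(f"event {self.event_id}: missing coordinate {col}")

    def coordinate_key(self) -> tuple:
        """Hashable key over the event-defining coordinates (flanks excluded)."""
        return (self.chrom, self.strand) + tuple(
            self.coords[c] for c in EVENT_DEFINING_COLUMNS[self.event_type]
        )

    def mean_psi(self, condition: int) -> float | None:
        vals = [v for v in (self.inc1 if condition == 1 else self.inc2) if v is not None]
        return sum(vals) / len(vals) if vals else None


def load_events(path, event_type: str) -> list[SpliceEvent]:
    """Read one rMATS-style TSV of the given event type.

    Only junction-count (JC) columns are used.  NA tokens in the
    comma-separated PSI lists become missing values; the raw strings are
    retained so writes round-trip bit-exact.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    expected = FIXED_COLUMNS + COORD_COLUMNS[event_type] + TAIL_COLUMNS
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise EventFormatError(
            f"{path}: columns {missing} required for event type {event_type}"
        )
    events = []
    for _, row in table.iterrows():
        events.append(
            SpliceEvent(
                event_id=f"{event_type}:{row['ID']}",
                event_type=event_type,
                gene_id=row["GeneID"],
                chrom=row["chr"],
                strand=row["strand"],
                coords={c: int(row[c]) for c in COORD_COLUMNS[event_type]},
                ijc1=_parse_int_list(row["IJC_SAMPLE_1"]),
                sjc1=_parse_int_list(row["SJC_SAMPLE_1"]),
                ijc2=_parse_int_list(row["IJC_SAMPLE_2"]),
                sjc2=_parse_int_list(row["SJC_SAMPLE_2"]),
                inc_form_len=int(row["IncFormLen"]),
                skip_form_len=int(row["SkipFormLen"]),
                pvalue=float(row["PValue"]),
                fdr=float(row["FDR"]),
                inc1=_parse_float_list(row["IncLevel1"]),
                inc2=_parse_float_list(row["IncLevel2"]),
                inc_level_difference=float(row["IncLevelDifference"]),
                raw={c: row[c] for c in expected},
            )
        )
    return events


def _fmt_float_list(vals: list[float | None]) -> str:
    return ",".join("NA" if v is None else f"{v:.3f}" for v in vals)


def write_events(events: list[SpliceEvent], path, event_type: str | None = None) -> None:
    """Write events of one type to an rMATS-style TSV.

    Raw field strings from a prior load are reused verbatim, so
    write(load(x)) reproduces x byte-for-byte for schema-conforming input.
    """
    if event_type is None:
        if not events:
            raise ValueError("event_type required when writing an empty table")
        event_type = events[0].event_type
    cols = FIXED_COLUMNS + COORD_COLUMNS[event_type] + TAIL_COLUMNS
    rows = []
    for ev in events:
        if ev.event_type != event_type:
            raise ValueError(f"event {ev.event_id} is {ev.event_type}, table is {event_type}")
        if ev.raw:
            rows.append([ev.raw[c] for c in cols])
        else:
            vals = {
                "ID": ev.event_id.split(":", 1)[1],
                "GeneID": ev.gene_id,
                "chr": ev.chrom,
                "strand": ev.strand,
                **{c: str(ev.coords[c]) for c in COORD_COLUMNS[event_type]},
                "IJC_SAMPLE_1": ",".join(map(str, ev.ijc1)),
                "SJC_SAMPLE_1": ",".join(map(str, ev.sjc1)),
                "IJC_SAMPLE_2": ",".join(map(str, ev.ijc2)),
                "SJC_SAMPLE_2": ",".join(map(str, ev.sjc2)),
                "IncFormLen": str(ev.inc_form_len),
                "SkipFormLen": str(ev.skip_form_len),
                "PValue": f"{ev.pvalue:.6g}",
                "FDR": f"{ev.fdr:.6g}",
                "IncLevel1": _fmt_float_list(ev.inc1),
                "IncLevel2": _fmt_float_list(ev.inc2),
                "IncLevelDifference": f"{ev.inc_level_difference:.3f}",
            }
            rows.append([vals[c] for c in cols])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


@dataclass
class SpliceFilterThresholds:
    fdr: float = 0.05            # strict <
    dpsi: float = 0.1            # strict > on |ΔPSI|
    fpkm_floor: float = 1.0      # >= in at least one genotype
    min_junction_reads: int = 80  # >= on a replicate-summed form in one condition


def filter_events(
    events: list[SpliceEvent],
    mean_fpkm: pd.DataFrame,
    thresholds: SpliceFilterThresholds | None = None,
) -> tuple[list[SpliceEvent], dict[str, int]]:
    """Apply the four-condition significance filter.

    An event survives iff all hold:

    * FDR < 0.05
    * |inclusion level difference| > 0.1
    * host gene mean FPKM >= 1 in at least one genotype
    * the replicate-summed inclusion OR skipping junction counts reach 80
      in at least one of the two conditions

    An event whose gene is absent from the FPKM table, or whose PSI list is
    all-missing in a condition, is excluded (counts reported).

    Returns the surviving events and a per-reason exclusion tally.
    """
    thresholds = thresholds or SpliceFilterThresholds()
    max_fpkm = mean_fpkm.max(axis=1)
    kept = []
    reasons = {
        "fdr": 0, "dpsi": 0, "expression": 0, "coverage": 0,
        "gene_missing": 0, "all_na_psi": 0,
    }
    for ev in events:
        if ev.mean_psi(1) is None or ev.mean_psi(2) is None:
            reasons["all_na_psi"] += 1
            continue
        if ev.gene_id not in max_fpkm.index:
            reasons["gene_missing"] += 1
            log.info("event %s: gene %s absent from FPKM table", ev.event_id, ev.gene_id)
            continue
        if not ev.fdr < thresholds.fdr:
            reasons["fdr"] += 1
            continue
        if not abs(ev.inc_level_difference) > thresholds.dpsi:
            reasons["dpsi"] += 1
            continue
        if not max_fpkm[ev.gene_id] >= thresholds.fpkm_floor:
            reasons["expression"] += 1
            continue
        sums = (sum(ev.ijc1), sum(ev.sjc1), sum(ev.ijc2), sum(ev.sjc2))
        if not any(s >= thresholds.min_junction_reads for s in sums):
            reasons["coverage"] += 1
            continue
        kept.append(ev)
    return kept, reasons


def deduplicate_events(events: list[SpliceEvent]) -> list[SpliceEvent]:
    """Keep, per identical event-defining coordinate group, the event with
    the highest |ΔPSI|; ties broken by lower FDR, then event_id."""
    groups: dict[tuple, list[SpliceEvent]] = {}
    order: list[tuple] = []
    for ev in events:
        key = ev.coordinate_key()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(ev)
    return [
        min(groups[key], key=lambda e: (-abs(e.inc_level_difference), e.fdr, e.event_id))
        for key in order
    ]


# --- NMD flagging -----------------------------------------------------------


def _alt_segment(ev: SpliceEvent) -> tuple[int, int]:
    """Genomic interval added by the inclusion isoform relative to skipping."""
    c = ev.coords
    if ev.event_type == "SE":
        return c["exonStart_0base"], c["exonEnd"]
    if ev.event_type == "RI":
        return c["upstreamEE"], c["downstreamES"]
    if ev.event_type in ("A5SS", "A3SS"):
        # extra sequence of the long form relative to the short form
        if c["longExonStart_0base"] == c["shortES"]:
            return c["shortEE"], c["longExonEnd"]
        return c["longExonStart_0base"], c["shortES"]
    raise ValueError(f"no single alternative segment for event type {ev.event_type}")


def _modified_exon_chain(ev: SpliceEvent, tx: Transcript, included: bool) -> list | None:
    """Exon chain of the event isoform, built from a reference transcript.

    Returns None when the event cannot be reconciled with the transcript
    (its flanking coordinates do not match exon boundaries).
    """
    exons = list(tx.exons)
    c = ev.coords

    if ev.event_type == "SE":
        se = (c["exonStart_0base"], c["exonEnd"])
        base = [e for e in exons if e != se]
        if included:
            base = sorted(base + [se])
        return base
    if ev.event_type == "RI":
        up = (c["upstreamES"], c["upstreamEE"])
        down = (c["downstreamES"], c["downstreamEE"])
        if up not in exons or down not in exons:
            return None
        if not included:
            return exons
        merged = []
        for e in exons:
            if e == up:
                merged.append((up[0], down[1]))
            elif e == down:
                continue
            else:
                merged.append(e)
        return merged
    if ev.event_type in ("A5SS", "A3SS"):
        long_e = (c["longExonStart_0base"], c["longExonEnd"])
        short_e = (c["shortES"], c["shortEE"])
        out = []
        seen = False
        for e in exons:
            if e in (long_e, short_e):
                out.append(long_e if included else short_e)
                seen = True
            else:
                out.append(e)
        return sorted(set(out)) if seen else None
    if ev.event_type == "MXE":
        e1 = (c["1stExonStart_0base"], c["1stExonEnd"])
        e2 = (c["2ndExonStart_0base"], c["2ndExonEnd"])
        base = [e for e in exons if e not in (e1, e2)]
        return sorted(base + [e1 if included else e2])
    return None


def _tx_coord(chain: list, strand: str, genomic_pos: int) -> float | None:
    """Transcript coordinate of a genomic position (0-based, within an exon)."""
    lens = [e - s for s, e in chain]
    if strand == "+":
        offset = 0
        for (s, e), ln in zip(chain, lens):
            if s <= genomic_pos < e:
                return offset + (genomic_pos - s)
            offset += ln
    else:
        offset = 0
        for (s, e), ln in zip(reversed(chain), [ln for ln in reversed(lens)]):
            if s <= genomic_pos < e:
                return offset + (e - 1 - genomic_pos)
            offset += ln
    return None


def flag_nmd(
    ev: SpliceEvent,
    ann: GenomeAnnotation,
    included: bool = True,
    segment_stop_offset: int | None = None,
) -> bool | None:
    """Predict whether the event isoform is a nonsense-mediated-decay target.

    The alternative segment is inserted into / removed from a compatible
    coding transcript's exon chain and the position of the termination
    codon is compared with the final exon-exon junction of the modified
    isoform: a termination codon >= 50 nt upstream of that junction is a
    premature termination codon (PTC) and flags the isoform for NMD.

    Without transcript sequence a stop codon inside the alternative segment
    cannot be discovered; callers that know one (e.g. the synthetic
    generator's truth, or an external ORF scan) pass its 0-based offset
    within the segment in transcription direction via
    ``segment_stop_offset``.  If the segment lies within the CDS, shifts
    the reading frame and no in-segment stop is supplied, the flag is
    indeterminate.

    Returns True / False, or None when indeterminate (no compatible coding
    transcript, or an unresolvable frameshift).
    """
    if ev.gene_id not in ann:
        return None
    candidates = [t for t in ann.gene(ev.gene_id).transcripts if t.is_coding]
    for tx in candidates:
        chain = _modified_exon_chain(ev, tx, included)
        if not chain:
            continue
        if len(chain) < 2:
            return False  # no exon-exon junction -> no NMD
        strand = tx.strand
        total = sum(e - s for s, e in chain)
        # final junction position in transcript coordinates
        last_exon = chain[-1] if strand == "+" else chain[0]
        last_junction = total - (last_exon[1] - last_exon[0])

        cds_lo = min(s for s, _ in tx.cds)
        cds_hi = max(e for _, e in tx.cds)
        # 3'-most CDS base in transcription direction
        stop_genomic = cds_hi - 1 if strand == "+" else cds_lo

        if ev.event_type != "MXE":
            seg = _alt_segment(ev)
            seg_len = seg[1] - seg[0]
            seg_in_cds = seg[0] < cds_hi and seg[1] > cds_lo
        else:
            c = ev.coords
            e1 = (c["1stExonStart_0base"], c["1stExonEnd"])
            e2 = (c["2ndExonStart_0base"], c["2ndExonEnd"])
            seg = e1 if included else e2
            other = e2 if included else e1
            seg_len = (seg[1] - seg[0]) - (other[1] - other[0])
            seg_in_cds = seg[0] < cds_hi and seg[1] > cds_lo

        if segment_stop_offset is not None and included and seg_in_cds:
            seg_start_tc = _tx_coord(chain, strand, seg[0] if strand == "+" else seg[1] - 1)
            if seg_start_tc is None:
                continue
            stop_tc = seg_start_tc + segment_stop_offset
        else:
            if seg_in_cds and seg_len % 3 != 0:
                return None  # frameshift; downstream stop unknowable without sequence
            stop_tc = _tx_coord(chain, strand, stop_genomic)
            if stop_tc is None:
                return None  # annotated stop removed by the event
        return bool(last_junction - stop_tc >= 50)
    return None
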