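"""Per-event-type RBP-binding windows and bound/unbound classification.

For each significant splicing event a set of genomic windows is built in
which an overlapping CLIP cluster counts the event as bound by the RBP:

* SE — the skipped exon, 500 intronic nt on each side of it, both
  constitutive flanking exons, and the 500 intronic nt adjacent to each
  flanking exon (7 windows);
* MXE — as SE but for each of the two mutually exclusive exons
  (10 windows);
* A5SS — the long exon containing the alternative 5' splice site, the 500
  intronic nt downstream of it, the downstream flanking exon and the 500
  intronic nt upstream of that exon (4 windows);
* A3SS — the mirror image with the upstream flanking exon (4 windows);
* RI — the retained intron and the two flanking exons (3 windows).

Intronic windows cover intronic sequence only: they are clipped at the
neighbouring exon boundary, so in an intron shorter than 1,000 nt the two
opposing windows overlap but never leave the intron.  "Upstream" and
"downstream" are resolved on the transcribed strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .clip import ClipCluster
from .splicing import SpliceEvent

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 500

WINDOW_ROLES = (
    "alt_exon",
    "alt_exon_upstream_intron_500",
    "alt_exon_downstream_intron_500",
    "upstream_flank_exon",
    "downstream_flank_exon",
    "upstream_flank_exon_downstream_intron_500",
    "downstream_flank_exon_upstream_intron_500",
    "retained_intron",
)

# genomic-direction labels -> transcription-direction roles, per strand
_ROLE_BY_STRAND = {
    "+": {
        "left_flank_exon": "upstream_flank_exon",
        "right_flank_exon": "downstream_flank_exon",
        "left_flank_inner_500": "upstream_flank_exon_downstream_intron_500",
        "right_flank_inner_500": "downstream_flank_exon_upstream_intron_500",
        "alt_left_500": "alt_exon_upstream_intron_500",
        "alt_right_500": "alt_exon_downstream_intron_500",
        "alt_exon": "alt_exon",
        "retained_intron": "retained_intron",
    },
    "-": {
        "left_flank_exon": "downstream_flank_exon",
        "right_flank_exon": "upstream_flank_exon",
        "left_flank_inner_500": "downstream_flank_exon_upstream_intron_500",
        "right_flank_inner_500": "upstream_flank_exon_downstream_intron_500",
        "alt_left_500": "alt_exon_downstream_intron_500",
        "alt_right_500": "alt_exon_upstream_intron_500",
        "alt_exon": "alt_exon",
        "retained_intron": "retained_intron",
    },
}


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    strand: str
    role: str


@dataclass
class BindingWindowSet:
    event_id: str
    event_type: str
    windows: list[Window]

    def __iter__(self):
        return iter(self.windows)


class WindowError(ValueError):
    pass


def _win(ev, start, end, label, out, size_note=""):
    role = _ROLE_BY_STRAND[ev.strand][label]
    if start < end:
        out.append(Window(ev.chrom, start, end, ev.strand, role))
    else:
        log.debug("event %s: degenerate %s window dropped%s", ev.event_id, role, size_note)


def _exon_with_introns(ev, exon, left_bound, right_bound, size, out,
                       left_label="alt_left_500", right_label="alt_right_500",
                       exon_label="alt_exon"):
    """One exon window plus its two adjacent intronic windows, clipped so the
    intronic windows stay between the exon and its neighbours."""
    s, e = exon
    _win(ev, s, e, exon_label, out)
    _win(ev, max(s - size, left_bound), s, left_label, out)
    _win(ev, e, min(e + size, right_bound), right_label, out)


def build_windows(ev: SpliceEvent, size: int = DEFAULT_WINDOW_SIZE) -> BindingWindowSet:
    """Construct the event-type-specific window set for one splicing event.

    Windows are built in genomic coordinates and role-labelled on the
    transcribed strand, so mirroring an event and flipping its strand
    yields the mirrored windows with upstream/downstream roles swapped.
    Zero-length windows after clipping (e.g. an exon abutting the
    alternative segment) are dropped with a debug log line.
    """
    c = ev.coords
    out: list[Window] = []
    t = ev.event_type

    # flanking exons are sorted genomically: rMATS names them in transcript
    # orientation, so on the minus strand "upstream" is genomically right
    if t == "SE":
        alt = (c["exonStart_0base"], c["exonEnd"])
        left, right = sorted([(c["upstreamES"], c["upstreamEE"]),
                              (c["downstreamES"], c["downstreamEE"])])
        _require_order(ev, left, alt, right)
        _win(ev, left[0], left[1], "left_flank_exon", out)
        _win(ev, left[1], min(left[1] + size, alt[0]), "left_flank_inner_500", out)
        _exon_with_introns(ev, alt, left[1], right[0], size, out)
        _win(ev, max(right[0] - size, alt[1]), right[0], "right_flank_inner_500", out)
        _win(ev, right[0], right[1], "right_flank_exon", out)

    elif t == "MXE":
        left, right = sorted([(c["upstreamES"], c["upstreamEE"]),
                              (c["downstreamES"], c["downstreamEE"])])
        first, second = sorted([
            (c["1stExonStart_0base"], c["1stExonEnd"]),
            (c["2ndExonStart_0base"], c["2ndExonEnd"]),
        ])
        _require_order(ev, left, first, second, right)
        _win(ev, left[0], left[1], "left_flank_exon", out)
        _win(ev, left[1], min(left[1] + size, first[0]), "left_flank_inner_500", out)
        _exon_with_introns(ev, first, left[1], second[0], size, out)
        _exon_with_introns(ev, second, first[1], right[0], size, out)
        _win(ev, max(right[0] - size, second[1]), right[0], "right_flank_inner_500", out)
        _win(ev, right[0], right[1], "right_flank_exon", out)

    elif t in ("A5SS", "A3SS"):
        long_e = (c["longExonStart_0base"], c["longExonEnd"])
        flank = (c["flankingES"], c["flankingEE"])
        # labels are genomic-direction; _win resolves them on the strand
        if long_e[1] <= flank[0]:  # long exon genomically left of the flank
            intron = (long_e[1], flank[0])
            _win(ev, long_e[0], long_e[1], "alt_exon", out)
            _win(ev, intron[0], min(intron[0] + size, intron[1]), "alt_right_500", out)
            _win(ev, max(intron[1] - size, intron[0]), intron[1],
                 "right_flank_inner_500", out)
            _win(ev, flank[0], flank[1], "right_flank_exon", out)
        elif flank[1] <= long_e[0]:  # flank genomically left of the long exon
            intron = (flank[1], long_e[0])
            _win(ev, flank[0], flank[1], "left_flank_exon", out)
            _win(ev, intron[0], min(intron[0] + size, intron[1]),
                 "left_flank_inner_500", out)
            _win(ev, max(intron[1] - size, intron[0]), intron[1], "alt_left_500", out)
            _win(ev, long_e[0], long_e[1], "alt_exon", out)
        else:
            raise WindowError(f"event {ev.event_id}: long exon overlaps flanking exon")

    elif t == "RI":
        up, down = sorted([(c["upstreamES"], c["upstreamEE"]),
                           (c["downstreamES"], c["downstreamEE"])])
        intron = (up[1], down[0])
        if intron[0] >= intron[1]:
            raise WindowError(f"event {ev.event_id}: no intron between flanking exons")
        _win(ev, up[0], up[1], "left_flank_exon", out)
        _win(ev, intron[0], intron[1], "retained_intron", out)
        _win(ev, down[0], down[1], "right_flank_exon", out)

    else:
        raise WindowError(f"unknown event type {t!r}")

    return BindingWindowSet(ev.event_id, t, out)


def _require_order(ev, *exons):
    prev = None
    for e in exons:
        if e[0] >= e[1]:
            raise WindowError(f"event {ev.event_id}: empty exon {e}")
        if prev is not None and prev[1] > e[0]:
            raise WindowError(f"event {ev.event_id}: exons out of genomic order")
        prev = e


@dataclass
class BindingCall:
    event_id: str
    bound: bool
    hits: list[tuple[ClipCluster, str]]  # (cluster, window_role)

    @property
    def hit_roles(self) -> list[str]:
        return sorted({role for _, role in self.hits})


def classify_bound(
    ev: SpliceEvent,
    clusters: list[ClipCluster],
    size: int = DEFAULT_WINDOW_SIZE,
) -> BindingCall:
    """Classify one event as RBP-bound: true iff any same-strand cluster
    overlaps (>= 1 nt) any of the event's windows.  All hits are reported."""
    wset = build_windows(ev, size=size)
    hits = []
    for cl in clusters:
        if cl.chrom != ev.chrom or cl.strand != ev.strand:
            continue
        for w in wset:
            if cl.start < w.end and w.start < cl.end:
                hits.append((cl, w.role))
    return BindingCall(ev.event_id, bool(hits), hits)


def windows_to_bed(window_sets: list[BindingWindowSet], path) -> None:
    """Export windows as BED6 for genome-browser inspection."""
    with open(path, "w") as fh:
        for ws in window_sets:
            for w in ws.windows:
                fh.write(
                    f"{w.chrom}\t{w.start}\t{w.end}\t{ws.event_id}|{w.role}\t.\t{w.strand}\n"
                )
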