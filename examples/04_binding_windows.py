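"""Build per-event-type binding windows and classify an event as RBP-bound.

A skipped exon is bound when a cluster lies on the exon, within 500
intronic nt on either side of it, on a flanking exon, or within the 500
intronic nt adjacent to a flanking exon — seven windows in all.
"""

from splicereg.clip import ClipCluster
from splicereg.splicing import SpliceEvent
from splicereg.windows import build_windows, classify_bound

event = SpliceEvent(
    event_id="SE:demo", event_type="SE", gene_id="G1", chrom="chr1", strand="+",
    coords={"exonStart_0base": 2000, "exonEnd": 2100,
            "upstreamES": 1000, "upstreamEE": 1200,
            "downstreamES": 3000, "downstreamEE": 3200},
    ijc1=[50] * 5, sjc1=[50] * 5, ijc2=[80] * 5, sjc2=[20] * 5,
    inc_form_len=244, skip_form_len=122, pvalue=1e-4, fdr=1e-3,
    inc1=[0.5] * 5, inc2=[0.8] * 5, inc_level_difference=-0.3,
)

for w in build_windows(event):
    print(f"  [{w.start:>5}, {w.end:>5})  {w.role}")

cluster = ClipCluster("chr1", 2550, 2570, "+", name="clip1")
call = classify_bound(event, [cluster])
print(f"bound: {call.bound}  via {call.hit_roles}")
# The cluster sits in the intron downstream of the skipped exon, inside
# both the exon's downstream-500 window and the flank's upstream-500
# window (the intron is 900 nt, so the opposing windows overlap).
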