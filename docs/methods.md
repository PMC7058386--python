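# Methods

This note documents the models and procedures `splicereg` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where more than one reasonable
implementation existed.

## Coordinates and annotation model

All internal coordinates are 0-based half-open; GTF input/output converts
at the boundary (GTF is 1-based closed), and BED and rMATS coordinates are
used as-is (both already 0-based-start). This removes the off-by-one
hazard from window arithmetic. `stop_codon` GTF records are merged into
the CDS before UTR derivation, since Ensembl places the stop codon outside
the CDS and omitting it would shift the 3'UTR start by 3 nt. Transcripts
with incomplete CDS annotation are treated as coding with the CDS as
given.

Feature derivation splits each transcript exactly: for a coding
transcript, 5'UTR ∪ CDS ∪ 3'UTR partitions the exonic sequence (asserted
in tests), with 5'/3' resolved in transcription direction; a non-coding
transcript contributes ncRNA exons and introns only. Every transcript of
a gene contributes features; the binding hierarchy, not a canonical
transcript choice, resolves multi-isoform ambiguity.

## CLIP feature assignment

A cluster or single-nucleotide crosslink site is assigned to the
highest-priority feature it overlaps with ≥ 1 nt on the same strand
(iCLIP is strand-specific): CDS > 3'UTR > 5'UTR > intron > ncRNA, else
intergenic. Ties across genes at equal priority break by larger overlap,
then lexicographic gene id, making assignment deterministic and
independent of transcript order. A gene is 3'UTR-bound when any cluster
overlaps the 3'UTR of *any* of its transcripts; partial overlap suffices
(full containment is not required — a documented choice, since crosslink
clusters routinely straddle feature boundaries).

## Expression summaries and the differential filter

TPM: rateᵍ = countᵍ/lengthᵍ, scaled per library to 10⁶. FPKM: counts are
first normalised by median-of-ratios size factors (the geometric
normalisation family; cross-checked against pyDESeq2's implementation in
tests), then divided by (total normalised reads/10⁶) × (length/10³).
Gene length is the exonic length of the gene's representative transcript.

The differential filter keeps a gene iff padj < 0.05 (strict), |log₂FC| >
0.5 (strict) and mean FPKM ≥ 1 (inclusive) in at least one genotype, the
mean taken over the five replicates of each genotype. Genes with missing
padj (independent-filtering NAs) are excluded and counted. Transcriptome
similarity uses Spearman's ρ of log₁₀(mean TPM + 0.01); the pseudocount
and base are configurable but cannot change ρ (the transform is
monotone) — they exist for plotting parity.

The differential test itself is *not* reimplemented: the pipeline ingests
DESeq2-format tables. The synthetic module fills them with pyDESeq2
(design `~ sex + genotype`, Wald tests, BH adjustment), the same engine
family the real inputs come from.

## Splicing-event model and filter

Events follow the rMATS junction-count (JC) layout per type, with
per-replicate PSI and inclusion/skipping junction counts as
comma-separated lists (NA tokens allowed; raw strings are preserved so
tables round-trip byte-exact). The filter requires FDR < 0.05 (strict),
|ΔPSI| > 0.1 (strict), host-gene expression as above, and coverage: with
IncSumᶜ/SkpSumᶜ the replicate-summed inclusion/skipping counts in
condition c, the event passes iff any of the four sums is ≥ 80. This is
the literal four-way disjunction of "either the included or skipped …
in at least one of the two conditions". Events with all-missing PSI in a
condition are excluded (conservative; missing values are otherwise
ignored in means).

Deduplication groups events by their *event-defining* coordinates (the
alternative exon(s)/segment; flanking exons excluded from the key, since
the same physical event is often reported once per flanking-exon context)
and keeps the highest |ΔPSI|; ties break by lower FDR, then event id.

## Binding windows

Window sets per type (500 nt default width, configurable):

* SE: skipped exon, ± 500 intronic nt around it, both flanking exons,
  and the 500 intronic nt adjacent to each flanking exon — 7 windows.
* MXE: the SE rule applied to each mutually exclusive exon, sharing the
  flanking-exon windows — 10.
* A5SS/A3SS: the long exon (the extended form containing the alternative
  splice site), the 500 intronic nt of the intron on its alternative
  side, the flanking exon across that intron, and the 500 intronic nt
  adjacent to that flank — 4.
* RI: the retained intron and both flanking exons — 3.

Intronic windows are clipped at the neighbouring exon boundary: "intronic
nucleotides" must not cover exonic sequence, so an intron shorter than
1,000 nt yields two overlapping windows that never leave the intron.
Zero-length windows after clipping are dropped with a debug log.
Upstream/downstream are resolved on the transcribed strand; internally
windows are built genomically and role-labelled per strand, which makes
the construction mirror-symmetric (property-tested). Flanking-exon
columns are sorted genomically on input, so tables that name flanks in
transcript orientation (minus-strand rMATS output) are handled
identically. An event is **bound** iff ≥ 1 same-strand cluster overlaps
≥ 1 window by ≥ 1 nt.

## NMD flagging

The prediction uses the standard 50-nt rule: rebuild the event isoform on
a compatible coding transcript's exon chain (insert/remove the
alternative segment), locate the termination codon, and flag NMD iff it
lies ≥ 50 nt upstream of the final exon–exon junction in
modified-transcript coordinates. Without transcript sequence (FASTA
handling is out of scope) a stop codon *inside* an alternative segment
cannot be discovered; callers that know one — the synthetic truth, or an
external ORF scan — pass its in-segment offset. A frame-preserving
segment without an in-segment stop keeps the annotated stop (mapped into
the modified isoform); a frame-shifting segment without a supplied stop
is *indeterminate* (returned as `None`), as is an event that cannot be
reconciled with any coding transcript. Single-exon isoforms are never
NMD targets (no junction).

## Regulon clustering

Rows are z-scored with the sample (n−1) standard deviation (the common
heatmap-scaling convention; constant rows map to zero), clustered by
complete linkage on Euclidean distances (SciPy), and the tree is cut to
exactly `n_clusters` (default 4, matching the four labelled clusters of
the study's heatmaps; the cut count was not stated in the source methods
and is configurable). The clustering input is the union of
genes/events significant in any of the three pairwise comparisons. The
abundance matrix is size-factor-normalised counts; the splicing matrix is
per-library PSI reassembled from the comparison tables.

Cluster pattern calls: per cluster, the mean z per genotype; a genotype
whose mean clears both others by a margin δ (default 0.5 z-units) in the
same direction names the cluster ("dKO-up", "dKO-down", "sKO-specific",
…); knockout genotypes take precedence over control when several clear
the margin; otherwise "mixed". The margin makes an otherwise visual call
testable. Complete linkage is used for both matrices (stated in the
source methods only for the splicing heatmap; adopted for both).

## Synthetic study generator

The generator emulates the study design: 15 libraries = 3 genotypes × 5
replicates, 3 female + 2 male per genotype (the sex covariate enters the
pyDESeq2 design). Defaults, chosen once as the package's study
conditions: 300 genes on two chromosomes (multi-exon, both strands, ~10%
non-coding, ~5% antigen-receptor decoys, ~20% with a second isoform
carrying a longer 3'UTR; intron lengths mix < 1,000 nt and ≥ 1,200 nt to
exercise window clipping); negative-binomial counts with dispersion 0.05
and baseline means ~50–8,000; planted effects |log₂FC| = 2 on 20 dKO-up,
20 dKO-down and 10 sKO-specific genes, plus 5 sub-1-FPKM genes exercising
the expression floor; 24 events per type of which half are planted with
|ΔPSI| = 0.4 (80% dKO-specific, 20% sKO-specific), with coordinate
duplicates (half-strength shift) exercising deduplication and
coverage-8 events exercising the 80-read rule; junction counts are
binomial at coverage 200/replicate with read-level inclusion probability
implied by the PSI and the rMATS form lengths (read length 123).

CLIP clusters (20 nt) are planted uniformly inside a random window of
each bound-designated event group and inside the 3'UTR of each
bound-designated gene (bound fractions 0.5 and 0.25); unbound
designations get decoy clusters in a reserved region beyond all genes.
Placements are cross-checked so an event cluster never touches the 3'UTR
of an unbound-designated gene and vice versa — designation recovery is
exact by construction, which is what the binding-recovery checks assert.

The rMATS significance columns are filled by a two-proportion z-test on
pooled junction counts with BH adjustment — a deliberately simple
stand-in for rMATS's paired likelihood model, sufficient to make planted
events clearly significant and null events clearly not. Everything is a
deterministic function of (parameters, seed).

**What passing tests do and do not show.** The generator produces clean
binomial/NB data with independent replicates, no mapping bias, no
isoform-composition confounding, no correlated events within a gene, and
planted effects far from the thresholds. Recovery there validates the
*bookkeeping* — filters, windows, hierarchy, clustering — not the
statistical power or error control of DESeq2/rMATS on real libraries,
which the pipeline consumes as input.

## Numerical and degenerate-input choices

Strict vs inclusive threshold readings follow the stated rules: padj,
FDR and |ΔPSI| cutoffs are strict (>/<); the FPKM floor and the 80-read
rule are inclusive (≥). Constant rows z-score to zero rather than NaN.
Zero-length windows are dropped. A library with zero total counts is an
error naming the library. Duplicate BED lines collapse. All
tie-breaks (assignment, deduplication) are total orders, so every output
is reproducible byte-for-byte at a fixed seed — asserted end-to-end.

Problem sizes in the test-suite and acceptance runs (300 genes, 24
events/type, 1,000-target oracle comparisons) were chosen as the smallest
sizes at which every planted-recovery statistic is stable across seeds;
all generator parameters scale up through `SyntheticParams`.

## Known limitations

* NMD prediction cannot find stops inside novel segments without
  sequence; such cases are indeterminate rather than guessed.
* The event-isoform reconstruction handles the five rMATS types on
  annotation-consistent exon chains; events that do not match any
  transcript's exon structure are indeterminate.
* FPKM uses a representative-transcript length, not a union-exon length
  per gene.
* The two-proportion stand-in ignores replicate-level overdispersion in
  PSI; its FDR column is for pipeline plumbing, not inference on real
  data.
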