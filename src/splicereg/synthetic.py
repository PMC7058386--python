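"""Synthetic study generator with planted ground truth.

Emulates the study design end-to-end so every pipeline stage is testable
without external data: 3 genotypes (ctrl, sKO for the single knockout,
dKO for the double knockout) x 5 replicate libraries each, with a sex
covariate (3 female + 2 male per genotype); negative-binomial count
matrices with planted log2 fold changes on genotype-specific genes;
binomial junction-count splicing events with planted inclusion-level
differences; and CLIP clusters planted inside (or decoys strictly outside)
the binding windows of designated events and the 3'UTRs of designated
genes.  A truth manifest records every planted effect so downstream
sensitivity / false-discovery rates can be scored.

The differential-abundance tables are produced with pyDESeq2 (the same
engine family the pipeline's real inputs come from, design ~ sex +
genotype); the splicing FDR column comes from a two-proportion z-test on
pooled junction counts with Benjamini-Hochberg adjustment — a labelled
stand-in for rMATS's paired likelihood model, adequate for planting
clearly significant and clearly null events.

All outputs are deterministic functions of (parameters, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation, Gene, Transcript, derive_features, write_gtf
from .clip import ClipCluster, write_clusters
from .splicing import COORD_COLUMNS, SpliceEvent, write_events
from .windows import build_windows

log = logging.getLogger(__name__)

GENOTYPES = ("ctrl", "sKO", "dKO")
COMPARISONS = (("dKO", "ctrl"), ("dKO", "sKO"), ("sKO", "ctrl"))


@dataclass(frozen=True)
class StudyDesign:
    """3 genotypes x 5 replicates, 3 female + 2 male per genotype."""

    genotypes: tuple = GENOTYPES
    n_replicates: int = 5
    sexes: tuple = ("F", "F", "F", "M", "M")

    @property
    def libraries(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.genotypes for r in range(self.n_replicates)]

    @property
    def genotype_of(self) -> dict[str, str]:
        return {lib: lib.rsplit("_", 1)[0] for lib in self.libraries}

    @property
    def sex_of(self) -> dict[str, str]:
        return {
            f"{g}_{r + 1}": self.sexes[r]
            for g in self.genotypes
            for r in range(self.n_replicates)
        }


@dataclass
class SyntheticParams:
    """Defaults mirror the study design and plant unambiguous effects."""

    n_genes: int = 300
    p_noncoding: float = 0.10
    p_receptor: float = 0.05
    p_second_transcript: float = 0.20
    # differential abundance
    n_dko_up: int = 20
    n_dko_down: int = 20
    n_sko_specific: int = 10
    log2fc: float = 2.0
    dispersion: float = 0.05
    n_low_expression: int = 5
    # alternative splicing
    events_per_type: int = 24
    planted_event_fraction: float = 0.5
    dpsi: float = 0.4
    coverage: int = 200
    low_coverage: int = 8
    n_low_coverage: int = 2
    n_duplicates: int = 2
    read_length: int = 123
    # CLIP
    bound_fraction: float = 0.5
    cluster_width: int = 20
    utr3_bound_fraction: float = 0.25
    window_size: int = 500


@dataclass
class TruthManifest:
    """Planted ground truth sufficient to score every downstream stage."""

    seed: int
    params: dict
    de_genes: list[dict] = field(default_factory=list)     # gene_id, log2fc, direction, pattern
    low_expression_genes: list[str] = field(default_factory=list)
    as_events: list[dict] = field(default_factory=list)    # event_id, type, dpsi, pattern, ...
    bound_events: list[str] = field(default_factory=list)
    unbound_events: list[str] = field(default_factory=list)
    utr3_bound_genes: list[str] = field(default_factory=list)
    utr3_unbound_genes: list[str] = field(default_factory=list)

    def expected_de(self, comparison: tuple[str, str]) -> dict[str, str]:
        """gene_id -> 'up'/'down' expected significant in a pairwise comparison."""
        g1, g2 = comparison
        out = {}
        for rec in self.de_genes:
            shifted = {"dKO"} if rec["pattern"].startswith("dKO") else {"sKO"}
            delta = (1 if g1 in shifted else 0) - (1 if g2 in shifted else 0)
            if delta == 0:
                continue
            up = (rec["direction"] == "up") == (delta > 0)
            out[rec["gene_id"]] = "up" if up else "down"
        return out

    def expected_as(self, comparison: tuple[str, str]) -> set[str]:
        """event_ids expected to pass the significance filter in a comparison."""
        g1, g2 = comparison
        out = set()
        for rec in self.as_events:
            shifted = {"dKO"} if rec["pattern"].startswith("dKO") else {"sKO"}
            if ((g1 in shifted) != (g2 in shifted)):
                out.add(rec["event_id"])
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# --- annotation -------------------------------------------------------------


def generate_annotation(
    n_genes: int = 300,
    seed: int = 0,
    p_noncoding: float = 0.10,
    p_receptor: float = 0.05,
    p_second_transcript: float = 0.20,
) -> GenomeAnnotation:
    """Emit a deterministic multi-exon annotation on two chromosomes.

    Genes alternate strands and mix coding, non-coding and antigen-receptor
    decoy biotypes; intron lengths mix short (< 1,000 nt, to exercise
    binding-window clipping) and long introns; a fraction of genes carries
    a second transcript with a distinct (longer) 3'UTR.
    """
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    cursors = {"chrS1": 10_000, "chrS2": 10_000}
    for i in range(n_genes):
        gid = f"SYNG{i:05d}"
        chrom = "chrS1" if i % 2 == 0 else "chrS2"
        strand = "+" if rng.random() < 0.5 else "-"
        u = rng.random()
        if u < p_receptor:
            biotype = str(rng.choice(["IG_V_gene", "IG_C_gene", "TR_V_gene", "TR_J_gene"]))
            coding = True
        elif u < p_receptor + p_noncoding:
            biotype, coding = "lincRNA", False
        else:
            biotype, coding = "protein_coding", True

        n_exons = int(rng.integers(4, 9))
        exon_lens = rng.integers(120, 360, size=n_exons)
        # mix of short (window-clipping) and long introns
        intron_lens = np.where(
            rng.random(n_exons - 1) < 0.4,
            rng.integers(200, 900, size=n_exons - 1),
            rng.integers(1200, 3000, size=n_exons - 1),
        )
        pos = cursors[chrom]
        exons = []
        for j, ln in enumerate(exon_lens):
            exons.append((pos, pos + int(ln)))
            if j < n_exons - 1:
                pos = pos + int(ln) + int(intron_lens[j])
        cursors[chrom] = exons[-1][1] + int(rng.integers(8_000, 15_000))

        gene = Gene(gid, chrom, strand, biotype=biotype, name=f"Syn{i}")
        tid = f"SYNT{i:05d}.1"
        if coding:
            cds = _make_cds(exons, rng)
            tx = Transcript(tid, gid, chrom, strand, exons=exons, cds=cds, biotype=biotype)
        else:
            tx = Transcript(tid, gid, chrom, strand, exons=exons, biotype=biotype)
        gene.transcripts.append(tx)

        if coding and rng.random() < p_second_transcript:
            # second isoform with an extended terminal exon -> distinct 3'UTR
            exons2 = list(exons)
            if strand == "+":
                s, e = exons2[-1]
                exons2[-1] = (s, e + 200)
            else:
                s, e = exons2[0]
                exons2[0] = (max(0, s - 200), e)
            gene.transcripts.append(
                Transcript(f"SYNT{i:05d}.2", gid, chrom, strand,
                           exons=exons2, cds=list(tx.cds), biotype=biotype)
            )
        genes.append(gene)
    ann = GenomeAnnotation(genes)
    ann.validate()
    return ann


def _make_cds(exons, rng) -> list:
    """CDS spanning from inside the second exon to inside the second-to-last
    exon, trimmed so the total CDS length is a multiple of 3."""
    first, last = 1, len(exons) - 2
    cds_start = exons[first][0] + int(rng.integers(10, 60))
    cds_end = exons[last][1] - int(rng.integers(10, 60))
    cds = []
    for s, e in exons:
        cs, ce = max(s, cds_start), min(e, cds_end)
        if cs < ce:
            cds.append((cs, ce))
    total = sum(e - s for s, e in cds)
    trim = total % 3
    if trim:
        s, e = cds[-1]
        cds[-1] = (s, e - trim)
    return cds


def gene_lengths(ann: GenomeAnnotation) -> pd.Series:
    """Exonic length (union of the first transcript's exons) per gene, nt."""
    return pd.Series(
        {g.id: sum(e - s for s, e in g.transcripts[0].exons) for g in ann.genes},
        name="length",
    )


# --- counts and differential tables ----------------------------------------


@dataclass
class CountsSim:
    counts: pd.DataFrame            # genes x 15 libraries, integer
    metadata: pd.DataFrame          # libraries x (genotype, sex)
    lengths: pd.Series
    truth_de: list[dict]
    low_expression_genes: list[str]


def generate_counts(
    ann: GenomeAnnotation,
    params: SyntheticParams | None = None,
    seed: int = 0,
    design: StudyDesign | None = None,
) -> CountsSim:
    """Negative-binomial counts with planted genotype-specific fold changes.

    Planted dKO-up/down genes shift their mean only in dKO libraries by
    2**(+/-log2fc); sKO-specific genes shift in sKO libraries.  A subset of
    genes carries a male-sex multiplicative effect (the covariate the DE
    design absorbs).  Receptor-biotype and low-expression genes are never
    planted.
    """
    params = params or SyntheticParams()
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    gene_ids = [g.id for g in ann.genes]
    plantable = [
        g.id for g in ann.genes
        if not g.biotype.startswith(("IG_", "TR_")) and g.biotype == "protein_coding"
    ]
    need = params.n_dko_up + params.n_dko_down + params.n_sko_specific + params.n_low_expression
    if len(plantable) < need:
        raise ValueError(f"only {len(plantable)} plantable genes for {need} planted effects")
    chosen = list(rng.choice(plantable, size=need, replace=False))
    dko_up = chosen[: params.n_dko_up]
    dko_down = chosen[params.n_dko_up: params.n_dko_up + params.n_dko_down]
    sko = chosen[params.n_dko_up + params.n_dko_down: need - params.n_low_expression]
    low_expr = chosen[need - params.n_low_expression:]

    base = np.exp(rng.normal(np.log(300.0), 0.7, size=len(gene_ids)))
    base = np.clip(base, 50.0, 8000.0)
    base = pd.Series(base, index=gene_ids)
    base[low_expr] = 0.5  # below the 1 FPKM floor

    male_effect_genes = set(rng.choice(gene_ids, size=max(1, len(gene_ids) // 8), replace=False))
    fold = 2.0 ** params.log2fc

    truth = (
        [{"gene_id": g, "log2fc": params.log2fc, "direction": "up", "pattern": "dKO-up"}
         for g in dko_up]
        + [{"gene_id": g, "log2fc": -params.log2fc, "direction": "down", "pattern": "dKO-down"}
           for g in dko_down]
        + [{"gene_id": g, "log2fc": params.log2fc, "direction": "up", "pattern": "sKO-specific"}
           for g in sko]
    )
    shift = {rec["gene_id"]: rec for rec in truth}

    n_nb = 1.0 / params.dispersion
    cols = {}
    for lib in design.libraries:
        geno = design.genotype_of[lib]
        sex = design.sex_of[lib]
        mu = base.copy()
        for gid, rec in shift.items():
            target = "dKO" if rec["pattern"].startswith("dKO") else "sKO"
            if geno == target:
                mu[gid] = mu[gid] * (fold if rec["direction"] == "up" else 1.0 / fold)
        if sex == "M":
            mu[list(male_effect_genes & set(gene_ids))] *= 1.3
        p = n_nb / (n_nb + mu.to_numpy())
        cols[lib] = rng.negative_binomial(n_nb, p)
    counts = pd.DataFrame(cols, index=gene_ids)
    metadata = pd.DataFrame(
        {
            "genotype": [design.genotype_of[lib] for lib in design.libraries],
            "sex": [design.sex_of[lib] for lib in design.libraries],
        },
        index=design.libraries,
    )
    return CountsSim(counts, metadata, gene_lengths(ann), truth, list(low_expr))


def deseq2_tables(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    comparisons=COMPARISONS,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-comparison DESeq2 result tables (pyDESeq2, design ~ sex + genotype)."""
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    dds = DeseqDataSet(
        counts=counts.T,
        metadata=metadata,
        design="~sex + genotype",
        quiet=True,
    )
    dds.deseq2()
    out = {}
    for g1, g2 in comparisons:
        ds = DeseqStats(dds, contrast=["genotype", g1, g2], quiet=True)
        ds.summary()
        t = ds.results_df.reset_index().rename(columns={"index": "gene_id"})
        if "gene_id" not in t.columns:  # index name may survive
            t = t.rename(columns={t.columns[0]: "gene_id"})
        out[(g1, g2)] = t[["gene_id", "baseMean", "log2FoldChange", "lfcSE",
                           "stat", "pvalue", "padj"]]
    return out


# --- splicing events --------------------------------------------------------


@dataclass
class EventsSim:
    #: per (comparison, event_type) -> list of SpliceEvent rows
    tables: dict
    #: per-library PSI matrix (event_id x 15 libraries)
    psi: pd.DataFrame
    truth_as: list[dict]


def _event_sites(tx: Transcript, etype: str, rng) -> dict | None:
    """Pick coordinates for one event of the given type on a transcript."""
    ex = tx.exons
    n = len(ex)
    if etype == "SE" and n >= 4:
        i = int(rng.integers(1, n - 1))
        return {
            "exonStart_0base": ex[i][0], "exonEnd": ex[i][1],
            "upstreamES": ex[i - 1][0], "upstreamEE": ex[i - 1][1],
            "downstreamES": ex[i + 1][0], "downstreamEE": ex[i + 1][1],
        }
    if etype == "MXE" and n >= 5:
        i = int(rng.integers(1, n - 3))
        return {
            "1stExonStart_0base": ex[i][0], "1stExonEnd": ex[i][1],
            "2ndExonStart_0base": ex[i + 1][0], "2ndExonEnd": ex[i + 1][1],
            "upstreamES": ex[i - 1][0], "upstreamEE": ex[i - 1][1],
            "downstreamES": ex[i + 2][0], "downstreamEE": ex[i + 2][1],
        }
    if etype in ("A5SS", "A3SS") and n >= 3:
        # the long form extends an exon into the adjacent intron on the side
        # where the alternative splice site lies, per type and strand
        extend_right = (etype == "A5SS") == (tx.strand == "+")
        i = int(rng.integers(1, n - 1))
        ext = int(rng.integers(60, 120))
        if extend_right:
            gap = ex[i + 1][0] - ex[i][1] if i + 1 < n else 0
            if i + 1 >= n or gap < ext + 150:
                return None
            return {
                "longExonStart_0base": ex[i][0], "longExonEnd": ex[i][1] + ext,
                "shortES": ex[i][0], "shortEE": ex[i][1],
                "flankingES": ex[i + 1][0], "flankingEE": ex[i + 1][1],
            }
        gap = ex[i][0] - ex[i - 1][1]
        if gap < ext + 150:
            return None
        return {
            "longExonStart_0base": ex[i][0] - ext, "longExonEnd": ex[i][1],
            "shortES": ex[i][0], "shortEE": ex[i][1],
            "flankingES": ex[i - 1][0], "flankingEE": ex[i - 1][1],
        }
    if etype == "RI" and n >= 3:
        i = int(rng.integers(0, n - 1))
        return {
            "riExonStart_0base": ex[i][0], "riExonEnd": ex[i + 1][1],
            "upstreamES": ex[i][0], "upstreamEE": ex[i][1],
            "downstreamES": ex[i + 1][0], "downstreamEE": ex[i + 1][1],
        }
    return None


def generate_events(
    ann: GenomeAnnotation,
    params: SyntheticParams | None = None,
    seed: int = 0,
    design: StudyDesign | None = None,
    expressed_genes: set[str] | None = None,
) -> EventsSim:
    """Binomial junction-count events with planted inclusion differences.

    Per library, inclusion reads are Binomial(coverage, p) where p is the
    read-level inclusion probability implied by the library's PSI and the
    rMATS form lengths; planted events shift PSI by +/- dpsi in their
    target genotype.  Each per-type table also contains coordinate
    duplicates (to exercise deduplication) and low-coverage events (to
    exercise the 80-read rule).
    """
    params = params or SyntheticParams()
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    inc_len = 2 * (params.read_length - 1)
    skip_len = params.read_length - 1

    host_txs = [
        g.transcripts[0] for g in ann.genes
        if g.biotype == "protein_coding" and len(g.transcripts[0].exons) >= 5
        and (expressed_genes is None or g.id in expressed_genes)
    ]
    rng.shuffle(host_txs)
    tx_iter = iter(host_txs)

    truth: list[dict] = []
    events_meta: list[dict] = []  # one per event row (shared across comparisons)
    psi_rows = {}

    for etype in COORD_COLUMNS:
        n_planted = int(round(params.events_per_type * params.planted_event_fraction))
        next_id = 0
        made = 0
        while made < params.events_per_type:
            try:
                tx = next(tx_iter)
            except StopIteration:
                raise ValueError("annotation too small for the requested event count") from None
            coords = _event_sites(tx, etype, rng)
            if coords is None:
                continue
            planted = made < n_planted
            low_cov = made >= params.events_per_type - params.n_low_coverage
            if low_cov:
                # a real shift at starvation coverage: everything passes except
                # the 80-read rule, which must be the excluding condition
                pattern, dpsi = "dKO", params.dpsi
                base_psi = float(rng.uniform(0.3, 0.5))
            elif planted:
                pattern = "dKO" if (made % 5) != 4 else "sKO-specific"
                sign = 1 if made % 2 == 0 else -1
                dpsi = sign * params.dpsi
                base_psi = float(rng.uniform(0.3, 0.55)) if sign > 0 else float(
                    rng.uniform(0.45, 0.7)
                )
            else:
                pattern, dpsi = "null", 0.0
                base_psi = float(rng.uniform(0.2, 0.8))
            event_id = f"{etype}:{next_id}"
            meta = {
                "event_id": event_id, "etype": etype, "tx": tx, "coords": coords,
                "base_psi": base_psi, "dpsi": dpsi, "pattern": pattern,
                "coverage": params.low_coverage if low_cov else params.coverage,
            }
            events_meta.append(meta)
            next_id += 1
            made += 1
            if planted and not low_cov:
                truth.append({
                    "event_id": event_id, "event_type": etype, "gene_id": tx.gene_id,
                    "dpsi": dpsi,
                    "pattern": "dKO-specific" if pattern == "dKO" else "sKO-specific",
                })
            # coordinate duplicate with a weaker planted shift
            if planted and made <= params.n_duplicates:
                dup_id = f"{etype}:{next_id}"
                events_meta.append({**meta, "event_id": dup_id, "dpsi": dpsi / 2.0})
                next_id += 1

    # per-library junction counts
    for meta in events_meta:
        psi_by_geno = {g: meta["base_psi"] for g in design.genotypes}
        target = "dKO" if meta["pattern"].startswith("dKO") else "sKO"
        if meta["pattern"] != "null":
            psi_by_geno[target] = float(np.clip(meta["base_psi"] + meta["dpsi"], 0.02, 0.98))
        counts = {}
        psis = {}
        for lib in design.libraries:
            psi = psi_by_geno[design.genotype_of[lib]]
            p_read = psi * inc_len / (psi * inc_len + (1 - psi) * skip_len)
            inc = int(rng.binomial(meta["coverage"], p_read))
            skp = meta["coverage"] - inc
            counts[lib] = (inc, skp)
            num = inc / inc_len
            den = num + skp / skip_len
            psis[lib] = round(num / den, 3) if den > 0 else None
        meta["counts"] = counts
        meta["psi"] = psis
        psi_rows[meta["event_id"]] = psis

    tables: dict = {}
    for comp in COMPARISONS:
        g1, g2 = comp
        libs1 = [lib for lib in design.libraries if design.genotype_of[lib] == g1]
        libs2 = [lib for lib in design.libraries if design.genotype_of[lib] == g2]
        for etype in COORD_COLUMNS:
            rows = [m for m in events_meta if m["etype"] == etype]
            pvals = []
            for m in rows:
                i1 = sum(m["counts"][lib][0] for lib in libs1)
                s1 = sum(m["counts"][lib][1] for lib in libs1)
                i2 = sum(m["counts"][lib][0] for lib in libs2)
                s2 = sum(m["counts"][lib][1] for lib in libs2)
                pvals.append(_two_proportion_p(i1, s1, i2, s2))
            fdrs = multipletests(pvals, method="fdr_bh")[1] if pvals else []
            evs = []
            for m, p, q in zip(rows, pvals, fdrs):
                inc1 = [m["psi"][lib] for lib in libs1]
                inc2 = [m["psi"][lib] for lib in libs2]
                mean1 = np.mean([v for v in inc1 if v is not None])
                mean2 = np.mean([v for v in inc2 if v is not None])
                evs.append(SpliceEvent(
                    event_id=m["event_id"],
                    event_type=etype,
                    gene_id=m["tx"].gene_id,
                    chrom=m["tx"].chrom,
                    strand=m["tx"].strand,
                    coords=dict(m["coords"]),
                    ijc1=[m["counts"][lib][0] for lib in libs1],
                    sjc1=[m["counts"][lib][1] for lib in libs1],
                    ijc2=[m["counts"][lib][0] for lib in libs2],
                    sjc2=[m["counts"][lib][1] for lib in libs2],
                    inc_form_len=inc_len,
                    skip_form_len=skip_len,
                    pvalue=float(p),
                    fdr=float(q),
                    inc1=inc1,
                    inc2=inc2,
                    inc_level_difference=round(float(mean1 - mean2), 3),
                ))
            tables[(comp, etype)] = evs

    psi = pd.DataFrame.from_dict(psi_rows, orient="index")[design.libraries]
    return EventsSim(tables, psi, truth)


def _two_proportion_p(i1: int, s1: int, i2: int, s2: int) -> float:
    n1, n2 = i1 + s1, i2 + s2
    if n1 == 0 or n2 == 0:
        return 1.0
    p1, p2 = i1 / n1, i2 / n2
    pool = (i1 + i2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


DEFAULT_PATTERN_GROUPS = {
    # per-genotype latent means (ctrl, sKO, dKO): four genotype-specific
    # directions that stay distinct after per-row z-scoring (z-scores
    # remove amplitude, so groups must differ in shape, not scale)
    "dKO-up": (-0.5, -0.5, 1.0),
    "dKO-down": (0.5, 0.5, -1.0),
    "sKO-up": (-0.5, 1.0, -0.5),
    "sKO-down": (0.5, -1.0, 0.5),
}


def generate_pattern_matrix(
    n_per_group: int = 10,
    noise_sd: float = 0.3,
    seed: int = 0,
    groups: dict | None = None,
    design: StudyDesign | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Rows drawn from planted genotype patterns plus Gaussian noise.

    Returns the row x library matrix, the planted group label per row, and
    the expected pattern call per group (what ``call_cluster_patterns``
    should report for a cluster of such rows).
    """
    groups = groups or DEFAULT_PATTERN_GROUPS
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    index = []
    for gname, means in groups.items():
        mean_of = dict(zip(design.genotypes, means))
        for i in range(n_per_group):
            row = [
                mean_of[design.genotype_of[lib]] + rng.normal(0.0, noise_sd)
                for lib in design.libraries
            ]
            rows.append(row)
            labels.append(gname)
            index.append(f"{gname}:{i}")
    matrix = pd.DataFrame(rows, index=index, columns=design.libraries)
    expected_calls = {
        "dKO-up": "dKO-up", "dKO-down": "dKO-down",
        "dKO-up-graded": "dKO-up",
        "sKO-up": "sKO-specific", "sKO-down": "sKO-specific",
        "sKO-specific": "sKO-specific",
    }
    expected = {g: expected_calls.get(g, "mixed") for g in groups}
    return matrix, pd.Series(labels, index=index, name="group"), expected


# --- CLIP clusters ----------------------------------------------------------


@dataclass
class ClipSim:
    clusters: list[ClipCluster]
    bound_events: list[str]
    unbound_events: list[str]
    utr3_bound_genes: list[str]
    utr3_unbound_genes: list[str]


def generate_clip(
    ann: GenomeAnnotation,
    events: list[SpliceEvent],
    params: SyntheticParams | None = None,
    seed: int = 0,
    de_gene_ids: list[str] | None = None,
) -> ClipSim:
    """Plant clusters inside the windows of bound-designated events and the
    3'UTRs of bound-designated genes; decoys for unbound designations go to
    a reserved region beyond all annotated genes, so they can overlap no
    window or 3'UTR of anything.

    Designations are made per event-coordinate group (coordinate duplicates
    share windows, hence a designation), and placements are cross-checked:
    an event cluster is never placed inside the 3'UTR of a gene designated
    unbound, and a 3'UTR cluster never inside a window of an event group
    designated unbound, so designation recovery is exact by construction.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    clusters: list[ClipCluster] = []

    # reserved decoy space per chromosome, beyond every gene
    tails = {}
    for g in ann.genes:
        end = max(t.end for t in g.transcripts)
        tails[g.chrom] = max(tails.get(g.chrom, 0), end)
    tails = {c: e + 50_000 for c, e in tails.items()}

    # group events by coordinate key: duplicates share windows
    groups: dict[tuple, list[SpliceEvent]] = {}
    order: list[tuple] = []
    for ev in events:
        key = ev.coordinate_key()
        if key not in groups:
            groups[key] = []
            order.append(key)
        if ev.event_id not in {e.event_id for e in groups[key]}:
            groups[key].append(ev)

    idx = derive_features(ann)
    gene_ids = de_gene_ids if de_gene_ids is not None else [g.id for g in ann.genes]
    gene_designation = {
        gid: bool(rng.random() < params.utr3_bound_fraction) for gid in gene_ids
    }
    group_designation = {
        key: bool(rng.random() < params.bound_fraction) for key in order
    }
    windows_of = {
        key: list(build_windows(groups[key][0], size=params.window_size))
        for key in order
    }

    def overlaps(chrom, start, end, strand, ivs) -> bool:
        return any(
            chrom == c and strand == st and start < e and s < end
            for c, s, e, st in ivs
        )

    unbound_utr3 = [
        (fi.chrom, fi.start, fi.end, fi.strand)
        for gid, bound in gene_designation.items() if not bound
        for fi in idx.gene_features(gid, kind="UTR3")
    ]
    unbound_windows = [
        (w.chrom, w.start, w.end, w.strand)
        for key, bound in group_designation.items() if not bound
        for w in windows_of[key]
    ]

    bound_ids, unbound_ids = [], []
    for k, key in enumerate(order):
        evs = groups[key]
        ev = evs[0]
        placed = False
        if group_designation[key]:
            usable = [w for w in windows_of[key] if w.end - w.start >= 5]
            rng.shuffle(usable)
            for w in usable:
                width = min(params.cluster_width, w.end - w.start)
                for _ in range(10):
                    start = int(rng.integers(w.start, w.end - width + 1))
                    if not overlaps(ev.chrom, start, start + width, ev.strand, unbound_utr3):
                        clusters.append(ClipCluster(ev.chrom, start, start + width,
                                                    ev.strand, name=f"clip_ev_{k}"))
                        placed = True
                        break
                if placed:
                    break
        if placed:
            bound_ids.extend(e.event_id for e in evs)
        else:
            tails[ev.chrom] += 1000
            start = tails[ev.chrom]
            clusters.append(ClipCluster(ev.chrom, start, start + params.cluster_width,
                                        ev.strand, name=f"decoy_ev_{k}"))
            unbound_ids.extend(e.event_id for e in evs)

    utr3_bound, utr3_unbound = [], []
    for k, gid in enumerate(gene_ids):
        placed = False
        if gene_designation[gid]:
            utr3s = [fi for fi in idx.gene_features(gid, kind="UTR3")
                     if fi.end - fi.start >= 5]
            rng.shuffle(utr3s)
            for fi in utr3s:
                width = min(params.cluster_width, fi.end - fi.start)
                for _ in range(10):
                    start = int(rng.integers(fi.start, fi.end - width + 1))
                    if not overlaps(fi.chrom, start, start + width, fi.strand,
                                    unbound_windows):
                        clusters.append(ClipCluster(fi.chrom, start, start + width,
                                                    fi.strand, name=f"clip_utr_{k}"))
                        placed = True
                        break
                if placed:
                    break
        if placed:
            utr3_bound.append(gid)
        else:
            utr3_unbound.append(gid)
    return ClipSim(clusters, bound_ids, unbound_ids, utr3_bound, utr3_unbound)


# --- full dataset -----------------------------------------------------------


@dataclass
class DatasetPaths:
    root: Path
    gtf: Path
    counts: Path
    metadata: Path
    clusters: Path
    de_tables: dict
    event_tables: dict
    truth: Path
    config: Path


def generate_dataset(
    outdir,
    seed: int = 0,
    params: SyntheticParams | None = None,
    design: StudyDesign | None = None,
) -> tuple[DatasetPaths, TruthManifest]:
    """Generate and write a complete synthetic study to ``outdir``.

    Emits the GTF, the counts matrix and library metadata, the three
    DESeq2-format comparison tables, five rMATS-format event tables per
    comparison, the CLIP cluster BED, a pipeline config (YAML) and the
    truth manifest (JSON).  Deterministic for a fixed (params, seed).
    """
    import yaml

    params = params or SyntheticParams()
    design = design or StudyDesign()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    s_ann, s_cnt, s_ev, s_clip = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]

    ann = generate_annotation(params.n_genes, seed=s_ann,
                              p_noncoding=params.p_noncoding,
                              p_receptor=params.p_receptor,
                              p_second_transcript=params.p_second_transcript)
    gtf = out / "annotation.gtf"
    write_gtf(ann, gtf)

    csim = generate_counts(ann, params, seed=s_cnt, design=design)
    counts_path = out / "counts.tsv"
    csim.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    meta_path = out / "libraries.tsv"
    csim.metadata.rename_axis("library").to_csv(meta_path, sep="\t")
    (out / "gene_lengths.tsv").write_text(
        "gene_id\tlength\n"
        + "".join(f"{g}\t{v}\n" for g, v in csim.lengths.items())
    )

    de_tables = deseq2_tables(csim.counts, csim.metadata)
    de_paths = {}
    for comp, table in de_tables.items():
        p = out / f"de_{comp[0]}_vs_{comp[1]}.tsv"
        table.to_csv(p, sep="\t", index=False, na_rep="NA")
        de_paths[comp] = p

    expressed = set(csim.counts.index) - set(csim.low_expression_genes)
    esim = generate_events(ann, params, seed=s_ev, design=design, expressed_genes=expressed)
    event_paths = {}
    for (comp, etype), evs in esim.tables.items():
        p = out / f"events_{comp[0]}_vs_{comp[1]}_{etype}.tsv"
        write_events(evs, p, event_type=etype)
        event_paths[(comp, etype)] = p
    esim.psi.rename_axis("event_id").to_csv(out / "event_psi_by_library.tsv", sep="\t")

    all_events = [ev for (comp, _), evs in esim.tables.items()
                  if comp == COMPARISONS[0] for ev in evs]
    clip = generate_clip(ann, all_events, params, seed=s_clip)
    bed = out / "clip_clusters.bed"
    write_clusters(clip.clusters, bed)

    manifest = TruthManifest(
        seed=seed,
        params=asdict(params),
        de_genes=csim.truth_de,
        low_expression_genes=csim.low_expression_genes,
        as_events=esim.truth_as,
        bound_events=clip.bound_events,
        unbound_events=clip.unbound_events,
        utr3_bound_genes=clip.utr3_bound_genes,
        utr3_unbound_genes=clip.utr3_unbound_genes,
    )
    truth_path = out / "truth.json"
    manifest.to_json(truth_path)

    # paths are written relative to the dataset root so the emitted files
    # are location-independent (and byte-identical across re-runs anywhere)
    config = {
        "annotation": gtf.name,
        "clusters": bed.name,
        "counts": counts_path.name,
        "libraries": meta_path.name,
        "gene_lengths": "gene_lengths.tsv",
        "comparisons": {
            f"{g1}_vs_{g2}": {
                "condition_1": g1,
                "condition_2": g2,
                "de_table": de_paths[(g1, g2)].name,
                "events": {etype: event_paths[((g1, g2), etype)].name
                           for etype in COORD_COLUMNS},
            }
            for g1, g2 in COMPARISONS
        },
        "thresholds": {
            "padj": 0.05, "log2fc": 0.5, "fpkm_floor": 1.0,
            "fdr": 0.05, "dpsi": 0.1, "min_junction_reads": 80,
            "window_size": params.window_size, "n_clusters": 4, "pattern_margin": 0.5,
        },
        "outdir": "results",
    }
    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    paths = DatasetPaths(out, gtf, counts_path, meta_path, bed,
                         de_paths, event_paths, truth_path, config_path)
    return paths, manifest
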