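import numpy as np
import pytest

from splicereg.annotation import GenomeAnnotation, Gene, Transcript
from splicereg.pipeline import PipelineConfig, run_pipeline
from splicereg.splicing import COORD_COLUMNS, SpliceEvent
from splicereg.synthetic import generate_dataset


def make_event(
    etype: str,
    coords: dict,
    strand: str = "+",
    chrom: str = "chrT",
    gene_id: str = "G1",
    event_id: str | None = None,
    dpsi: float = 0.2,
    fdr: float = 0.01,
    ijc1=None,
    sjc1=None,
    ijc2=None,
    sjc2=None,
    inc1=None,
    inc2=None,
) -> SpliceEvent:
    """Minimal valid SpliceEvent for window / filter tests."""
    n = 5
    return SpliceEvent(
        event_id=event_id or f"{etype}:0",
        event_type=etype,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        coords=coords,
        ijc1=ijc1 or [50] * n,
        sjc1=sjc1 or [50] * n,
        ijc2=ijc2 or [50] * n,
        sjc2=sjc2 or [50] * n,
        inc_form_len=244,
        skip_form_len=122,
        pvalue=fdr / 2,
        fdr=fdr,
        inc1=inc1 or [min(1.0, max(0.0, 0.5 + dpsi / 2))] * n,
        inc2=inc2 or [min(1.0, max(0.0, 0.5 - dpsi / 2))] * n,
        inc_level_difference=dpsi,
    )


def random_event(rng: np.random.Generator, etype: str | None = None) -> SpliceEvent:
    """Random event of any type with mixed short (< 1,000 nt) and long introns."""
    etype = etype or str(rng.choice(list(COORD_COLUMNS)))
    strand = "+" if rng.random() < 0.5 else "-"
    chrom = f"chr{int(rng.integers(1, 4))}"

    def exon_len():
        return int(rng.integers(50, 400))

    def intron_len():
        return int(rng.integers(80, 900)) if rng.random() < 0.5 else int(
            rng.integers(1000, 3000)
        )

    pos = int(rng.integers(1000, 100_000))

    def next_exon(gap):
        nonlocal pos
        start = pos + gap
        end = start + exon_len()
        pos = end
        return start, end

    first = next_exon(0)
    if etype == "SE":
        alt = next_exon(intron_len())
        last = next_exon(intron_len())
        coords = {"exonStart_0base": alt[0], "exonEnd": alt[1],
                  "upstreamES": first[0], "upstreamEE": first[1],
                  "downstreamES": last[0], "downstreamEE": last[1]}
    elif etype == "MXE":
        e1 = next_exon(intron_len())
        e2 = next_exon(intron_len())
        last = next_exon(intron_len())
        coords = {"1stExonStart_0base": e1[0], "1stExonEnd": e1[1],
                  "2ndExonStart_0base": e2[0], "2ndExonEnd": e2[1],
                  "upstreamES": first[0], "upstreamEE": first[1],
                  "downstreamES": last[0], "downstreamEE": last[1]}
    elif etype in ("A5SS", "A3SS"):
        flank = next_exon(intron_len())
        ext = int(rng.integers(20, (flank[0] - first[1]) // 2 + 21))
        if rng.random() < 0.5:  # long exon left of flank
            coords = {"longExonStart_0base": first[0], "longExonEnd": first[1] + ext,
                      "shortES": first[0], "shortEE": first[1],
                      "flankingES": flank[0], "flankingEE": flank[1]}
        else:  # long exon right of flank
            coords = {"longExonStart_0base": flank[0] - ext, "longExonEnd": flank[1],
                      "shortES": flank[0], "shortEE": flank[1],
                      "flankingES": first[0], "flankingEE": first[1]}
    else:  # RI
        last = next_exon(intron_len())
        coords = {"riExonStart_0base": first[0], "riExonEnd": last[1],
                  "upstreamES": first[0], "upstreamEE": first[1],
                  "downstreamES": last[0], "downstreamEE": last[1]}
    return make_event(etype, coords, strand=strand, chrom=chrom,
                      event_id=f"{etype}:{int(rng.integers(1e6))}")


@pytest.fixture()
def two_exon_tx() -> Transcript:
    """+ strand, exons [0,100) and [200,300), CDS [50,100)+[200,250)."""
    return Transcript("T1", "G1", "chrT", "+",
                      exons=[(0, 100), (200, 300)], cds=[(50, 100), (200, 250)])


@pytest.fixture()
def demo_annotation(two_exon_tx) -> GenomeAnnotation:
    g1 = Gene("G1", "chrT", "+", transcripts=[two_exon_tx])
    t2 = Transcript("T2", "G2", "chrT", "-",
                    exons=[(1000, 1100), (1200, 1300)],
                    cds=[(1050, 1100), (1200, 1250)])
    g2 = Gene("G2", "chrT", "-", transcripts=[t2])
    t3 = Transcript("T3", "G3", "chrT", "+", exons=[(2000, 2200)], biotype="lincRNA")
    g3 = Gene("G3", "chrT", "+", biotype="lincRNA", transcripts=[t3])
    return GenomeAnnotation([g1, g2, g3])


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    return generate_dataset(out, seed=11)


@pytest.fixture(scope="session")
def pipeline_report(synthetic_dataset):
    paths, _manifest = synthetic_dataset
    config = PipelineConfig.from_yaml(paths.config)
    return run_pipeline(config)
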