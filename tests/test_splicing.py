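import numpy as np
import pandas as pd
import pytest

from splicereg.annotation import GenomeAnnotation, Gene, Transcript
from splicereg.splicing import (
    SpliceFilterThresholds,
    deduplicate_events,
    filter_events,
    flag_nmd,
    load_events,
    write_events,
)
from splicereg.synthetic import COMPARISONS, SyntheticParams, generate_annotation, generate_events

from conftest import make_event


SE_COORDS = {
    "exonStart_0base": 2000, "exonEnd": 2100,
    "upstreamES": 1000, "upstreamEE": 1200,
    "downstreamES": 3000, "downstreamEE": 3200,
}


class TestEventIO:
    def test_na_tokens_become_missing(self, tmp_path):
        ev = make_event("SE", SE_COORDS, inc1=[0.5, 0.6, 0.55, None, 0.5])
        p = tmp_path / "se.tsv"
        write_events([ev], p)
        (back,) = load_events(p, "SE")
        assert back.inc1 == [0.5, 0.6, 0.55, None, 0.5]
        assert back.mean_psi(1) == pytest.approx(np.mean([0.5, 0.6, 0.55, 0.5]))

    def test_empty_table(self, tmp_path):
        p = tmp_path / "se.tsv"
        write_events([], p, event_type="SE")
        assert load_events(p, "SE") == []

    def test_round_trip_bit_exact(self, tmp_path, synthetic_dataset):
        """A generated SE table survives read -> write byte-for-byte."""
        paths, _ = synthetic_dataset
        src = paths.event_tables[(COMPARISONS[0], "SE")]
        events = load_events(src, "SE")
        out = tmp_path / "roundtrip.tsv"
        write_events(events, out, event_type="SE")
        assert out.read_text() == src.read_text()

    def test_wrong_column_set_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        write_events([make_event("SE", SE_COORDS)], p)
        with pytest.raises(ValueError, match="MXE"):
            load_events(p, "MXE")


class TestFilterEvents:
    FPKM = pd.DataFrame({"ctrl": [3.0], "dKO": [0.2]}, index=["G1"])

    def test_all_conditions_pass(self):
        ev = make_event("SE", SE_COORDS, dpsi=0.12, fdr=0.04,
                        ijc1=[17] * 5, sjc1=[2] * 5, ijc2=[5] * 5, sjc2=[10] * 5)
        kept, _ = filter_events([ev], self.FPKM)
        assert kept == [ev]

    def test_toy_table_one_failure_each(self):
        """Six events: one failing each of the four rules, one with an
        unknown gene, two passing -> exactly 2 survive."""
        good = dict(dpsi=0.2, fdr=0.01, ijc1=[20] * 5, sjc1=[20] * 5,
                    ijc2=[20] * 5, sjc2=[20] * 5)
        events = [
            make_event("SE", SE_COORDS, event_id="SE:pass1", **good),
            make_event("SE", SE_COORDS, event_id="SE:fdr", **{**good, "fdr": 0.2}),
            make_event("SE", SE_COORDS, event_id="SE:dpsi", **{**good, "dpsi": 0.05}),
            make_event("SE", SE_COORDS, event_id="SE:cov",
                       **{**good, "ijc1": [3] * 5, "sjc1": [3] * 5,
                          "ijc2": [3] * 5, "sjc2": [3] * 5}),
            make_event("SE", SE_COORDS, event_id="SE:expr", gene_id="GLOW", **good),
            make_event("SE", SE_COORDS, event_id="SE:pass2", **good),
        ]
        fpkm = pd.DataFrame({"ctrl": [3.0, 0.2]}, index=["G1", "GLOW"])
        kept, reasons = filter_events(events, fpkm)
        assert [e.event_id for e in kept] == ["SE:pass1", "SE:pass2"]
        assert reasons["fdr"] == 1 and reasons["dpsi"] == 1
        assert reasons["coverage"] == 1 and reasons["expression"] == 1

    @pytest.mark.parametrize(
        "field,value,kept_expected",
        [
            ("fdr", 0.05, False),       # FDR < 0.05 strict
            ("dpsi", 0.1, False),       # |ΔPSI| > 0.1 strict
            ("dpsi", 0.101, True),
        ],
    )
    def test_boundary_strictness(self, field, value, kept_expected):
        kw = dict(dpsi=0.2, fdr=0.01)
        kw[field] = value
        ev = make_event("SE", SE_COORDS, **kw)
        kept, _ = filter_events([ev], self.FPKM)
        assert bool(kept) is kept_expected

    def test_80_reads_boundary_inclusive(self):
        ev = make_event("SE", SE_COORDS, dpsi=0.2, fdr=0.01,
                        ijc1=[16] * 5, sjc1=[0] * 5, ijc2=[15] * 5, sjc2=[0] * 5)
        kept, _ = filter_events([ev], self.FPKM)
        assert kept  # IncSum_1 == 80 satisfies ">= 80"
        ev2 = make_event("SE", SE_COORDS, dpsi=0.2, fdr=0.01,
                         ijc1=[15] * 5, sjc1=[15] * 5,
                         ijc2=[15] * 5, sjc2=[15] * 5)
        kept2, _ = filter_events([ev2], self.FPKM)
        assert not kept2  # all four sums are 75 < 80

    def test_tightening_never_adds_events(self):
        rng = np.random.default_rng(5)
        events = [
            make_event("SE", SE_COORDS, event_id=f"SE:{i}",
                       dpsi=float(rng.uniform(-0.5, 0.5)),
                       fdr=float(rng.uniform(0, 0.2)),
                       ijc1=list(rng.integers(0, 40, 5)),
                       sjc1=list(rng.integers(0, 40, 5)),
                       ijc2=list(rng.integers(0, 40, 5)),
                       sjc2=list(rng.integers(0, 40, 5)))
            for i in range(40)
        ]
        loose, _ = filter_events(events, self.FPKM, SpliceFilterThresholds())
        tight, _ = filter_events(
            events, self.FPKM,
            SpliceFilterThresholds(fdr=0.01, dpsi=0.2, min_junction_reads=120),
        )
        assert {e.event_id for e in tight} <= {e.event_id for e in loose}


class TestDeduplicate:
    def test_highest_absolute_dpsi_wins(self):
        a = make_event("SE", SE_COORDS, event_id="SE:a", dpsi=0.2)
        b = make_event("SE", SE_COORDS, event_id="SE:b", dpsi=-0.3)
        assert deduplicate_events([a, b]) == [b]

    def test_singleton_unchanged(self):
        a = make_event("SE", SE_COORDS)
        assert deduplicate_events([a]) == [a]

    def test_tie_breaks_on_fdr_then_id(self):
        a = make_event("SE", SE_COORDS, event_id="SE:a", dpsi=0.3, fdr=0.02)
        b = make_event("SE", SE_COORDS, event_id="SE:b", dpsi=-0.3, fdr=0.01)
        assert deduplicate_events([a, b]) == [b]
        c = make_event("SE", SE_COORDS, event_id="SE:c", dpsi=0.3, fdr=0.01)
        assert deduplicate_events([a, c]) == [c]

    def test_flanks_excluded_from_key(self):
        other_flanks = {**SE_COORDS, "upstreamES": 900, "upstreamEE": 1100}
        a = make_event("SE", SE_COORDS, event_id="SE:a", dpsi=0.2)
        b = make_event("SE", other_flanks, event_id="SE:b", dpsi=0.5)
        assert deduplicate_events([a, b]) == [b]

    def test_matches_brute_force_grouping(self):
        """Every kept event attains its coordinate group's max |ΔPSI|."""
        rng = np.random.default_rng(8)
        coords_pool = [SE_COORDS,
                       {**SE_COORDS, "exonStart_0base": 2200, "exonEnd": 2300}]
        events = [
            make_event("SE", coords_pool[int(rng.integers(2))],
                       event_id=f"SE:{i}", dpsi=float(rng.uniform(-0.6, 0.6)))
            for i in range(30)
        ]
        kept = deduplicate_events(events)
        keys = [e.coordinate_key() for e in kept]
        assert len(keys) == len(set(keys))
        for e in kept:
            group = [x for x in events if x.coordinate_key() == e.coordinate_key()]
            assert abs(e.inc_level_difference) == pytest.approx(
                max(abs(x.inc_level_difference) for x in group)
            )


class TestFlagNmd:
    @pytest.fixture()
    def host(self):
        """Coding transcript: 4 exons; the SE event inserts/removes exon 2."""
        tx = Transcript(
            "T1", "G1", "chrT", "+",
            exons=[(1000, 1200), (2000, 2099), (3000, 3200), (4000, 4300)],
            cds=[(1100, 1200), (2000, 2099), (3000, 3200), (4000, 4100)],
        )
        return GenomeAnnotation([Gene("G1", "chrT", "+", transcripts=[tx])])

    def se_event(self):
        return make_event("SE", {
            "exonStart_0base": 2000, "exonEnd": 2099,
            "upstreamES": 1000, "upstreamEE": 1200,
            "downstreamES": 3000, "downstreamEE": 3200,
        })

    def test_in_segment_stop_far_from_last_junction(self, host):
        # 99-nt in-frame segment carrying a stop: PTC sits two exons
        # upstream of the final junction -> NMD
        assert flag_nmd(self.se_event(), host, included=True,
                        segment_stop_offset=30) is True

    def test_ptc_in_terminal_exon_is_not_nmd(self):
        tx = Transcript(
            "T1", "G1", "chrT", "+",
            exons=[(1000, 1200), (2000, 2099), (3000, 3200)],
            # annotated stop inside the terminal exon
            cds=[(1100, 1200), (2000, 2099), (3000, 3100)],
        )
        ann = GenomeAnnotation([Gene("G1", "chrT", "+", transcripts=[tx])])
        assert flag_nmd(self.se_event(), ann, included=True) is False

    def test_frameshift_without_known_stop_is_indeterminate(self, host):
        ev = make_event("SE", {
            "exonStart_0base": 2000, "exonEnd": 2100,  # 100 nt, not %3
            "upstreamES": 1000, "upstreamEE": 1200,
            "downstreamES": 3000, "downstreamEE": 3200,
        })
        # the host transcript lacks this exon variant; use skipping of a
        # frame-shifting exon instead
        tx = Transcript(
            "T1", "G1", "chrT", "+",
            exons=[(1000, 1200), (2000, 2100), (3000, 3200), (4000, 4300)],
            cds=[(1100, 1200), (2000, 2100), (3000, 3200), (4000, 4100)],
        )
        ann = GenomeAnnotation([Gene("G1", "chrT", "+", transcripts=[tx])])
        assert flag_nmd(ev, ann, included=False) is None

    def test_single_exon_isoform_cannot_be_nmd(self):
        tx = Transcript("T1", "G1", "chrT", "+",
                        exons=[(1000, 1200), (2000, 2099)],
                        cds=[(1050, 1200), (2000, 2060)])
        ann = GenomeAnnotation([Gene("G1", "chrT", "+", transcripts=[tx])])
        ev = make_event("SE", {
            "exonStart_0base": 2000, "exonEnd": 2099,
            "upstreamES": 1000, "upstreamEE": 1200,
            "downstreamES": 2000, "downstreamEE": 2099,
        })
        assert flag_nmd(ev, ann, included=False) is False

    def test_unreconcilable_event_indeterminate(self, host):
        ev = make_event("SE", {
            "exonStart_0base": 9000, "exonEnd": 9099,
            "upstreamES": 8000, "upstreamEE": 8100,
            "downstreamES": 9500, "downstreamEE": 9600,
        }, gene_id="NOPE")
        assert flag_nmd(ev, host, included=True) is None


class TestPlantedSignal:
    def test_planted_dpsi_concentrates(self):
        """At coverage 200/replicate the measured ΔPSI of planted events
        lies within 0.05 of the planted 0.4."""
        ann = generate_annotation(200, seed=21)
        params = SyntheticParams(events_per_type=10, n_low_coverage=0, n_duplicates=0)
        sim = generate_events(ann, params, seed=22)
        truth = {t["event_id"]: t for t in sim.truth_as}
        comp = COMPARISONS[0]  # dKO vs ctrl
        errors = []
        for etype in ("SE", "MXE", "A5SS", "A3SS", "RI"):
            for ev in sim.tables[(comp, etype)]:
                rec = truth.get(ev.event_id)
                if rec and rec["pattern"] == "dKO-specific":
                    errors.append(ev.inc_level_difference - rec["dpsi"])
                    # each event within binomial noise of its planted shift
                    assert abs(errors[-1]) < 0.1
        assert len(errors) >= 15
        assert abs(np.mean(errors)) < 0.05

    def test_null_events_rarely_exceed_dpsi_threshold(self):
        ann = generate_annotation(250, seed=23)
        params = SyntheticParams(events_per_type=20, planted_event_fraction=0.0,
                                 n_low_coverage=0, n_duplicates=0)
        sim = generate_events(ann, params, seed=24)
        comp = COMPARISONS[0]
        diffs = [abs(ev.inc_level_difference)
                 for etype in ("SE", "MXE", "A5SS", "A3SS", "RI")
                 for ev in sim.tables[(comp, etype)]]
        assert np.mean([d > 0.1 for d in diffs]) < 0.05
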