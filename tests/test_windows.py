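import numpy as np
import pytest

from splicereg.clip import ClipCluster
from splicereg.windows import WindowError, build_windows, classify_bound

from conftest import make_event, random_event


SE_COORDS = {
    "exonStart_0base": 2000, "exonEnd": 2100,
    "upstreamES": 1000, "upstreamEE": 1200,
    "downstreamES": 3000, "downstreamEE": 3200,
}


def _swap_role(role: str) -> str:
    """Role of the same window after a strand flip: upstream <-> downstream
    wherever they appear in the label."""
    return "_".join(
        {"upstream": "downstream", "downstream": "upstream"}.get(tok, tok)
        for tok in role.split("_")
    )


def oracle_windows(ev, size=500):
    """Independent enumerator: every event exon is a window; every intron
    between consecutive event exons contributes its first and last `size`
    nucleotides (clipped to the intron); an RI contributes the whole
    retained intron and no intronic flanks."""
    c = ev.coords
    if ev.event_type == "SE":
        exons = [(c["upstreamES"], c["upstreamEE"]),
                 (c["exonStart_0base"], c["exonEnd"]),
                 (c["downstreamES"], c["downstreamEE"])]
    elif ev.event_type == "MXE":
        exons = sorted([
            (c["upstreamES"], c["upstreamEE"]),
            (c["1stExonStart_0base"], c["1stExonEnd"]),
            (c["2ndExonStart_0base"], c["2ndExonEnd"]),
            (c["downstreamES"], c["downstreamEE"]),
        ])
    elif ev.event_type in ("A5SS", "A3SS"):
        exons = sorted([
            (c["longExonStart_0base"], c["longExonEnd"]),
            (c["flankingES"], c["flankingEE"]),
        ])
    else:  # RI
        up = (c["upstreamES"], c["upstreamEE"])
        down = (c["downstreamES"], c["downstreamEE"])
        return {up, down, (up[1], down[0])}
    wins = set(exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        intron = (e1, s2)
        wins.add((intron[0], min(intron[0] + size, intron[1])))
        wins.add((max(intron[1] - size, intron[0]), intron[1]))
    return {w for w in wins if w[0] < w[1]}


class TestBuildWindows:
    def test_se_example_coordinates_and_roles(self):
        ev = make_event("SE", SE_COORDS, strand="+")
        got = {(w.start, w.end): w.role for w in build_windows(ev)}
        assert got == {
            (1000, 1200): "upstream_flank_exon",
            (1200, 1700): "upstream_flank_exon_downstream_intron_500",
            (1500, 2000): "alt_exon_upstream_intron_500",
            (2000, 2100): "alt_exon",
            (2100, 2600): "alt_exon_downstream_intron_500",
            (2500, 3000): "downstream_flank_exon_upstream_intron_500",
            (3000, 3200): "downstream_flank_exon",
        }

    def test_minus_strand_swaps_role_labels(self):
        plus = {(w.start, w.end): w.role
                for w in build_windows(make_event("SE", SE_COORDS, strand="+"))}
        minus = {(w.start, w.end): w.role
                 for w in build_windows(make_event("SE", SE_COORDS, strand="-"))}
        assert set(plus) == set(minus)  # identical genomic intervals
        for iv, role in plus.items():
            assert minus[iv] == _swap_role(role)

    def test_ri_has_exactly_three_windows(self):
        ev = make_event("RI", {
            "riExonStart_0base": 400, "riExonEnd": 900,
            "upstreamES": 400, "upstreamEE": 500,
            "downstreamES": 800, "downstreamEE": 900,
        })
        got = {(w.start, w.end, w.role) for w in build_windows(ev)}
        assert got == {
            (400, 500, "upstream_flank_exon"),
            (500, 800, "retained_intron"),
            (800, 900, "downstream_flank_exon"),
        }

    @pytest.mark.parametrize("etype,expected",
                             [("SE", 7), ("MXE", 10), ("A5SS", 4), ("A3SS", 4), ("RI", 3)])
    def test_window_cardinality_per_type(self, etype, expected):
        rng = np.random.default_rng(4)
        for _ in range(40):
            ev = random_event(rng, etype)
            assert len(build_windows(ev).windows) == expected, ev.coords

    def test_short_intron_windows_clipped_to_intron(self):
        """In an intron shorter than 1,000 nt the opposing windows overlap
        but never cover exonic sequence."""
        coords = {
            "exonStart_0base": 2000, "exonEnd": 2100,
            "upstreamES": 1000, "upstreamEE": 1700,  # intron 1700-2000 (300 nt)
            "downstreamES": 2400, "downstreamEE": 2600,  # intron 2100-2400 (300 nt)
        }
        ws = build_windows(make_event("SE", coords))
        intronic = [w for w in ws
                    if "intron" in w.role]
        assert len(intronic) == 4
        for w in intronic:
            assert (1700 <= w.start and w.end <= 2000) or (2100 <= w.start and w.end <= 2400)

    def test_strand_mirror_symmetry(self):
        """Mirroring the event through a pivot and flipping strand yields
        the mirrored window set with swapped upstream/downstream roles."""
        rng = np.random.default_rng(12)
        pivot = 1_000_000
        for _ in range(60):
            ev = random_event(rng)
            mirrored_coords = {}
            c = ev.coords
            pairs = {
                "SE": [("exonStart_0base", "exonEnd"), ("upstreamES", "upstreamEE"),
                       ("downstreamES", "downstreamEE")],
                "MXE": [("1stExonStart_0base", "1stExonEnd"),
                        ("2ndExonStart_0base", "2ndExonEnd"),
                        ("upstreamES", "upstreamEE"), ("downstreamES", "downstreamEE")],
                "A5SS": [("longExonStart_0base", "longExonEnd"), ("shortES", "shortEE"),
                         ("flankingES", "flankingEE")],
                "A3SS": [("longExonStart_0base", "longExonEnd"), ("shortES", "shortEE"),
                         ("flankingES", "flankingEE")],
                "RI": [("riExonStart_0base", "riExonEnd"), ("upstreamES", "upstreamEE"),
                       ("downstreamES", "downstreamEE")],
            }[ev.event_type]
            for skey, ekey in pairs:
                mirrored_coords[skey] = pivot - c[ekey]
                mirrored_coords[ekey] = pivot - c[skey]
            flipped = make_event(ev.event_type, mirrored_coords,
                                 strand="-" if ev.strand == "+" else "+",
                                 chrom=ev.chrom)
            # multisets of (interval, role): in a short intron the two
            # opposing windows can clip to the same genomic interval
            orig = sorted((w.start, w.end, w.role) for w in build_windows(ev))
            mirr = sorted((pivot - w.end, pivot - w.start, w.role)
                          for w in build_windows(flipped))
            assert orig == mirr

    def test_missing_flank_raises(self):
        bad = dict(SE_COORDS)
        bad["downstreamES"] = bad["upstreamES"]  # out of order
        bad["downstreamEE"] = bad["upstreamEE"]
        with pytest.raises(WindowError):
            build_windows(make_event("SE", bad))


class TestClassifyBound:
    def test_cluster_on_alt_exon(self):
        ev = make_event("SE", SE_COORDS)
        call = classify_bound(ev, [ClipCluster("chrT", 2050, 2060, "+")])
        assert call.bound and call.hit_roles == ["alt_exon"]

    def test_disjoint_cluster_not_bound(self):
        ev = make_event("SE", SE_COORDS)
        assert not classify_bound(ev, [ClipCluster("chrT", 5000, 5100, "+")]).bound

    def test_wrong_strand_not_bound(self):
        ev = make_event("SE", SE_COORDS, strand="+")
        assert not classify_bound(ev, [ClipCluster("chrT", 2050, 2060, "-")]).bound

    def test_agrees_with_brute_force_on_random_pairs(self):
        """1,000 random (event, cluster) pairs: classification equals
        all-pairs interval overlap against the oracle enumerator."""
        rng = np.random.default_rng(31)
        for _ in range(1000):
            ev = random_event(rng)
            lo = min(v for v in ev.coords.values())
            hi = max(v for v in ev.coords.values())
            start = int(rng.integers(max(0, lo - 1500), hi + 1500))
            cl = ClipCluster(ev.chrom, start, start + int(rng.integers(5, 80)),
                             ev.strand if rng.random() < 0.8 else
                             ("-" if ev.strand == "+" else "+"))
            got = classify_bound(ev, [cl]).bound
            expected = cl.strand == ev.strand and any(
                cl.start < e and s < cl.end for s, e in oracle_windows(ev)
            )
            assert got == expected, (ev.event_type, ev.strand, ev.coords, cl)
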