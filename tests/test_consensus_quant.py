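import math

import numpy as np
import pytest

from repchip.consensus_quant import (
    ConsensusRegion,
    background_rpkms,
    build_consensus,
    dabg,
    dabg_screen,
    quantify,
    reference_regions,
    rpkm,
)
from repchip.replicate_overlap import PeakGroup
from tests.conftest import make_peak, make_read

SIZES = {"chr1": 1_000_000}


def group_of(*peaks, n_replicates=2, gid="g0"):
    support = {p.replicate_id or f"r{i}" for i, p in enumerate(peaks)}
    return PeakGroup(group_id=gid, members=list(peaks), support=support,
                     n_replicates=n_replicates)


class TestBuildConsensus:
    def test_max_is_span(self):
        g = group_of(make_peak(100, 200, rep="A"), make_peak(150, 300, rep="B"))
        r = build_consensus(g, "MAX", SIZES)
        assert (r.start, r.end) == (100, 300)

    def test_smt_between_summits_inclusive(self):
        g = group_of(
            make_peak(100, 200, summit=150, rep="A"),
            make_peak(200, 300, summit=250, rep="B"),
        )
        r = build_consensus(g, "SMT", SIZES)
        assert (r.start, r.end) == (150, 251)
        assert r.avg_summit == 200

    def test_smt_minimum_width_widening(self):
        g = group_of(
            make_peak(90, 130, summit=100, rep="A"),
            make_peak(95, 140, summit=110, rep="B"),
        )
        r = build_consensus(g, "SMT", SIZES, min_width=50)
        assert r.end - r.start == 50
        # symmetric widening of [100, 111)
        assert (r.start, r.end) == (81, 131)

    def test_asf_footprint_around_average_summit(self):
        g = group_of(
            make_peak(100, 200, summit=150, rep="A"),
            make_peak(200, 300, summit=250, rep="B"),
        )
        r = build_consensus(g, "ASF", SIZES, footprint=100)
        assert (r.start, r.end) == (150, 250)
        assert r.avg_summit == 200
        assert r.width == 100

    def test_asw_uses_average_width(self):
        g = group_of(
            make_peak(100, 200, summit=150, rep="A"),
            make_peak(200, 300, summit=250, rep="B"),
        )
        r = build_consensus(g, "ASW", SIZES, avg_width=151)
        assert r.width == 151
        assert r.avg_summit == 200

    def test_smt_within_max_before_widening(self, rng):
        for _ in range(20):
            s1, s2 = sorted(int(x) for x in rng.integers(1000, 2000, 2))
            g = group_of(
                make_peak(s1 - 10, s1 + 50, summit=s1, rep="A"),
                make_peak(s2 - 50, s2 + 10, summit=s2, rep="B"),
            )
            smt = build_consensus(g, "SMT", SIZES, min_width=1)
            mx = build_consensus(g, "MAX", SIZES)
            assert mx.start <= smt.start and smt.end <= mx.end

    def test_summit_fallback_to_midpoint(self):
        g = group_of(make_peak(100, 200, rep="A"), make_peak(100, 200, rep="B"))
        r = build_consensus(g, "SMT", SIZES, min_width=1)
        assert r.avg_summit == 150

    def test_clipping_at_chromosome_start(self):
        g = group_of(make_peak(0, 60, summit=10, rep="A"), make_peak(5, 60, summit=10, rep="B"))
        r = build_consensus(g, "ASF", SIZES, footprint=100)
        assert r.start == 0
        assert r.end == 60  # 10 + ceil(100/2)

    def test_unknown_chromosome_error(self):
        g = group_of(make_peak(0, 60, chrom="chrX", rep="A"))
        with pytest.raises(ValueError, match="chromosome"):
            build_consensus(g, "MAX", SIZES)

    def test_clip_to_empty_error(self):
        g = group_of(make_peak(150, 200, rep="A"))
        with pytest.raises(ValueError, match="clip"):
            build_consensus(g, "MAX", {"chr1": 100})

    def test_asf_requires_footprint(self):
        g = group_of(make_peak(0, 60, summit=10, rep="A"))
        with pytest.raises(ValueError):
            build_consensus(g, "ASF", SIZES)


class TestReferenceRegions:
    def test_deepest_replicate_wins(self):
        sets = {"A": [make_peak(0, 100)], "B": [make_peak(500, 600), make_peak(700, 800)]}
        regions = reference_regions(sets, {"A": 10_000_000, "B": 12_000_000})
        assert [(r.start, r.end) for r in regions] == [(500, 600), (700, 800)]
        assert all(r.method == "REF" for r in regions)

    def test_tie_breaks_lexicographically(self):
        sets = {"B": [make_peak(500, 600)], "A": [make_peak(0, 100)]}
        regions = reference_regions(sets, {"A": 5, "B": 5})
        assert [(r.start, r.end) for r in regions] == [(0, 100)]

    def test_single_replicate(self):
        sets = {"A": [make_peak(0, 100)]}
        regions = reference_regions(sets, {"A": 5})
        assert len(regions) == 1


class TestQuantify:
    def test_rpkm_worked_example(self):
        # 100 reads in a 500 bp region, 20M mapped -> 10.0
        assert rpkm(100, 500, 20_000_000) == pytest.approx(10.0)
        region = ConsensusRegion("g0", "MAX", "chr1", 1000, 1500)
        reads = [make_read(1000 + 4 * i, 1036 + 4 * i) for i in range(100)]
        m = quantify([region], {"A": reads}, {"A": 20_000_000})
        assert m.values[0, 0] == pytest.approx(10.0)

    def test_zero_overlap_is_zero(self):
        region = ConsensusRegion("g0", "MAX", "chr1", 1000, 1500)
        m = quantify([region], {"A": [make_read(0, 36)]}, {"A": 1000})
        assert m.values[0, 0] == 0.0

    def test_scale_invariance(self):
        region = ConsensusRegion("g0", "MAX", "chr1", 0, 500)
        reads = [make_read(10 * i, 10 * i + 36) for i in range(40)]
        m1 = quantify([region], {"A": reads}, {"A": 1_000_000})
        m2 = quantify([region], {"A": reads + reads}, {"A": 2_000_000})
        assert m1.values[0, 0] == pytest.approx(m2.values[0, 0])

    def test_read_multicounted_across_overlapping_regions(self):
        regions = [
            ConsensusRegion("a", "MAX", "chr1", 100, 200),
            ConsensusRegion("b", "MAX", "chr1", 150, 250),
        ]
        m = quantify(regions, {"A": [make_read(140, 176)]}, {"A": 100})
        assert (m.values > 0).all()

    def test_boundary_read_not_counted(self):
        # read ending exactly at region start shares no base
        region = ConsensusRegion("g0", "MAX", "chr1", 100, 200)
        m = quantify([region], {"A": [make_read(64, 100), make_read(200, 236)]}, {"A": 10})
        assert m.values[0, 0] == 0.0

    def test_totals_default_to_read_counts(self):
        region = ConsensusRegion("g0", "MAX", "chr1", 0, 1000)
        reads = [make_read(i, i + 36) for i in range(10)]
        m = quantify([region], {"A": reads})
        assert m.total_mapped == {"A": 10}

    def test_to_frame_shape(self):
        regions = [ConsensusRegion(f"g{i}", "MAX", "chr1", i * 100, i * 100 + 50)
                   for i in range(3)]
        m = quantify(regions, {"A": [make_read(0, 36)], "B": [make_read(120, 156)]})
        df = m.to_frame()
        assert list(df.columns) == ["group_id", "chrom", "start", "end", "A", "B"]
        assert len(df) == 3


class TestDabg:
    def test_target_at_background_mean(self):
        res = dabg(1.5, [1.0, 1.0, 2.0, 2.0])
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)
        assert not res.detected

    def test_worked_example(self):
        # bg mean 1.5, sample sd sqrt(1/3); z = 1.5/sqrt(1/3) = 2.598
        res = dabg(3.0, [1.0, 1.0, 2.0, 2.0])
        assert res.z == pytest.approx(1.5 / math.sqrt(1 / 3), abs=1e-9)
        assert res.z == pytest.approx(2.598, abs=1e-3)
        # one-sided normal tail via the complementary error function
        expected_p = 0.5 * math.erfc(res.z / math.sqrt(2))
        assert res.p == pytest.approx(expected_p, abs=1e-12)
        assert res.p == pytest.approx(0.0047, abs=5e-4)
        assert res.detected

    def test_alpha_zero_never_detects(self):
        res = dabg(100.0, [1.0, 1.0, 2.0, 2.0], alpha=0.0)
        assert not res.detected

    def test_small_background_error(self):
        with pytest.raises(ValueError):
            dabg(1.0, [1.0, 2.0])

    def test_zero_spread_error(self):
        with pytest.raises(ValueError, match="spread|widen"):
            dabg(1.0, [2.0, 2.0, 2.0, 2.0])

    def test_monotone_in_target(self, rng):
        bg = rng.lognormal(0, 0.5, 20)
        targets = np.sort(rng.uniform(0, 5, 10))
        zs = [dabg(t, bg).z for t in targets]
        assert all(a <= b + 1e-12 for a, b in zip(zs, zs[1:]))

    def test_background_strictly_below_quartile(self):
        values = np.arange(1.0, 101.0)
        bg = background_rpkms(values)
        q25 = np.percentile(values, 25)
        assert (bg < q25).all()
        assert len(bg) == 25  # values 1..25 are below 25.75


class TestDabgScreen:
    def make_setup(self):
        peaks_a = [make_peak(100, 300, rep="A")]
        peaks_b = [make_peak(120, 320, rep="B")]
        group = PeakGroup("g0", peaks_a + peaks_b, {"A", "B"}, n_replicates=3)
        missing_group = PeakGroup("g1", [make_peak(5000, 5200, rep="A")], {"A"}, 3)
        regions = [
            ConsensusRegion("g0", "MAX", "chr1", 100, 320),
            ConsensusRegion("g1", "MAX", "chr1", 5000, 5200),
        ]
        reads = {lab: [make_read(150 + i, 186 + i) for i in range(20)] for lab in "ABC"}
        matrix = quantify(regions, reads)
        rpkms = {lab: list(np.linspace(1, 30, 20)) for lab in "ABC"}
        return [group, missing_group], matrix, rpkms

    def test_supported_replicates_not_tested(self):
        groups, matrix, rpkms = self.make_setup()
        results = dabg_screen(groups, matrix, rpkms)
        tested = {(r.group_id, r.replicate_id) for r in results}
        assert ("g0", "A") not in tested and ("g0", "B") not in tested
        assert ("g0", "C") in tested
        assert ("g1", "B") in tested and ("g1", "C") in tested

    def test_small_background_replicate_skipped(self):
        groups, matrix, rpkms = self.make_setup()
        rpkms["C"] = [1.0, 2.0]  # < 12 called peaks
        results = dabg_screen(groups, matrix, rpkms)
        assert all(r.replicate_id != "C" for r in results)

    def test_threshold_rule(self):
        groups, matrix, rpkms = self.make_setup()
        results = dabg_screen(groups, matrix, rpkms, rule="threshold")
        for r in results:
            q25 = np.percentile(rpkms[r.replicate_id], 25)
            assert r.detected == (r.rpkm > q25)

    def test_unknown_rule_error(self):
        groups, matrix, rpkms = self.make_setup()
        with pytest.raises(ValueError):
            dabg_screen(groups, matrix, rpkms, rule="bogus")
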