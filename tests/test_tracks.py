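"""Track parsing, P-site shifting, rpm normalization, and region counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ribopeak as rp
from ribopeak.annotation import GeneModel
from ribopeak.tracks import (
    DensityTrack,
    TrackError,
    count_region,
    normalize_rpm,
    read_track,
    shift_psite,
    split_count,
    write_track,
)

LENGTHS = {"chrI": 400, "chrII": 200}


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTrack:
    def test_bedgraph_interval_semantics(self, tmp_path):
        plus = _write(tmp_path, "p.bg", "chrI\t9\t12\t4\n")
        minus = _write(tmp_path, "m.bg", "")
        t = read_track(plus, minus, "rnaseq", LENGTHS)
        assert t.data["chrI"]["+"][9] == 4
        assert t.data["chrI"]["+"][11] == 4
        assert t.data["chrI"]["+"][12] == 0
        assert t.total_mapped == 12.0  # no header: sum of counts

    def test_variable_step_is_one_based(self, tmp_path):
        plus = _write(tmp_path, "p.wig", "variableStep chrom=chrI span=1\n10\t7\n")
        minus = _write(tmp_path, "m.bg", "")
        t = read_track(plus, minus, "ribo40S", LENGTHS)
        assert t.data["chrI"]["+"][9] == 7

    def test_fixed_step_with_span(self, tmp_path):
        plus = _write(tmp_path, "p.wig", "fixedStep chrom=chrI start=11 step=3 span=2\n1\n2\n")
        minus = _write(tmp_path, "m.bg", "")
        t = read_track(plus, minus, "ribo40S", LENGTHS)
        arr = t.data["chrI"]["+"]
        assert arr[10] == 1 and arr[11] == 1
        assert arr[13] == 2 and arr[14] == 2

    def test_total_mapped_headers_sum_across_strands(self, tmp_path):
        plus = _write(tmp_path, "p.bg", "#total_mapped=600000\nchrI\t0\t1\t1\n")
        minus = _write(tmp_path, "m.bg", "#total_mapped=400000\nchrI\t5\t6\t1\n")
        t = read_track(plus, minus, "rnaseq", LENGTHS)
        assert t.total_mapped == 1_000_000

    def test_overlapping_bedgraph_intervals_fatal(self, tmp_path):
        plus = _write(tmp_path, "p.bg", "chrI\t0\t10\t1\nchrI\t5\t15\t2\n")
        minus = _write(tmp_path, "m.bg", "")
        with pytest.raises(TrackError, match="overlap"):
            read_track(plus, minus, "rnaseq", LENGTHS)

    def test_negative_values_fatal(self, tmp_path):
        plus = _write(tmp_path, "p.bg", "chrI\t0\t10\t-1\n")
        minus = _write(tmp_path, "m.bg", "")
        with pytest.raises(TrackError, match="negative"):
            read_track(plus, minus, "rnaseq", LENGTHS)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        track = DensityTrack(
            "ribo40S",
            {c: {s: np.round(rng.poisson(0.3, n).astype(float)) for s in "+-"}
             for c, n in LENGTHS.items()},
            "raw",
        )
        track.total_mapped = track.total_counts()
        write_track(track, tmp_path / "p.bg", tmp_path / "m.bg")
        back = read_track(tmp_path / "p.bg", tmp_path / "m.bg", "ribo40S", LENGTHS)
        for c in LENGTHS:
            for s in "+-":
                np.testing.assert_array_equal(back.data[c][s], track.data[c][s])
        assert back.total_mapped == track.total_mapped


class TestShiftPsite:
    def _track(self):
        data = {"chrI": {"+": np.zeros(400), "-": np.zeros(400)}}
        data["chrI"]["+"][100] = 3
        data["chrI"]["-"][200] = 5
        return DensityTrack("ribo40S", data, "raw", 8.0)

    def test_plus_strand_moves_downstream(self):
        t = shift_psite(self._track(), 13)
        assert t.data["chrI"]["+"][113] == 3
        assert t.data["chrI"]["+"][100] == 0

    def test_minus_strand_mirrors(self):
        t = shift_psite(self._track(), 13)
        assert t.data["chrI"]["-"][187] == 5

    def test_offset_zero_is_identity(self):
        t0 = self._track()
        t = shift_psite(t0, 0)
        np.testing.assert_array_equal(t.data["chrI"]["+"], t0.data["chrI"]["+"])

    def test_double_shift_fatal(self):
        t = shift_psite(self._track(), 13)
        with pytest.raises(TrackError, match="already"):
            shift_psite(t, 13)

    def test_edge_counts_dropped(self):
        data = {"chrI": {"+": np.zeros(400), "-": np.zeros(400)}}
        data["chrI"]["+"][395] = 2  # would land at 408
        data["chrI"]["-"][5] = 3  # would land at -8
        t = shift_psite(DensityTrack("ribo40S", data, "raw", 5.0), 13)
        assert t.total_counts() == 0

    @settings(max_examples=25, deadline=None)
    @given(
        positions=st.lists(st.integers(0, 399), min_size=1, max_size=30),
        offset=st.integers(0, 20),
        strand=st.sampled_from("+-"),
    )
    def test_matches_per_read_shift_oracle(self, positions, offset, strand):
        """Array shifting equals shifting each read individually."""
        data = {"chrI": {"+": np.zeros(400), "-": np.zeros(400)}}
        for p in positions:
            data["chrI"][strand][p] += 1
        shifted = shift_psite(DensityTrack("x", data, "raw", len(positions)), offset)
        oracle = np.zeros(400)
        for p in positions:
            q = p + offset if strand == "+" else p - offset
            if 0 <= q < 400:
                oracle[q] += 1
        np.testing.assert_array_equal(shifted.data["chrI"][strand], oracle)


class TestNormalizeRpm:
    def test_scaling(self):
        data = {"chrI": {"+": np.zeros(400), "-": np.zeros(400)}}
        data["chrI"]["+"][0] = 4
        t = DensityTrack("rnaseq", data, "raw", 2_000_000)
        r = normalize_rpm(t)
        assert r.data["chrI"]["+"][0] == pytest.approx(2.0)
        assert r.units == "rpm"

    def test_genome_wide_sum_conserved_to_one_million(self):
        rng = np.random.default_rng(1)
        data = {c: {s: rng.poisson(2.0, n).astype(float) for s in "+-"} for c, n in LENGTHS.items()}
        t = DensityTrack("rnaseq", data, "raw")
        t.total_mapped = t.total_counts()
        r = normalize_rpm(t)
        assert r.total_counts() == pytest.approx(1e6, rel=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        base = {c: {s: rng.poisson(2.0, n).astype(float) for s in "+-"} for c, n in LENGTHS.items()}
        t1 = DensityTrack("rnaseq", {c: {s: a.copy() for s, a in d.items()} for c, d in base.items()}, "raw")
        t1.total_mapped = t1.total_counts()
        t2 = DensityTrack("rnaseq", {c: {s: 3.0 * a for s, a in d.items()} for c, d in base.items()}, "raw")
        t2.total_mapped = t2.total_counts()
        for c in LENGTHS:
            for s in "+-":
                np.testing.assert_allclose(
                    normalize_rpm(t1).data[c][s], normalize_rpm(t2).data[c][s]
                )

    def test_empty_library_fatal(self):
        t = DensityTrack("rnaseq", {"chrI": {"+": np.zeros(10), "-": np.zeros(10)}}, "raw", 0.0)
        with pytest.raises(TrackError, match="total_mapped"):
            normalize_rpm(t)


def _uniform_track(value=1.0, contig_len=5000, total=None):
    data = {"chrI": {"+": np.full(contig_len, value), "-": np.full(contig_len, value)}}
    t = DensityTrack("rnaseq", data, "raw")
    t.total_mapped = total if total is not None else t.total_counts()
    return t


class TestCountRegion:
    GENE = GeneModel("G", "chrI", "+", 1000, 2000, utr5_len=60, utr3_len=90)

    def test_orf_rpkm(self):
        # 1000-nt ORF with 50 rpm mapped -> 50 rpkm
        data = {"chrI": {"+": np.zeros(5000), "-": np.zeros(5000)}}
        data["chrI"]["+"][1000:2000] = 0.05  # rpm units
        t = DensityTrack("rnaseq", data, "rpm", 1_000_000)
        rc = count_region(t, self.GENE, "orf")
        assert rc.rpm == pytest.approx(50.0)
        assert rc.rpkm == pytest.approx(50.0)

    def test_below_expression_threshold_flagged(self):
        data = {"chrI": {"+": np.zeros(5000), "-": np.zeros(5000)}}
        data["chrI"]["+"][1000:2000] = 0.0049
        t = DensityTrack("rnaseq", data, "rpm", 1_000_000)
        rc = count_region(t, self.GENE, "orf")
        assert rc.rpkm == pytest.approx(4.9)
        assert "below_threshold" in rc.flags

    def test_empty_region_counts_zero(self):
        t = _uniform_track(0.0, total=1000)
        rc = count_region(t, self.GENE, "orf")
        assert rc.raw == 0 and rc.rpkm == 0

    def test_spliced_orf_excludes_introns_additively(self):
        gene = GeneModel("G", "chrI", "+", 1000, 2000, introns=((1200, 1350), (1600, 1650)))
        t = _uniform_track(1.0)
        whole = count_region(t, gene, "whole_orf_interval")
        spliced = count_region(t, gene, "orf")
        intron = count_region(t, gene, "intron")
        assert spliced.raw + intron.raw == whole.raw
        assert spliced.length == 800 and intron.length == 200

    def test_upstream_window_uniform_coverage(self):
        t = _uniform_track(1.0)
        rc = count_region(t, self.GENE, "upstream200")
        assert rc.raw == 200

    def test_upstream_window_truncated_at_contig_edge(self):
        gene = GeneModel("G", "chrI", "+", 50, 350)
        t = _uniform_track(1.0)
        rc = count_region(t, gene, "upstream200")
        assert rc.raw == 50
        assert "truncated" in rc.flags

    def test_minus_strand_uses_minus_array(self):
        data = {"chrI": {"+": np.zeros(5000), "-": np.zeros(5000)}}
        data["chrI"]["-"][1000:2000] = 2.0
        t = DensityTrack("rnaseq", data, "raw", 4000)
        gene = GeneModel("G", "chrI", "-", 1000, 2000)
        assert count_region(t, gene, "orf").raw == 2000


class TestSplitCount:
    def _track_with(self, first_cov, last_cov, gene):
        data = {"chrI": {"+": np.zeros(5000), "-": np.zeros(5000)}}
        pos = gene.spliced_positions()
        data["chrI"][gene.strand][pos[:100]] = first_cov
        data["chrI"][gene.strand][pos[-100:]] = last_cov
        t = DensityTrack("rnaseq", data, "raw")
        t.total_mapped = max(t.total_counts(), 1.0)
        return t

    GENE = GeneModel("G", "chrI", "+", 1000, 1300)

    def test_positive_above_twofold(self):
        sc = split_count(self._track_with(0.1, 0.25, self.GENE), self.GENE)
        assert sc.first == pytest.approx(10) and sc.last == pytest.approx(25)
        assert sc.ratio == pytest.approx(2.5)
        assert sc.is_split_positive

    def test_boundary_ratio_two_is_negative(self):
        sc = split_count(self._track_with(0.1, 0.2, self.GENE), self.GENE)
        assert sc.ratio == pytest.approx(2.0)
        assert not sc.is_split_positive

    def test_zero_denominator_guard(self):
        sc = split_count(self._track_with(0.0, 0.12, self.GENE), self.GENE)
        assert np.isnan(sc.ratio)
        assert "ratio_undefined" in sc.flags
        assert sc.is_split_positive  # 12 >= 10 informative reads
        sc2 = split_count(self._track_with(0.0, 0.05, self.GENE), self.GENE)
        assert not sc2.is_split_positive  # 5 < 10

    def test_short_orf_untestable(self):
        gene = GeneModel("G", "chrI", "+", 1000, 1150)
        sc = split_count(_uniform_track(1.0), gene)
        assert "untestable" in sc.flags
        assert not sc.is_split_positive

    def test_ratio_invariant_under_rpm_normalization(self):
        t = self._track_with(0.1, 0.37, self.GENE)
        sc_raw = split_count(t, self.GENE)
        sc_rpm = split_count(normalize_rpm(t), self.GENE)
        assert sc_rpm.ratio == pytest.approx(sc_raw.ratio)
        assert sc_rpm.is_split_positive == sc_raw.is_split_positive

    def test_minus_strand_windows_follow_transcript_orientation(self):
        gene = GeneModel("G", "chrI", "-", 1000, 1300)
        data = {"chrI": {"+": np.zeros(5000), "-": np.zeros(5000)}}
        # transcript-first 100 nt of a minus gene are genomic 1200..1300
        data["chrI"]["-"][1000:1100] = 0.3  # transcript-LAST window
        t = DensityTrack("rnaseq", data, "raw")
        t.total_mapped = t.total_counts()
        sc = split_count(t, gene)
        assert sc.first == 0 and sc.last == pytest.approx(30)
        assert sc.is_split_positive
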