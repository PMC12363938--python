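"""Motif scanning, pause scores, peak heights, calling rules, curation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ribopeak as rp
from ribopeak.annotation import GeneModel, build_extended_leader, revcomp
from ribopeak.peaks import (
    Peak,
    apply_curation,
    call_leader_peaks,
    call_orf_peaks,
    detect_main_start_peak,
    is_surviving,
    pause_score,
    peak_height,
    scan_motifs,
    surviving,
)
from ribopeak.tracks import DensityTrack

CONTIG_LEN = 6000


def _track(values_at=None, uniform=0.0, shift=13):
    data = {"chrI": {"+": np.full(CONTIG_LEN, float(uniform)),
                     "-": np.full(CONTIG_LEN, float(uniform))}}
    for (strand, pos), v in (values_at or {}).items():
        data["chrI"][strand][pos] = v
    t = DensityTrack("ribo40S", data, "rpm", 1e6)
    t.psite_shift_applied = shift
    return t


def _gene_with_seq(leader_seq, orf_seq, strand="+", utr5_len=None):
    """Build a single-gene toy genome with the given leader/ORF sequences."""
    pad = 2000
    forward_tx = leader_seq + orf_seq
    if strand == "+":
        genome_seq = "C" * pad + forward_tx + "C" * (CONTIG_LEN - pad - len(forward_tx))
        orf_start = pad + len(leader_seq)
        orf_end = orf_start + len(orf_seq)
    else:
        genome_seq = "C" * pad + revcomp(forward_tx) + "C" * (CONTIG_LEN - pad - len(forward_tx))
        orf_start = pad + 0 if False else pad + 0
        orf_start = pad
        orf_end = pad + len(orf_seq)
    gene = GeneModel("G", "chrI", strand, orf_start, orf_end,
                     utr5_len=len(leader_seq) if utr5_len is None else utr5_len)
    genome = {"chrI": genome_seq}
    leader = build_extended_leader(gene, [gene], len(leader_seq), CONTIG_LEN)
    return gene, genome, leader


class TestScanMotifs:
    def test_leader_scan_matches_string_oracle(self):
        # AUGGCAUGA ending just before the main start holds AUGs at -9 and -4
        leader_seq = "C" * 51 + "ATGGCATGA"
        gene, genome, leader = _gene_with_seq(leader_seq, "ATG" + "CCG" * 30 + "TAA")
        hits = scan_motifs(genome, gene, leader, motifs=("start",), regions=("leader",))
        offs = sorted(h.offset for h in hits)
        oracle = sorted(i - len(leader_seq) for i in range(len(leader_seq) - 2)
                        if leader_seq[i:i + 3] == "ATG")
        assert offs == oracle == [-9, -4]
        assert {h.frame for h in hits} == {(-9) % 3, (-4) % 3}

    def test_minus_strand_reads_transcript_orientation(self):
        leader_seq = "C" * 20 + "ATG" + "C" * 7
        gene, genome, leader = _gene_with_seq(leader_seq, "ATG" + "GGC" * 20 + "TAA", strand="-")
        hits = scan_motifs(genome, gene, leader, motifs=("start",), regions=("leader",))
        assert [h.offset for h in hits] == [-10]
        # the genomic base at the hit is the forward-strand complement (T of CAT)
        assert genome["chrI"][hits[0].genomic_pos] == "T"

    def test_orf_scan_excludes_annotated_start(self):
        gene, genome, leader = _gene_with_seq("C" * 30, "ATG" + "CCG" * 20 + "TAA")
        hits = scan_motifs(genome, gene, leader, motifs=("start",), regions=("orf",))
        assert hits == []

    def test_internal_augs_found_with_frames(self):
        orf = "ATG" + "CCG" * 10 + "ATG" + "CC" + "ATG" + "CCGCC" + "TAA"
        gene, genome, leader = _gene_with_seq("C" * 30, orf)
        hits = scan_motifs(genome, gene, leader, motifs=("start",), regions=("orf",))
        assert [(h.offset, h.frame) for h in hits] == [(33, 0), (38, 2)]

    def test_no_adenine_no_motifs(self):
        gene, genome, leader = _gene_with_seq("CGT" * 20, "ATG" + "CCG" * 10 + "TAA")
        hits = scan_motifs(genome, gene, leader, motifs=("start",), regions=("leader",))
        assert hits == []

    def test_ambiguous_bases_never_match(self):
        gene, genome, leader = _gene_with_seq("C" * 27 + "ANG", "ATG" + "CCG" * 10 + "TAA")
        hits = scan_motifs(genome, gene, leader, motifs=("start",), regions=("leader",))
        assert hits == []

    def test_stop_motifs_on_request(self):
        leader_seq = "C" * 20 + "TAA" + "C" * 4 + "TGA"
        gene, genome, leader = _gene_with_seq(leader_seq, "ATG" + "CCG" * 10 + "TAA")
        hits = scan_motifs(genome, gene, leader, motifs=("stop",), regions=("leader",))
        assert sorted((h.offset, h.motif) for h in hits) == [(-10, "stop_UAA"), (-3, "stop_UGA")]


class TestPauseScore:
    def test_uniform_track_scores_one(self):
        for c in (0.01, 1.0, 250.0):
            assert pause_score(_track(uniform=c), "chrI", "+", 3000) == pytest.approx(1.0)

    def test_isolated_spike(self):
        t = _track({("+", 3000): 100.0})
        assert pause_score(t, "chrI", "+", 3000) == pytest.approx(101.0)

    def test_zero_at_position_scores_zero(self):
        t = _track({("+", 3010): 5.0}, uniform=0.0)
        assert pause_score(t, "chrI", "+", 3000) == pytest.approx(0.0)

    def test_all_zero_window_is_nan(self):
        assert np.isnan(pause_score(_track(), "chrI", "+", 3000))

    def test_scale_invariance(self):
        t1 = _track({("+", 3000): 7.0, ("+", 3020): 2.0}, uniform=0.5)
        t2 = _track({("+", 3000): 70.0, ("+", 3020): 20.0}, uniform=5.0)
        assert pause_score(t1, "chrI", "+", 3000) == pytest.approx(
            pause_score(t2, "chrI", "+", 3000)
        )

    def test_exclusive_window_variant(self):
        t = _track({("+", 3000): 100.0}, uniform=0.0)
        assert np.isnan(pause_score(t, "chrI", "+", 3000, include_center=False))
        t2 = _track({("+", 3000): 100.0}, uniform=1.0)
        assert pause_score(t2, "chrI", "+", 3000, include_center=False) == pytest.approx(100.0)


class TestPeakHeight:
    def test_five_nt_window_per_kb(self):
        t = _track({("+", 3000): 0.5})
        h, truncated = peak_height(t, "chrI", "+", 3000)
        assert h == pytest.approx(100.0)  # 0.5 rpm / 0.005 kb
        assert not truncated

    def test_all_zero_window(self):
        h, _ = peak_height(_track(), "chrI", "+", 3000)
        assert h == 0.0

    def test_linearity(self):
        t1 = _track({("+", 3000): 0.4, ("+", 3001): 0.2})
        t2 = _track({("+", 3000): 0.8, ("+", 3001): 0.4})
        h1, _ = peak_height(t1, "chrI", "+", 3000)
        h2, _ = peak_height(t2, "chrI", "+", 3000)
        assert h2 == pytest.approx(2 * h1)

    def test_truncation_at_contig_edge(self):
        t = _track({("+", 0): 0.5})
        h, truncated = peak_height(t, "chrI", "+", 0)
        assert truncated
        assert h == pytest.approx(0.5 / 0.003)  # 3-nt effective window


def _leader_gene(height, frame0_no_stop=False):
    """Gene with one leader AUG at -60; optionally frame-0 with no stop."""
    if frame0_no_stop:
        leader_seq = "C" * 40 + "ATG" + "C" * 57  # -60, frame 0, no stop before start
    else:
        leader_seq = "C" * 40 + "ATG" + "C" * 3 + "TAA" + "C" * 51  # in-frame stop at -54
    orf = "ATG" + "CCG" * 40 + "TAA"
    gene, genome, leader = _gene_with_seq(leader_seq, orf)
    aug_pos = gene.orf_start - 60
    track = _track({("+", aug_pos): height / 200.0})
    return gene, genome, leader, track


class TestCallLeaderPeaks:
    def test_called_strictly_above_92(self, thresholds):
        gene, genome, leader, track = _leader_gene(93.0)
        got = surviving(call_leader_peaks(gene, leader, track, genome, thresholds))
        assert len(got) == 1 and got[0].distance_to_main_start == -60

    def test_boundary_92_not_called(self, thresholds):
        gene, genome, leader, track = _leader_gene(92.0)
        peaks = call_leader_peaks(gene, leader, track, genome, thresholds)
        assert surviving(peaks) == []
        assert any("below_threshold" in p.flags for p in peaks)

    def test_frame0_without_stop_is_misannotated_start(self, thresholds):
        gene, genome, leader, track = _leader_gene(500.0, frame0_no_stop=True)
        peaks = call_leader_peaks(gene, leader, track, genome, thresholds)
        assert len(peaks) == 1
        assert "frame0_misannotated_start" in peaks[0].flags
        assert surviving(peaks) == []

    def test_frame0_with_stop_survives(self, thresholds):
        gene, genome, leader, track = _leader_gene(500.0)
        got = surviving(call_leader_peaks(gene, leader, track, genome, thresholds))
        assert len(got) == 1 and got[0].frame == 0

    def test_score_recorded_but_not_gating(self, thresholds):
        # a broad plateau gives score ~1 yet the peak is still called on height
        gene, genome, leader, _ = _leader_gene(500.0)
        aug_pos = gene.orf_start - 60
        track = _track(uniform=500.0 / 200.0)
        got = surviving(call_leader_peaks(gene, leader, track, genome, thresholds))
        assert len(got) == 1
        assert got[0].score == pytest.approx(1.0)


def _orf_gene(height, uniform=0.0, adjacent_stop=False):
    """Gene with one internal AUG at +45 (frame 0 avoided: +46)."""
    if adjacent_stop:
        body = "CCG" * 14 + "C" + "ATG" + "TGA" + "CCG" * 24  # AUG at +46 then stop
    else:
        body = "CCG" * 14 + "C" + "ATG" + "CGC" + "CCG" * 24
    orf = "ATG" + body + "TAA"
    gene, genome, leader = _gene_with_seq("C" * 30, orf)
    aug_pos = gene.orf_start + 46
    track = _track({("+", aug_pos): height / 200.0, ("+", aug_pos + 30): uniform})
    return gene, genome, track


class TestCallOrfPeaks:
    def test_called_when_score_and_height_pass(self, thresholds):
        gene, genome, track = _orf_gene(140.0)
        got = surviving(call_orf_peaks(gene, track, genome, thresholds))
        assert len(got) == 1
        assert got[0].distance_to_main_start == 46
        assert got[0].frame == 1

    def test_height_conjunct_fails(self, thresholds):
        gene, genome, track = _orf_gene(100.0)  # score huge, height 100 < 137
        assert surviving(call_orf_peaks(gene, track, genome, thresholds)) == []

    def test_score_conjunct_fails(self, thresholds):
        # uniform background drives the pause score to ~1 despite a big height
        gene, genome, _ = _orf_gene(0)
        track = _track(uniform=1.0)
        peaks = call_orf_peaks(gene, track, genome, thresholds)
        assert all("below_threshold" in p.flags for p in peaks)

    def test_aug_adjacent_stop_excluded(self, thresholds):
        gene, genome, track = _orf_gene(500.0, adjacent_stop=True)
        peaks = call_orf_peaks(gene, track, genome, thresholds)
        assert any("aug_adjacent_stop" in p.flags for p in peaks)
        assert surviving(peaks) == []

    def test_frame0_internal_start_excluded(self, thresholds):
        orf = "ATG" + "CCG" * 15 + "ATG" + "CCG" * 24 + "TAA"  # internal AUG at +48, frame 0
        gene, genome, _ = _gene_with_seq("C" * 30, orf)
        track = _track({("+", gene.orf_start + 48): 500.0 / 200.0})
        peaks = call_orf_peaks(gene, track, genome, thresholds)
        assert len(peaks) == 1 and "frame0_internal_start" in peaks[0].flags
        assert surviving(peaks) == []


class TestMainStartPeak:
    @pytest.mark.parametrize("height,expected", [(150.0, True), (0.0, False), (92.0, False)])
    def test_threshold_strict(self, height, expected, thresholds):
        gene, genome, leader = _gene_with_seq("C" * 30, "ATG" + "CCG" * 20 + "TAA")
        track = _track({("+", gene.start_codon_pos): height / 200.0})
        present, got_height = detect_main_start_peak(gene, track, thresholds)
        assert present is expected
        assert got_height == pytest.approx(height)


class TestCuration:
    def _peaks(self):
        return [
            Peak("G1", 1000, "orf", "start_AUG", 1, 46, score=6.0, height=400.0,
                 flags=frozenset({"below_threshold"})),  # fails only the score conjunct
            Peak("G2", 2000, "leader", "start_AUG", 2, -40, score=20.0, height=300.0),
        ]

    def test_addback_bypasses_score_not_height(self, tmp_path, thresholds):
        allow = tmp_path / "allow.tsv"
        allow.write_text("G1\t1000\tadd\tscore denominator inflated by a neighbor peak\n")
        peaks, log = apply_curation(self._peaks(), allowlist=str(allow))
        assert "manual_add" in peaks[0].flags
        assert is_surviving(peaks[0], thresholds)  # height 400 > 137 still required
        assert any("manual_add" in line for line in log)

    def test_addback_height_conjunct_still_applies(self, tmp_path, thresholds):
        allow = tmp_path / "allow.tsv"
        allow.write_text("G1\t1000\tadd\t\n")
        low = [Peak("G1", 1000, "orf", "start_AUG", 1, 46, 6.0, 100.0,
                    frozenset({"below_threshold"}))]
        peaks, _ = apply_curation(low, allowlist=str(allow))
        assert not is_surviving(peaks[0], thresholds)

    def test_denylist_removes(self, tmp_path, thresholds):
        deny = tmp_path / "deny.tsv"
        deny.write_text("G2\t2000\tremove\tpeak on an upstream unannotated transcript\n")
        peaks, _ = apply_curation(self._peaks(), denylist=str(deny))
        assert "manual_remove" in peaks[1].flags
        assert not is_surviving(peaks[1], thresholds)

    def test_unmatched_entry_warned_and_ignored(self, tmp_path, caplog):
        deny = tmp_path / "deny.tsv"
        deny.write_text("NOPE\t1\tremove\t\n")
        import logging
        with caplog.at_level(logging.WARNING, logger="ribopeak.peaks"):
            peaks, log = apply_curation(self._peaks(), denylist=str(deny))
        assert peaks == self._peaks()
        assert any("ignored" in line for line in log)

    def test_empty_lists_identity(self):
        peaks, log = apply_curation(self._peaks())
        assert peaks == self._peaks() and log == []


class TestThresholdMonotonicity:
    @settings(max_examples=20, deadline=None)
    @given(
        d_height=st.floats(0, 300),
        d_score=st.floats(0, 20),
    )
    def test_raising_thresholds_never_adds_peaks(self, d_height, d_score, mini_fixture, shifted_40s):
        annotation, truths, _, _ = mini_fixture
        base = rp.Thresholds()
        harder = base.replace(
            leader_peak_min_height=base.leader_peak_min_height + d_height,
            orf_peak_min_height=base.orf_peak_min_height + d_height,
            orf_peak_min_score=base.orf_peak_min_score + d_score,
        )
        genes = list(annotation.genes.values())
        lengths = annotation.contig_lengths
        for t in truths[:12]:
            g = annotation.genes[t.gene_id]
            leader = build_extended_leader(g, genes, 2000, lengths[g.contig], base)
            for caller in (
                lambda th: call_leader_peaks(g, leader, shifted_40s, annotation.genome, th),
                lambda th: call_orf_peaks(g, shifted_40s, annotation.genome, th),
            ):
                easy = {(p.gene_id, p.genomic_pos) for p in caller(base) if is_surviving(p, base)}
                hard = {(p.gene_id, p.genomic_pos) for p in caller(harder) if is_surviving(p, harder)}
                assert hard <= easy


class TestStrandSymmetry:
    def test_mirrored_gene_gives_identical_peaks(self, thresholds):
        """A minus-strand copy of a plus-strand locus yields the same peak set
        in transcript-relative coordinates."""
        leader_seq = "C" * 40 + "ATG" + "C" * 3 + "TAA" + "C" * 51
        orf = "ATG" + "CCG" * 14 + "C" + "ATG" + "CGC" + "CCG" * 24 + "TAA"
        out = {}
        for strand in "+-":
            gene, genome, leader = _gene_with_seq(leader_seq, orf, strand=strand)
            aug_leader = leader.to_genomic(60)
            aug_orf = int(gene.spliced_positions()[46])
            track = _track({(strand, aug_leader): 2.0, (strand, aug_orf): 10.0})
            peaks = call_leader_peaks(gene, leader, track, genome, thresholds)
            peaks += call_orf_peaks(gene, track, genome, thresholds)
            out[strand] = sorted(
                (p.region, p.distance_to_main_start, p.frame, round(p.height, 6),
                 tuple(sorted(p.flags)))
                for p in peaks
            )
        assert out["+"] == out["-"]
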