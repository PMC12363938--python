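"""40S peak scoring: motif scanning, pause scores, heights, and peak calls.

The pause score of a motif is the shifted, rpm-normalized 40S count at
the motif's first nucleotide divided by the mean count in a window of
``pause_halfwindow`` nt to either side (window includes the motif
position, so a uniform track scores exactly 1).  Peak height is the rpm
sum over a centered ``peak_sum_window``-nt window expressed per kb
(x200 for the default 5-nt window).

Leader AUG peaks are called on height alone (strictly above
``leader_peak_min_height``); ORF-internal AUG peaks must pass both the
pause score and the (stricter) height cutoff.  Frame-0 artifacts —
misannotated starts in leaders, internal starts in ORFs — and AUGs
immediately abutting a stop codon are flagged and excluded from the
evidence set but kept in the reported peak list.  Stop-codon peaks are
scanned with the same height machinery but are annotation-only: they
corroborate a uORF/iORF's termination site and never gate
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import Annotation, ExtendedLeader, GeneModel
from .params import Thresholds
from .tracks import DensityTrack

log = logging.getLogger(__name__)

START_CODON = "ATG"
STOP_CODONS = ("TAA", "TAG", "TGA")

EXCLUSION_FLAGS = frozenset(
    {"frame0_misannotated_start", "frame0_internal_start", "aug_adjacent_stop"}
)


@dataclass(frozen=True)
class Peak:
    """One scanned candidate translation-event signal."""

    gene_id: str
    genomic_pos: int  # first nt of the motif
    region: str  # "leader" | "orf"
    motif: str  # "start_AUG" | "stop_UAA" | "stop_UAG" | "stop_UGA"
    frame: int  # relative to the main ORF reading frame
    distance_to_main_start: int  # nt; negative = upstream of the main AUG
    score: float  # pause score (NaN when the window is all zero)
    height: float  # rpkm over the summation window
    flags: frozenset = frozenset()

    def with_flags(self, *extra: str) -> "Peak":
        return replace(self, flags=self.flags | frozenset(extra))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    region: str
    motif: str
    genomic_pos: int
    offset: int  # transcript-relative; negative = upstream of the main AUG
    frame: int


def scan_motifs(
    genome: Dict[str, str],
    gene: GeneModel,
    leader: Optional[ExtendedLeader],
    motifs: Sequence[str] = ("start",),
    regions: Sequence[str] = ("leader", "orf"),
) -> List[MotifHit]:
    """Report every start (and optionally stop) codon in all frames.

    The leader and the spliced ORF are scanned separately, strand-aware
    (sequences are reverse-complemented for ``-`` genes before
    scanning).  The ORF scan excludes the annotated start codon itself.
    Frames are transcript-relative: ``offset mod 3`` with offset measured
    from the first nt of the main AUG (negative upstream).  Ambiguous
    bases never match.
    """
    wanted: List[Tuple[str, str]] = []
    if "start" in motifs:
        wanted.append((START_CODON, "start_AUG"))
    if "stop" in motifs:
        wanted.extend((c, "stop_" + c.replace("T", "U")) for c in STOP_CODONS)

    hits: List[MotifHit] = []
    if "leader" in regions and leader is not None and leader.length >= 3:
        seq = leader.sequence(genome)
        n = len(seq)
        for i in range(n - 2):
            codon = seq[i : i + 3]
            for pattern, name in wanted:
                if codon == pattern:
                    offset = i - n  # negative, first nt of the motif
                    hits.append(
                        MotifHit(
                            gene.gene_id,
                            "leader",
                            name,
                            leader.to_genomic(-offset),
                            offset,
                            offset % 3,
                        )
                    )
    if "orf" in regions:
        seq = gene.spliced_seq(genome)
        positions = gene.spliced_positions()
        for i in range(1, len(seq) - 2):  # i=0 is the annotated start
            codon = seq[i : i + 3]
            for pattern, name in wanted:
                if codon == pattern:
                    hits.append(
                        MotifHit(
                            gene.gene_id,
                            "orf",
                            name,
                            int(positions[i]),
                            i,
                            i % 3,
                        )
                    )
    hits.sort(key=lambda h: h.offset)
    return hits


def _window_values(
    track: DensityTrack, contig: str, strand: str, pos: int, halfwidth: int
) -> Tuple[np.ndarray, bool]:
    arr = track.data[contig][strand]
    lo = max(0, pos - halfwidth)
    hi = min(arr.size, pos + halfwidth + 1)
    return arr[lo:hi], (lo != pos - halfwidth or hi != pos + halfwidth + 1)


def pause_score(
    track40s: DensityTrack,
    contig: str,
    strand: str,
    pos: int,
    halfwindow: int = 50,
    include_center: bool = True,
) -> float:
    """Reads at a position over the mean of its surrounding window.

    The track must be rpm-normalized and peak-stage P-site shifted.
    The window is truncated at contig edges; an all-zero window yields
    NaN (score undefined).
    """
    arr = track40s.data[contig][strand]
    center = float(arr[pos])
    window, _ = _window_values(track40s, contig, strand, pos, halfwindow)
    if not include_center:
        denom_sum = float(window.sum()) - center
        denom_n = window.size - 1
    else:
        denom_sum = float(window.sum())
        denom_n = window.size
    if denom_sum == 0.0 or denom_n == 0:
        return float("nan")
    return center / (denom_sum / denom_n)


def peak_height(
    track40s: DensityTrack,
    contig: str,
    strand: str,
    pos: int,
    sum_window: int = 5,
) -> Tuple[float, bool]:
    """rpm sum over a centered window, per kb (rpkm); returns (height, truncated).

    For the default 5-nt window this is the rpm sum x 200.  Windows
    running off a contig are truncated and the rpkm refers to the
    effective (truncated) window length.
    """
    half = sum_window // 2
    window, truncated = _window_values(track40s, contig, strand, pos, half)
    if window.size == 0:
        return 0.0, True
    return float(window.sum()) / (window.size / 1000.0), truncated


def _score_hit(
    hit: MotifHit,
    gene: GeneModel,
    track40s: DensityTrack,
    thresholds: Thresholds,
) -> Tuple[float, float, frozenset]:
    score = pause_score(
        track40s,
        gene.contig,
        gene.strand,
        hit.genomic_pos,
        thresholds.pause_halfwindow,
        thresholds.pause_include_center,
    )
    height, truncated = peak_height(
        track40s, gene.contig, gene.strand, hit.genomic_pos, thresholds.peak_sum_window
    )
    flags = set()
    if np.isnan(score):
        flags.add("zero_window")
    if truncated:
        flags.add("window_truncated")
    return score, height, frozenset(flags)


def _has_inframe_stop_before_start(leader_seq: str, aug_index: int) -> bool:
    """In-frame stop between a leader AUG and the main start codon?"""
    for i in range(aug_index + 3, len(leader_seq) - 2, 3):
        if leader_seq[i : i + 3] in STOP_CODONS:
            return True
    # a stop codon straddling the leader/ORF boundary cannot rescue the
    # frame-0 case: frame 0 means the AUG is in frame with the main ORF,
    # so the last (possibly partial) codon ends exactly at the main AUG
    return False


def call_leader_peaks(
    gene: GeneModel,
    leader: ExtendedLeader,
    track40s: DensityTrack,
    genome: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
) -> List[Peak]:
    """Score every leader AUG; height alone decides the call.

    Returns all scanned candidates: sub-threshold motifs carry
    ``below_threshold``; frame-0 AUGs with no in-frame stop before the
    main start carry ``frame0_misannotated_start`` and are excluded from
    the uORF evidence set.  Pause scores are recorded for transparency
    but never gate leader peaks.
    """
    if thresholds is None:
        thresholds = Thresholds()
    leader_seq = leader.sequence(genome)
    peaks: List[Peak] = []
    for hit in scan_motifs(genome, gene, leader, motifs=("start",), regions=("leader",)):
        score, height, flags = _score_hit(hit, gene, track40s, thresholds)
        flagset = set(flags)
        if not height > thresholds.leader_peak_min_height:
            flagset.add("below_threshold")
        if hit.frame == 0:
            aug_index = len(leader_seq) + hit.offset
            if not _has_inframe_stop_before_start(leader_seq, aug_index):
                flagset.add("frame0_misannotated_start")
        peaks.append(
            Peak(
                gene.gene_id,
                hit.genomic_pos,
                "leader",
                hit.motif,
                hit.frame,
                hit.offset,
                score,
                height,
                frozenset(flagset),
            )
        )
    return peaks


def call_orf_peaks(
    gene: GeneModel,
    track40s: DensityTrack,
    genome: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
) -> List[Peak]:
    """Score every internal AUG; pause score AND height jointly decide.

    Frame-0 internal AUGs (misannotated or internal starts) are flagged
    ``frame0_internal_start``; AUGs whose next codon in their own frame
    is a stop are flagged ``aug_adjacent_stop``; both are excluded from
    the iORF evidence set.
    """
    if thresholds is None:
        thresholds = Thresholds()
    seq = gene.spliced_seq(genome)
    peaks: List[Peak] = []
    for hit in scan_motifs(genome, gene, None, motifs=("start",), regions=("orf",)):
        score, height, flags = _score_hit(hit, gene, track40s, thresholds)
        flagset = set(flags)
        called = (score > thresholds.orf_peak_min_score) and (
            height > thresholds.orf_peak_min_height
        )
        if not called:
            flagset.add("below_threshold")
        if hit.frame == 0:
            flagset.add("frame0_internal_start")
        if seq[hit.offset + 3 : hit.offset + 6] in STOP_CODONS:
            flagset.add("aug_adjacent_stop")
        peaks.append(
            Peak(
                gene.gene_id,
                hit.genomic_pos,
                "orf",
                hit.motif,
                hit.frame,
                hit.offset,
                score,
                height,
                frozenset(flagset),
            )
        )
    return peaks


def call_stop_peaks(
    gene: GeneModel,
    leader: Optional[ExtendedLeader],
    track40s: DensityTrack,
    genome: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
    regions: Sequence[str] = ("leader", "orf"),
) -> List[Peak]:
    """Annotation-only stop-codon peaks (leader and/or ORF), height-gated.

    Reuses the leader height criterion; these corroborate uORF/iORF
    termination sites but never enter classification.
    """
    if thresholds is None:
        thresholds = Thresholds()
    peaks: List[Peak] = []
    for hit in scan_motifs(genome, gene, leader, motifs=("stop",), regions=regions):
        if hit.motif.startswith("start"):
            continue
        score, height, flags = _score_hit(hit, gene, track40s, thresholds)
        flagset = set(flags) | {"annotation_only"}
        if not height > thresholds.leader_peak_min_height:
            flagset.add("below_threshold")
        peaks.append(
            Peak(
                gene.gene_id,
                hit.genomic_pos,
                hit.region,
                hit.motif,
                hit.frame,
                hit.offset,
                score,
                height,
                frozenset(flagset),
            )
        )
    return peaks


def detect_main_start_peak(
    gene: GeneModel,
    track40s: DensityTrack,
    thresholds: Optional[Thresholds] = None,
) -> Tuple[bool, float]:
    """40S peak at the annotated start codon of the main ORF?

    Discriminates inefficient initiation (peak present) from internal
    transcript isoforms (peak absent).  Reuses the leader height
    criterion (strictly above ``leader_peak_min_height``).
    """
    if thresholds is None:
        thresholds = Thresholds()
    height, _ = peak_height(
        track40s, gene.contig, gene.strand, gene.start_codon_pos, thresholds.peak_sum_window
    )
    return height > thresholds.leader_peak_min_height, height


def read_curation_list(path: str) -> List[Tuple[str, int, str, str]]:
    """Parse a curation list: gene_id <TAB> genomic_pos <TAB> action <TAB> note."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            parts = line.split("\t")
            gene_id, pos, action = parts[0], int(parts[1]), parts[2]
            note = parts[3] if len(parts) > 3 else ""
            entries.append((gene_id, pos, action, note))
    return entries


def apply_curation(
    peaks: List[Peak],
    allowlist: Optional[str] = None,
    denylist: Optional[str] = None,
) -> Tuple[List[Peak], List[str]]:
    """Force listed peaks in or out; returns (updated peaks, action log).

    Allowlist entries set ``manual_add``, which bypasses the pause-score
    conjunct but not the height conjunct unless the note contains
    ``force``.  Denylist entries set ``manual_remove``.  Entries that
    match no scanned motif are warned about and ignored.
    """
    index = {(p.gene_id, p.genomic_pos): i for i, p in enumerate(peaks)}
    out = list(peaks)
    actions: List[str] = []
    for path, kind in ((allowlist, "add"), (denylist, "remove")):
        if path is None:
            continue
        for gene_id, pos, action, note in read_curation_list(path):
            key = (gene_id, pos)
            if key not in index:
                log.warning("curation entry %s:%d matches no scanned motif; ignored", gene_id, pos)
                actions.append(f"ignored\t{gene_id}\t{pos}\tno matching motif")
                continue
            i = index[key]
            if kind == "add":
                extra = ["manual_add"]
                if "force" in note.lower() or action == "add_force":
                    extra.append("manual_add_force")
                out[i] = out[i].with_flags(*extra)
                actions.append(f"manual_add\t{gene_id}\t{pos}\t{note}")
            else:
                out[i] = out[i].with_flags("manual_remove")
                actions.append(f"manual_remove\t{gene_id}\t{pos}\t{note}")
    return out, actions


def is_surviving(peak: Peak, thresholds: Optional[Thresholds] = None) -> bool:
    """Does a scanned candidate count as evidence for classification?"""
    if thresholds is None:
        thresholds = Thresholds()
    if "manual_remove" in peak.flags:
        return False
    if "annotation_only" in peak.flags:
        return False
    if "manual_add_force" in peak.flags:
        return True
    if peak.flags & EXCLUSION_FLAGS:
        return False
    if "manual_add" in peak.flags:
        # bypasses the score conjunct; the height conjunct still applies
        min_h = (
            thresholds.orf_peak_min_height
            if peak.region == "orf"
            else thresholds.leader_peak_min_height
        )
        return peak.height > min_h
    return "below_threshold" not in peak.flags


def surviving(peaks: Iterable[Peak], thresholds: Optional[Thresholds] = None) -> List[Peak]:
    return [p for p in peaks if is_surviving(p, thresholds)]


def peaks_to_frame(peaks: Iterable[Peak]) -> pd.DataFrame:
    """Tabular peak report, 5'->3' in transcript orientation per gene."""
    rows = [
        {
            "gene_id": p.gene_id,
            "genomic_pos": p.genomic_pos,
            "region": p.region,
            "motif": p.motif,
            "frame": p.frame,
            "distance_to_main_start": p.distance_to_main_start,
            "score": p.score,
            "height": p.height,
            "flags": ",".join(sorted(p.flags)) or ".",
        }
        for p in peaks
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "genomic_pos",
            "region",
            "motif",
            "frame",
            "distance_to_main_start",
            "score",
            "height",
            "flags",
        ],
    )
    if len(df):
        df = df.sort_values(["gene_id", "distance_to_main_start"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def write_peaks(
    peaks: Iterable[Peak],
    annotation: Annotation,
    tsv_path: str,
    bed_path: Optional[str] = None,
) -> None:
    """Write the peak table as TSV plus an optional BED6+ companion."""
    df = peaks_to_frame(peaks)
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if bed_path is None:
        return
    with open(bed_path, "w") as fh:
        for _, r in df.iterrows():
            gene = annotation.genes[r.gene_id]
            start = int(r.genomic_pos) if gene.strand == "+" else int(r.genomic_pos) - 2
            score = 0.0 if np.isnan(r.score) else r.score
            fh.write(
                f"{gene.contig}\t{start}\t{start + 3}\t"
                f"{r.gene_id}:{int(r.distance_to_main_start)}\t{score:.6g}\t{gene.strand}\t"
                f"{r.height:.6g}\t{int(r.frame)}\t{r.flags}\n"
            )
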