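"""Strand-specific per-nucleotide density tracks and region statistics.

A :class:`DensityTrack` holds dense per-contig float arrays of footprint
5'-end counts for one assay (40S, 80S, or RNA-seq), one array per strand.
Tracks are read from strand-split bedGraph (0-based half-open) or wiggle
(1-based) files, optionally carrying a ``#total_mapped=<int>`` header so
that rpm normalization can refer to the full library rather than only the
loaded contigs.  P-site shifting moves every count downstream (5'->3' on
its own strand) by a fixed offset; RNA-seq is never shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .annotation import GeneModel
from .params import Thresholds

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


class TrackError(ValueError):
    pass


@dataclass
class DensityTrack:
    assay: str
    data: Dict[str, Dict[str, np.ndarray]]  # contig -> strand -> array
    units: str = "raw"  # "raw" | "rpm"
    total_mapped: float = 0.0
    psite_shift_applied: int = 0

    def copy(self) -> "DensityTrack":
        return DensityTrack(
            assay=self.assay,
            data={c: {s: a.copy() for s, a in d.items()} for c, d in self.data.items()},
            units=self.units,
            total_mapped=self.total_mapped,
            psite_shift_applied=self.psite_shift_applied,
        )

    def array(self, contig: str, strand: str) -> np.ndarray:
        return self.data[contig][strand]

    def total_counts(self) -> float:
        return float(
            sum(a.sum() for d in self.data.values() for a in d.values())
        )

    def values_at(self, contig: str, strand: str, positions: np.ndarray) -> np.ndarray:
        return self.data[contig][strand][positions]


def _empty_data(contig_lengths: Dict[str, int]) -> Dict[str, Dict[str, np.ndarray]]:
    return {
        c: {s: np.zeros(n, dtype=np.float64) for s in STRANDS}
        for c, n in contig_lengths.items()
    }


def _parse_track_file(path: str, arrays: Dict[str, np.ndarray], contig_lengths: Dict[str, int]) -> Optional[float]:
    """Parse one strand's bedGraph or wiggle file into per-contig arrays.

    Returns the ``#total_mapped`` header value if present.  Overlapping
    bedGraph intervals and negative values are fatal.
    """
    total_mapped: Optional[float] = None
    occupied = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    mode = "bedgraph"
    chrom = None
    wig_pos = 0
    wig_step = 1
    wig_span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#total_mapped="):
                total_mapped = float(line.split("=", 1)[1])
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode, chrom = "fixed", kv["chrom"]
                wig_pos = int(kv["start"]) - 1  # wiggle is 1-based
                wig_step = int(kv.get("step", 1))
                wig_span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode, chrom = "variable", kv["chrom"]
                wig_span = int(kv.get("span", 1))
                continue
            fields = line.split()
            if mode == "bedgraph":
                if len(fields) != 4:
                    raise TrackError(f"{path}:{lineno}: malformed bedGraph line")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if value < 0:
                    raise TrackError(f"{path}:{lineno}: negative value {value}")
                if chrom not in arrays:
                    continue  # contig not loaded
                if occupied[chrom][start:end].any():
                    raise TrackError(f"{path}:{lineno}: overlapping bedGraph intervals on {chrom}")
                occupied[chrom][start:end] = True
                arrays[chrom][start:end] = value
            elif mode == "fixed":
                value = float(fields[0])
                if value < 0:
                    raise TrackError(f"{path}:{lineno}: negative value {value}")
                if chrom in arrays:
                    arrays[chrom][wig_pos : wig_pos + wig_span] = value
                wig_pos += wig_step
            else:  # variable
                pos, value = int(fields[0]) - 1, float(fields[1])
                if value < 0:
                    raise TrackError(f"{path}:{lineno}: negative value {value}")
                if chrom in arrays:
                    arrays[chrom][pos : pos + wig_span] = value
    return total_mapped


def read_track(
    plus_path: str,
    minus_path: str,
    assay: str,
    contig_lengths: Dict[str, int],
) -> DensityTrack:
    """Read a strand-split pair of bedGraph/wiggle files into a raw track.

    ``total_mapped`` is the sum of the two files' ``#total_mapped``
    headers when both are present, otherwise the sum of all loaded
    counts.
    """
    data = _empty_data(contig_lengths)
    plus_arrays = {c: data[c]["+"] for c in data}
    minus_arrays = {c: data[c]["-"] for c in data}
    t_plus = _parse_track_file(plus_path, plus_arrays, contig_lengths)
    t_minus = _parse_track_file(minus_path, minus_arrays, contig_lengths)
    track = DensityTrack(assay=assay, data=data, units="raw")
    headers = [t for t in (t_plus, t_minus) if t is not None]
    track.total_mapped = sum(headers) if headers else track.total_counts()
    return track


def write_track(track: DensityTrack, plus_path: str, minus_path: str) -> None:
    """Write a track as a strand-split bedGraph pair with a total_mapped header.

    Runs of equal nonzero values are merged; values are printed with
    ``%.10g`` so that write/read round-trips are stable.
    """
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            if strand == "+":  # library-level metadata lives in one file
                fh.write(f"#total_mapped={track.total_mapped:.10g}\n")
            for contig in sorted(track.data):
                arr = track.data[contig][strand]
                nz = np.nonzero(arr)[0]
                if nz.size == 0:
                    continue
                run_start = nz[0]
                prev = nz[0]
                val = arr[nz[0]]
                for p in nz[1:]:
                    if p == prev + 1 and arr[p] == val:
                        prev = p
                        continue
                    fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{val:.10g}\n")
                    run_start, prev, val = p, p, arr[p]
                fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{val:.10g}\n")


def shift_psite(track: DensityTrack, offset: int) -> DensityTrack:
    """Move every count ``offset`` nt in the 5'->3' direction of its strand.

    Counts shifted past a contig end are dropped (and logged).  Shifting
    an already-shifted track is fatal; RNA-seq tracks should be shifted
    by 0 (identity) or not at all.
    """
    if track.psite_shift_applied != 0:
        raise TrackError(
            f"track already P-site shifted by {track.psite_shift_applied} nt"
        )
    out = track.copy()
    if offset == 0:
        return out
    dropped = 0.0
    for contig, d in out.data.items():
        plus = d["+"]
        minus = d["-"]
        shifted_plus = np.zeros_like(plus)
        shifted_plus[offset:] = plus[: plus.size - offset]
        dropped += plus[plus.size - offset :].sum()
        shifted_minus = np.zeros_like(minus)
        shifted_minus[: minus.size - offset] = minus[offset:]
        dropped += minus[:offset].sum()
        d["+"] = shifted_plus
        d["-"] = shifted_minus
    if dropped:
        log.info("shift_psite(%+d): dropped %.3f counts past contig ends", offset, dropped)
    out.psite_shift_applied = offset
    return out


def normalize_rpm(track: DensityTrack) -> DensityTrack:
    """Scale counts to reads-per-million-mapped; requires a raw track."""
    if track.units != "raw":
        raise TrackError("track already rpm-normalized")
    if track.total_mapped <= 0:
        raise TrackError("cannot rpm-normalize a track with total_mapped == 0")
    out = track.copy()
    factor = 1e6 / track.total_mapped
    for d in out.data.values():
        for s in STRANDS:
            d[s] = d[s] * factor
    out.units = "rpm"
    return out


@dataclass
class RegionCount:
    gene_id: str
    region_kind: str
    length: int
    raw: float
    rpm: float
    rpkm: float
    flags: set = field(default_factory=set)


def _region_positions(gene: GeneModel, region_kind: str, thresholds: Thresholds, contig_length: int) -> Tuple[np.ndarray, set]:
    """Genomic positions (transcript 5'->3' order) of a named gene region."""
    flags: set = set()
    if region_kind == "orf":
        pos = gene.spliced_positions()
    elif region_kind == "whole_orf_interval":
        pos = np.arange(gene.orf_start, gene.orf_end)
        if gene.strand == "-":
            pos = pos[::-1]
    elif region_kind == "intron":
        parts = [np.arange(a, b) for a, b in gene.introns]
        pos = np.concatenate(parts) if parts else np.empty(0, dtype=int)
        if gene.strand == "-":
            pos = pos[::-1]
    elif region_kind in ("first100", "last100"):
        spliced = gene.spliced_positions()
        w = thresholds.split_count_window
        pos = spliced[:w] if region_kind == "first100" else spliced[-w:]
    elif region_kind == "leader":
        n = gene.utr5_len
        if gene.strand == "+":
            pos = np.arange(gene.orf_start - n, gene.orf_start)
        else:
            pos = np.arange(gene.orf_end, gene.orf_end + n)[::-1]
    elif region_kind == "utr3":
        a, b = gene.utr3_interval()
        pos = np.arange(a, b)
        if gene.strand == "-":
            pos = pos[::-1]
    elif region_kind == "upstream200":
        n = thresholds.upstream_window
        if gene.strand == "+":
            a = gene.orf_start - n
            if a < 0:
                a, flags = 0, {"truncated"}
            pos = np.arange(a, gene.orf_start)
        else:
            b = gene.orf_end + n
            if b > contig_length:
                b, flags = contig_length, {"truncated"}
            pos = np.arange(gene.orf_end, b)[::-1]
    else:
        raise ValueError(f"unknown region_kind {region_kind!r}")
    inside = (pos >= 0) & (pos < contig_length)
    if not inside.all():
        flags.add("truncated")
        pos = pos[inside]
    return pos, flags


def count_region(
    track: DensityTrack,
    gene: GeneModel,
    region_kind: str,
    thresholds: Optional[Thresholds] = None,
) -> RegionCount:
    """Raw/rpm/rpkm over a named region of one gene, strand-matched.

    Spliced ORF counting excludes intronic positions.  ``rpkm`` is
    rpm divided by the region length in kb; a zero-length region yields
    NaN rpkm with a ``zero_length`` flag.  ORF counts below
    ``expression_min`` rpkm carry a ``below_threshold`` flag.
    """
    if thresholds is None:
        thresholds = Thresholds()
    contig_length = track.data[gene.contig]["+"].size
    pos, flags = _region_positions(gene, region_kind, thresholds, contig_length)
    total = float(track.values_at(gene.contig, gene.strand, pos).sum()) if pos.size else 0.0
    if track.units == "rpm":
        rpm = total
        raw = total * track.total_mapped / 1e6
    else:
        raw = total
        rpm = total * 1e6 / track.total_mapped if track.total_mapped > 0 else float("nan")
    length = int(pos.size)
    if length == 0:
        rpkm = float("nan")
        flags.add("zero_length")
    else:
        rpkm = rpm / (length / 1000.0)
    if region_kind == "orf" and length and rpkm < thresholds.expression_min:
        flags.add("below_threshold")
    return RegionCount(gene.gene_id, region_kind, length, raw, rpm, rpkm, flags)


@dataclass
class SplitCountResult:
    gene_id: str
    first: float
    last: float
    ratio: float  # NaN when first == 0
    is_split_positive: bool
    flags: set = field(default_factory=set)


def split_count(
    track_rnaseq: DensityTrack,
    gene: GeneModel,
    thresholds: Optional[Thresholds] = None,
) -> SplitCountResult:
    """Last-100 / first-100 RNA-seq density ratio over the main ORF.

    A strictly more than ``split_count_ratio``-fold excess in the final
    window marks an internal transcript isoform.  ORFs shorter than two
    windows are untestable.  With zero reads in the first window the
    ratio is undefined; the test is then positive only if the last
    window holds at least ``min_informative_reads`` raw reads.
    """
    if thresholds is None:
        thresholds = Thresholds()
    w = thresholds.split_count_window
    if gene.spliced_length < 2 * w:
        return SplitCountResult(gene.gene_id, 0.0, 0.0, float("nan"), False, {"untestable"})
    first_rc = count_region(track_rnaseq, gene, "first100", thresholds)
    last_rc = count_region(track_rnaseq, gene, "last100", thresholds)
    first, last = first_rc.raw, last_rc.raw
    flags: set = set()
    if first == 0:
        flags.add("ratio_undefined")
        positive = last >= thresholds.min_informative_reads
        ratio = float("nan")
    else:
        ratio = last / first
        positive = ratio > thresholds.split_count_ratio
    return SplitCountResult(gene.gene_id, first, last, ratio, positive, flags)


def write_count_table(counts: Iterable[RegionCount], path: str) -> None:
    """Tab-separated count table (gene_id, region_kind, raw, rpm, rpkm)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tregion_kind\traw\trpm\trpkm\n")
        for rc in counts:
            fh.write(
                f"{rc.gene_id}\t{rc.region_kind}\t{rc.raw:.6g}\t{rc.rpm:.6g}\t{rc.rpkm:.6g}\n"
            )
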