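"""Numeric parameters of the peak-calling and classification pipeline.

Every threshold used anywhere in the pipeline lives in :class:`Thresholds`
so that a run is fully described by one serializable record.  Defaults are
the values used throughout the analysis this package implements: peak
heights are in rpkm computed over a 5-nt summation window, pause scores
are fold enrichments over a 101-nt window, and the two 40S P-site offsets
reflect the two pipeline stages that consume the 40S track (gene-level
quantitation vs. peak scoring).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class Thresholds:
    """Complete numeric parameter set.

    Attributes
    ----------
    leader_peak_min_height:
        Minimum 5'-leader 40S peak height in rpkm (strict ``>``); leader
        peaks are called on height alone because background variability
        makes the pause-score denominator unreliable in leaders.
    orf_peak_min_height, orf_peak_min_score:
        ORF-internal 40S peaks must exceed BOTH the height (rpkm) and the
        pause score (fold) cutoffs; ORFs carry more 40S background
        (artifactual 80S subunit separation), hence the stricter joint rule.
    pause_halfwindow:
        Half-width in nt of the pause-score window (50 → 101-nt window).
    peak_sum_window:
        Width in nt of the centered peak-height summation window (odd).
    psite_offset_80s, psite_offset_40s_quant, psite_offset_40s_peaks:
        P-site shifts in nt applied to footprint 5' ends.  The 40S track
        is shifted 14 nt for gene-level quantitation but 13 nt for peak
        scoring; both are exposed because the two stages are calibrated
        independently.
    leader_max_extension:
        Maximum upstream extension of the annotated 5'UTR when searching
        for alternative-TSS translation events (2000 nt; a 3000-nt
        variant is used to look for outliers).
    extended_leader_cutoff:
        Peaks further than this many nt upstream of the main start define
        a 5'-extended (LUTI-like) transcript; at or below, a short-leader
        uORF transcript.  The value ~ the genome-average 5'UTR length.
    split_count_window, split_count_ratio:
        The split-count test compares RNA-seq raw counts in the first and
        last ``split_count_window`` nt of the main ORF; a last/first ratio
        strictly above ``split_count_ratio`` indicates an internal
        transcript isoform.
    min_informative_reads:
        Zero-denominator guard for the split-count test: with zero reads
        in the first window the test is positive only if the last window
        holds at least this many raw reads.
    utr3_sd_multiplier:
        The long-3'UTR cutoff is mean + multiplier * SD of annotated
        3'UTR lengths.
    expression_min:
        Minimum ORF footprint density (rpkm) for a gene to enter the
        peak analysis.
    fc_min, fdr_orf, fdr_intron:
        NMD-target selection from differential-expression tables:
        fold-change strictly above ``fc_min`` (log2fc > 1) and adjusted p
        strictly below the per-feature FDR cutoff (1% ORF, 5% intron).
    upstream_window:
        Width in nt of the upstream window used to build count tables for
        condition-responsive (LUTI-unmasking) differential expression.
    """

    leader_peak_min_height: float = 92.0
    orf_peak_min_height: float = 137.0
    orf_peak_min_score: float = 10.0
    pause_halfwindow: int = 50
    peak_sum_window: int = 5
    psite_offset_80s: int = 13
    psite_offset_40s_quant: int = 14
    psite_offset_40s_peaks: int = 13
    leader_max_extension: int = 2000
    extended_leader_cutoff: int = 100
    split_count_window: int = 100
    split_count_ratio: float = 2.0
    min_informative_reads: int = 10
    utr3_sd_multiplier: float = 2.0
    expression_min: float = 5.0
    fc_min: float = 2.0
    fdr_orf: float = 0.01
    fdr_intron: float = 0.05
    upstream_window: int = 200
    # behavioural switches (documented design choices, not tuning knobs)
    pause_include_center: bool = True
    main_start_uses_leader_height: bool = True
    obstacles_include_dubious: bool = True
    obstacles_same_strand_only: bool = False
    utr3_population_sd: bool = True
    leader_class_by_peak_position: bool = True

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.type in ("float", "int")
        }
        for name, value in numeric.items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be strictly positive, got {value}")
        for name in ("fdr_orf", "fdr_intron"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.peak_sum_window % 2 != 1:
            raise ValueError("peak_sum_window must be odd (centered window)")

    def replace(self, **kwargs) -> "Thresholds":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)
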