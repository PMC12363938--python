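"""NMD-target selection and mechanistic classification.

Genes upregulated in an NMD-deficient (*upf1*-like) background are
selected from differential-expression results computed over main-ORF
counts (FDR < 1%) and intron counts (FDR < 5%), both requiring strictly
more than 2-fold upregulation.  Each selected gene is then rationalized
by the peak evidence: a surviving 5'-leader peak further than 100 nt
upstream of the main AUG marks a 5'-extended (LUTI-like) transcript,
one at or within 100 nt a short-leader uORF transcript; ORF-internal
peaks split into inefficient-initiation transcripts (IIT: 40S peak at
the main start) and internal transcript isoforms (ITI: no main-start
peak, or a positive RNA-seq split-count test, which overrides IIT);
no-peak genes fall back to structural explanations (long 3'UTR,
pseudo-bicistronic pair, pseudogene pair), with retained introns always
reported when the gene was intron-selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .params import Thresholds
from .tracks import DensityTrack, RegionCount, SplitCountResult, count_region

log = logging.getLogger(__name__)

LEADER_CLASSES = ("extended_5p", "short_5p_utr", "none")
ORF_CLASSES = ("IIT", "ITI", "none")
CATEGORIES = (
    "uORF_extended_LUTI",
    "uORF_short_leader",
    "IIT",
    "ITI",
    "retained_intron",
    "long_3UTR",
    "pseudo_bicistronic",
    "pseudogene",
    "unexplained",
)
# declared precedence for no-peak structural explanations
STRUCTURAL_ORDER = ("long_3UTR", "pseudo_bicistronic", "pseudogene")


def read_de_table(path: str) -> pd.DataFrame:
    """Read a DE results table (gene_id, feature, log2fc, padj, mean_expression)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "feature", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    return df


def select_nmd_genes(
    de_orf: pd.DataFrame,
    de_intron: pd.DataFrame,
    thresholds: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """Select NMD-sensitive genes from ORF and intron DE tables.

    ORF-selected: ``padj < fdr_orf`` AND ``log2fc > log2(fc_min)``;
    intron-selected: ``padj < fdr_intron`` AND the same fold-change rule
    (all inequalities strict).  Returns one row per selected gene with
    ``nmd_via`` in {orf_de, intron_de, both} and a ``retained_intron``
    flag for intron-selected genes.  Records with missing padj are
    skipped with a warning.
    """
    if thresholds is None:
        thresholds = Thresholds()
    lfc_min = float(np.log2(thresholds.fc_min))

    def _pick(df: pd.DataFrame, fdr: float) -> Set[str]:
        n_missing = int(df["padj"].isna().sum())
        if n_missing:
            log.warning("%d DE records with missing padj skipped", n_missing)
        ok = df.dropna(subset=["padj"])
        sel = ok[(ok["padj"] < fdr) & (ok["log2fc"] > lfc_min)]
        return set(sel["gene_id"])

    orf_set = _pick(de_orf, thresholds.fdr_orf)
    intron_set = _pick(de_intron, thresholds.fdr_intron)
    rows = []
    for gid in sorted(orf_set | intron_set):
        in_orf, in_intron = gid in orf_set, gid in intron_set
        via = "both" if (in_orf and in_intron) else ("orf_de" if in_orf else "intron_de")
        rows.append(
            {"gene_id": gid, "nmd_via": via, "retained_intron": in_intron}
        )
    return pd.DataFrame(rows, columns=["gene_id", "nmd_via", "retained_intron"])


def classify_leader(
    surviving_leader_peaks: Sequence, thresholds: Optional[Thresholds] = None
) -> str:
    """5'-extended vs short-leader call from surviving leader peaks.

    ``extended_5p`` iff the 5'-most surviving peak lies strictly more
    than ``extended_leader_cutoff`` nt upstream of the main start;
    ``short_5p_utr`` iff peaks exist but all lie at or within the
    cutoff; ``none`` without peaks.
    """
    if thresholds is None:
        thresholds = Thresholds()
    if not surviving_leader_peaks:
        return "none"
    most_upstream = min(p.distance_to_main_start for p in surviving_leader_peaks)
    if -most_upstream > thresholds.extended_leader_cutoff:
        return "extended_5p"
    return "short_5p_utr"


def classify_orf(
    has_orf_peaks: bool,
    main_start_peak: bool,
    split_positive: bool,
) -> str:
    """IIT/ITI discrimination.

    ITI iff (ORF peaks present AND no main-start peak) OR the
    split-count test is positive (the split test overrides an IIT
    call); IIT iff ORF peaks present with a main-start peak and a
    negative split test; ``none`` otherwise.
    """
    if (has_orf_peaks and not main_start_peak) or split_positive:
        return "ITI"
    if has_orf_peaks and main_start_peak and not split_positive:
        return "IIT"
    return "none"


def long_utr3_threshold(
    utr3_lengths: Sequence[float],
    multiplier: float = 2.0,
    population_sd: bool = True,
) -> Tuple[float, Set[str]]:
    """Length cutoff for "long" 3'UTRs: mean + multiplier * SD.

    Computed over all annotated genes (not only NMD targets).  A
    degenerate distribution (SD 0) returns the mean with a warning flag.
    """
    lengths = np.asarray([x for x in utr3_lengths if np.isfinite(x)], dtype=float)
    if lengths.size < 2:
        raise ValueError("need at least 2 finite 3'UTR lengths")
    sd = float(lengths.std(ddof=0 if population_sd else 1))
    mean = float(lengths.mean())
    flags: Set[str] = set()
    if sd == 0.0:
        flags.add("degenerate_sd")
        log.warning("all 3'UTR lengths equal; threshold degenerates to the mean")
    return mean + multiplier * sd, flags


@dataclass
class GeneEvidence:
    """All inputs to the per-gene rationalization."""

    gene_id: str
    nmd_via: str = "orf_de"
    leader_class: str = "none"
    has_orf_peaks: bool = False
    main_start_peak: bool = False
    split_positive: bool = False
    long_utr3: bool = False
    bicistronic_member: bool = False
    pseudogene_member: bool = False
    retained_intron: bool = False


@dataclass
class GeneClassification:
    gene_id: str
    nmd_via: str
    leader_class: str
    orf_class: str
    rationalization: Tuple[str, ...]
    evidence: GeneEvidence

    @property
    def explained(self) -> bool:
        return self.rationalization != ("unexplained",)


def rationalize(ev: GeneEvidence, thresholds: Optional[Thresholds] = None) -> GeneClassification:
    """Assemble the ordered rationalization for one NMD-sensitive gene.

    Leader and ORF classes are both reported when both apply (genes can
    express two NMD-sensitive isoforms).  ``retained_intron`` is always
    reported when flagged.  Structural explanations (long 3'UTR,
    pseudo-bicistronic, pseudogene, in that declared order) apply only
    to genes with neither leader nor ORF peak evidence.  A gene with
    nothing at all is ``unexplained``.
    """
    orf_class = classify_orf(ev.has_orf_peaks, ev.main_start_peak, ev.split_positive)
    cats: List[str] = []
    if ev.leader_class == "extended_5p":
        cats.append("uORF_extended_LUTI")
    elif ev.leader_class == "short_5p_utr":
        cats.append("uORF_short_leader")
    if orf_class != "none":
        cats.append(orf_class)
    if ev.retained_intron:
        cats.append("retained_intron")
    if ev.leader_class == "none" and orf_class == "none":
        structural = {
            "long_3UTR": ev.long_utr3,
            "pseudo_bicistronic": ev.bicistronic_member,
            "pseudogene": ev.pseudogene_member,
        }
        cats.extend(c for c in STRUCTURAL_ORDER if structural[c])
    if not cats:
        cats = ["unexplained"]
    return GeneClassification(
        gene_id=ev.gene_id,
        nmd_via=ev.nmd_via,
        leader_class=ev.leader_class,
        orf_class=orf_class,
        rationalization=tuple(cats),
        evidence=ev,
    )


def read_pair_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing pair columns {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "."
    return df


def annotate_structures(
    nmd_ids: Set[str],
    known_ids: Set[str],
    bicistronic_pairs: Optional[pd.DataFrame] = None,
    pseudogene_pairs: Optional[pd.DataFrame] = None,
) -> Tuple[Dict[str, Set[str]], pd.DataFrame]:
    """Set pair-membership flags and emit a pair-level report.

    A pair is counted once even when both members are NMD-sensitive; a
    gene listed in several pairs is flagged once.  Pair entries naming
    unknown genes are skipped with a warning.
    """
    flags: Dict[str, Set[str]] = {gid: set() for gid in nmd_ids}
    pair_rows: List[dict] = []
    for df, flag, kind in (
        (bicistronic_pairs, "bicistronic_member", "bicistronic"),
        (pseudogene_pairs, "pseudogene_member", "pseudogene"),
    ):
        if df is None:
            continue
        for _, row in df.iterrows():
            a, b = row["gene_a"], row["gene_b"]
            unknown = [g for g in (a, b) if g not in known_ids]
            if unknown:
                log.warning("pair (%s, %s): unknown gene id(s) %s; skipped", a, b, unknown)
                continue
            members = [g for g in (a, b) if g in nmd_ids]
            if not members:
                continue
            for g in members:
                flags[g].add(flag)
            pair_rows.append(
                {
                    "pair_kind": kind,
                    "gene_a": a,
                    "gene_b": b,
                    "n_nmd_members": len(members),
                    "source": row.get("source", "."),
                }
            )
    report = pd.DataFrame(
        pair_rows, columns=["pair_kind", "gene_a", "gene_b", "n_nmd_members", "source"]
    )
    return flags, report


def summarize(
    classifications: Sequence[GeneClassification],
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Per-category counts, peak-evidence overlap, and the rationalized fraction.

    The overlap counts (leader-only / orf-only / both / neither)
    partition the input; all arithmetic is exact integer counting.
    """
    n = len(classifications)
    cat_counts = {c: 0 for c in CATEGORIES}
    leader_only = orf_only = both = neither = 0
    explained = 0
    for cl in classifications:
        for c in cl.rationalization:
            cat_counts[c] += 1
        has_leader = cl.leader_class != "none"
        has_orf = cl.orf_class != "none"
        if has_leader and has_orf:
            both += 1
        elif has_leader:
            leader_only += 1
        elif has_orf:
            orf_only += 1
        else:
            neither += 1
        if cl.explained:
            explained += 1
    rows = [{"category": c, "n_genes": cat_counts[c]} for c in CATEGORIES]
    table = pd.DataFrame(rows, columns=["category", "n_genes"])
    rollup: Dict[str, object] = {
        "n_genes": n,
        "leader_only": leader_only,
        "orf_only": orf_only,
        "both": both,
        "neither": neither,
        "n_explained": explained,
        "fraction_explained": (explained / n) if n else float("nan"),
    }
    if n == 0:
        rollup["fraction_explained_undefined"] = True
    return table, rollup


def classifications_to_frame(classifications: Sequence[GeneClassification]) -> pd.DataFrame:
    rows = []
    for cl in classifications:
        ev = cl.evidence
        rows.append(
            {
                "gene_id": cl.gene_id,
                "nmd_via": cl.nmd_via,
                "leader_class": cl.leader_class,
                "orf_class": cl.orf_class,
                "rationalization": ",".join(cl.rationalization),
                "has_leader_peaks": ev.leader_class != "none",
                "has_orf_peaks": ev.has_orf_peaks,
                "main_start_peak": ev.main_start_peak,
                "split_positive": ev.split_positive,
                "long_utr3": ev.long_utr3,
                "bicistronic_member": ev.bicistronic_member,
                "pseudogene_member": ev.pseudogene_member,
                "retained_intron": ev.retained_intron,
            }
        )
    cols = [
        "gene_id",
        "nmd_via",
        "leader_class",
        "orf_class",
        "rationalization",
        "has_leader_peaks",
        "has_orf_peaks",
        "main_start_peak",
        "split_positive",
        "long_utr3",
        "bicistronic_member",
        "pseudogene_member",
        "retained_intron",
    ]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df = df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    return df


def upstream_window_de_input(
    tracks_by_condition: Dict[str, DensityTrack],
    genes: Sequence[GeneModel],
    thresholds: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """Raw RNA-seq counts over the upstream window, per gene per condition.

    Produces the count table for an external differential-expression run
    over the region immediately 5' of each ORF (the signature of a
    condition-induced 5'-extended transcript otherwise masked by NMD).
    Windows truncated at a contig edge are flagged.
    """
    if thresholds is None:
        thresholds = Thresholds()
    conditions = sorted(tracks_by_condition)
    rows = []
    for gene in genes:
        row: Dict[str, object] = {"gene_id": gene.gene_id}
        truncated = False
        for cond in conditions:
            rc = count_region(tracks_by_condition[cond], gene, "upstream200", thresholds)
            row[f"raw_{cond}"] = rc.raw
            truncated = truncated or ("truncated" in rc.flags)
        row["truncated"] = truncated
        rows.append(row)
    cols = ["gene_id"] + [f"raw_{c}" for c in conditions] + ["truncated"]
    return pd.DataFrame(rows, columns=cols)
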