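"""Deterministic synthetic genome, footprint tracks, and truth labels.

The generator emits a toy genome whose genes instantiate the transcript
archetypes the pipeline is built to recognize — canonical, short-leader
uORF, 5'-extended (LUTI-like), inefficient-initiation (IIT), internal
transcript isoform (ITI), long 3'UTR, pseudo-bicistronic and pseudogene
pair members, retained intron, and negative control — together with 40S,
80S and RNA-seq density tracks, differential-expression tables, pair
tables, and a per-gene truth record of every planted event.

Design of the stated world:

* Background sequence is drawn from {C, G, T} only, so no start or stop
  codon can arise outside a planted motif (all of AUG/UAA/UAG/UGA need
  an A).  A cleanup pass removes any residual AUG shadow created by
  planted A's on either strand, and a verification pass asserts that
  every AUG a scan finds in a scored region was planted.
* 40S peaks are 5-nt pyramids (weights 1-2-4-2-1) placed at the motif
  position pre-shifted 13 nt upstream, so that the pipeline's P-site
  shift centers them on the motif.  The pyramid mass is chosen so the
  pipeline's peak height equals the intended height exactly (the
  generator inverts the rpm normalization).
* Planted heights: 460 rpkm for leader/start/stop peaks (5x the 92-rpkm
  leader cutoff) and 2740 rpkm for internal-ORF peaks (20x the 137-rpkm
  cutoff) — internal peaks need the larger margin because Poisson
  background inflates the pause-score denominator.
* Differential-expression padj values are assigned (1e-6 for intended
  targets, 1.0 otherwise), never computed: the pipeline's selection
  logic is under test, not the external test's calibration.
* All core arithmetic is integer/rational; floats appear only at track
  write-out, so outputs are byte-identical across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import Annotation, GeneModel, build_extended_leader, revcomp
from .params import Thresholds
from .peaks import scan_motifs
from .tracks import DensityTrack, write_track

log = logging.getLogger(__name__)

MINI_FIXTURE_SEED = 20250815

ARCHETYPES = (
    "canonical",
    "short_leader_uORF",
    "extended_LUTI",
    "IIT",
    "ITI",
    "long_3UTR",
    "bicistronic_pair_member",
    "pseudogene_pair_member",
    "retained_intron",
    "negative_control",
)

DEFAULT_COUNTS = {
    "canonical": 6,
    "short_leader_uORF": 8,
    "extended_LUTI": 8,
    "IIT": 8,
    "ITI": 8,
    "long_3UTR": 6,
    "bicistronic_pair_member": 6,
    "pseudogene_pair_member": 4,
    "retained_intron": 6,
    "negative_control": 4,
}

# archetype -> the rationalization category its geometry encodes
EXPECTED_CATEGORY = {
    "short_leader_uORF": "uORF_short_leader",
    "extended_LUTI": "uORF_extended_LUTI",
    "IIT": "IIT",
    "ITI": "ITI",
    "long_3UTR": "long_3UTR",
    "bicistronic_pair_member": "pseudo_bicistronic",
    "pseudogene_pair_member": "pseudogene",
    "retained_intron": "retained_intron",
}

PYRAMID = (Fraction(1, 10), Fraction(2, 10), Fraction(4, 10), Fraction(2, 10), Fraction(1, 10))


@dataclass(frozen=True)
class PlantedEvent:
    kind: str  # leader_AUG | orf_AUG | main_start | stop
    offset: int  # transcript-relative, first nt of the motif; negative = upstream
    frame: int
    height: float  # intended pipeline peak height, rpkm


@dataclass(frozen=True)
class SyntheticTruth:
    gene_id: str
    archetype: str
    contig: str
    strand: str
    planted_events: Tuple[PlantedEvent, ...]
    intended_log2fc_orf: float
    intended_log2fc_intron: float
    seed: int


@dataclass
class SimConfig:
    """Stated world of the simulator; defaults define the mini fixture."""

    archetype_counts: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    n_contigs: int = 2
    utr5_len: int = 60
    utr3_len: int = 90
    long_utr3_len: int = 600
    orf_len: int = 300  # spliced length incl. start and stop codons
    intron_len: int = 90
    intron_after: int = 150  # ORF nt preceding the intron
    intergenic: int = 600
    contig_pad: int = 700
    uorf_body_len: int = 6  # nt between the uORF AUG and its stop
    short_uorf_distance: int = 48  # nt upstream of the main AUG (<= 100)
    luti_uorf_distance: int = 250  # nt upstream (> 100, beyond the annotated UTR)
    internal_aug_base: int = 150  # +1/+2 adjusts the frame to 1/2
    iti_tss_offset: int = 120  # internal TSS, nt into the ORF
    height_leader: float = 460.0
    height_main_start: float = 460.0
    height_stop: float = 460.0
    height_orf: float = 2740.0
    log2fc_orf: float = 2.0
    log2fc_intron: float = 2.0
    padj_target: float = 1e-6
    padj_null: float = 1.0
    total_reads: float = 1_000_000.0  # per assay
    coverage_80s: int = 3  # raw reads per nt over translated ORFs
    coverage_rnaseq_wt: int = 2  # raw reads per nt over covered spans
    psite_offset_40s: int = 13
    psite_offset_80s: int = 13


def _cgt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(["C", "G", "T"])[rng.integers(0, 3, size=n)])


def transcript_offset_to_genomic(gene: GeneModel, offset: int) -> int:
    """Genomic position of a transcript-relative offset (negative = upstream)."""
    if offset < 0:
        if gene.strand == "+":
            return gene.orf_start + offset
        return gene.orf_end - 1 - offset
    return int(gene.spliced_positions()[offset])


def _upstream_shift(strand: str, pos: int, nt: int) -> int:
    """Move a genomic position ``nt`` toward the 5' end of its strand."""
    return pos - nt if strand == "+" else pos + nt


@dataclass
class _GenePlan:
    gene_id: str
    archetype: str
    contig: str
    strand: str
    utr5: int
    utr3: int
    intron: Optional[Tuple[int, int]]  # ORF-relative genomic interval
    events: List[PlantedEvent]
    tx_start: int = 0  # forward-genomic transcript span
    tx_end: int = 0
    orf_start: int = 0
    orf_end: int = 0


def _plan_genes(config: SimConfig, rng: np.random.Generator) -> List[_GenePlan]:
    plans: List[_GenePlan] = []
    idx = 0
    order: List[str] = []
    for arch in ARCHETYPES:
        order.extend([arch] * config.archetype_counts.get(arch, 0))
    order = [order[i] for i in rng.permutation(len(order))]
    h_l, h_m, h_s, h_o = (
        config.height_leader,
        config.height_main_start,
        config.height_stop,
        config.height_orf,
    )
    for arch in order:
        strand = "+" if idx % 2 == 0 else "-"
        utr3 = config.long_utr3_len if arch == "long_3UTR" else config.utr3_len
        intron = None
        if arch == "retained_intron":
            intron = (config.intron_after, config.intron_after + config.intron_len)
        events: List[PlantedEvent] = []
        if arch in ("short_leader_uORF", "extended_LUTI"):
            d = (
                config.short_uorf_distance
                if arch == "short_leader_uORF"
                else config.luti_uorf_distance
            ) + idx % 3
            stop_off = -d + 3 + config.uorf_body_len
            events.append(PlantedEvent("leader_AUG", -d, (-d) % 3, h_l))
            events.append(PlantedEvent("stop", stop_off, stop_off % 3, h_s))
            events.append(PlantedEvent("main_start", 0, 0, h_m))
        elif arch == "IIT":
            k = config.internal_aug_base + 1 + idx % 2
            events.append(PlantedEvent("orf_AUG", k, k % 3, h_o))
            events.append(PlantedEvent("main_start", 0, 0, h_m))
        elif arch == "ITI":
            k = config.internal_aug_base + 1 + idx % 2
            events.append(PlantedEvent("orf_AUG", k, k % 3, h_o))
        elif arch == "negative_control":
            pass
        else:  # canonical-geometry archetypes keep a main-start scanning peak
            events.append(PlantedEvent("main_start", 0, 0, h_m))
        plans.append(
            _GenePlan(
                gene_id=f"SYN{idx + 1:04d}",
                archetype=arch,
                contig="",
                strand=strand,
                utr5=config.utr5_len,
                utr3=utr3,
                intron=intron,
                events=events,
            )
        )
        idx += 1
    return plans


def _build_transcript(plan: _GenePlan, config: SimConfig, rng: np.random.Generator) -> Tuple[str, List[Tuple[int, int]]]:
    """Transcript sequence 5'->3' and ORF-relative protected motif spans."""
    spliced = config.orf_len
    body = list(_cgt(rng, spliced - 6))
    protected: List[Tuple[int, int]] = [(0, 3), (spliced - 3, spliced)]
    for ev in plan.events:
        if ev.kind == "orf_AUG":
            body[ev.offset - 3 : ev.offset] = list("ATG")
            protected.append((ev.offset, ev.offset + 3))
    orf = "ATG" + "".join(body) + "TAA"
    if plan.intron is not None:
        a, _ = plan.intron
        intron_seq = "GT" + _cgt(rng, config.intron_len - 5) + "CAG"
        orf = orf[:a] + intron_seq + orf[a:]
        protected = [
            (s + (config.intron_len if s >= a else 0), e + (config.intron_len if s >= a else 0))
            for s, e in protected
        ]
    tx = _cgt(rng, plan.utr5) + orf + _cgt(rng, plan.utr3)
    protected = [(s + plan.utr5, e + plan.utr5) for s, e in protected]
    return tx, protected


def generate_genome(
    config: Optional[SimConfig] = None,
    seed: int = MINI_FIXTURE_SEED,
    outdir: Optional[str] = None,
) -> Tuple[Annotation, List[SyntheticTruth]]:
    """Build the synthetic genome, gene models, and truth table.

    Deterministic given ``seed``.  When ``outdir`` is given, writes
    ``genome.fa``, ``genes.gff3`` and ``truth.tsv`` there.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(seed)
    plans = _plan_genes(config, rng)
    n_contigs = max(1, config.n_contigs)
    per_contig = -(-len(plans) // n_contigs)

    contigs: Dict[str, np.ndarray] = {}
    protected_by_contig: Dict[str, np.ndarray] = {}
    genes: Dict[str, GeneModel] = {}
    truths: List[SyntheticTruth] = []

    for ci in range(n_contigs):
        contig = f"chrS{ci + 1}"
        chunk = plans[ci * per_contig : (ci + 1) * per_contig]
        if not chunk:
            continue
        # first pass: geometry
        pos = config.contig_pad
        for plan in chunk:
            plan.contig = contig
            orf_genomic = config.orf_len + (config.intron_len if plan.intron else 0)
            tx_len = plan.utr5 + orf_genomic + plan.utr3
            plan.tx_start, plan.tx_end = pos, pos + tx_len
            if plan.strand == "+":
                plan.orf_start = pos + plan.utr5
            else:
                plan.orf_start = pos + plan.utr3
            plan.orf_end = plan.orf_start + orf_genomic
            pos = plan.tx_end + config.intergenic
        contig_len = pos - config.intergenic + config.contig_pad
        seq = np.array(list(_cgt(rng, contig_len)))
        protected = np.zeros(contig_len, dtype=bool)

        def _mark(lo: int, hi: int) -> None:
            protected[lo:hi] = True

        for plan in chunk:
            tx, tx_protected = _build_transcript(plan, config, rng)
            if plan.strand == "+":
                seq[plan.tx_start : plan.tx_end] = list(tx)
                for s, e in tx_protected:
                    _mark(plan.tx_start + s, plan.tx_start + e)
            else:
                seq[plan.tx_start : plan.tx_end] = list(revcomp(tx))
                for s, e in tx_protected:
                    _mark(plan.tx_end - e, plan.tx_end - s)
            introns: Tuple[Tuple[int, int], ...] = ()
            if plan.intron is not None:
                a, b = plan.intron
                if plan.strand == "+":
                    introns = ((plan.orf_start + a, plan.orf_start + b),)
                else:
                    introns = ((plan.orf_end - b, plan.orf_end - a),)
            gene = GeneModel(
                gene_id=plan.gene_id,
                contig=contig,
                strand=plan.strand,
                orf_start=plan.orf_start,
                orf_end=plan.orf_end,
                introns=introns,
                utr5_len=plan.utr5,
                utr3_len=plan.utr3,
            )
            genes[gene.gene_id] = gene
            # paint leader uORFs (they may lie outside the annotated UTR)
            for ev in plan.events:
                if ev.kind != "leader_AUG":
                    continue
                uorf = "ATG" + _cgt(rng, config.uorf_body_len) + "TAA"
                start_nt = transcript_offset_to_genomic(gene, ev.offset)
                if plan.strand == "+":
                    lo = start_nt
                    seq[lo : lo + len(uorf)] = list(uorf)
                    _mark(lo, lo + 3)
                    _mark(lo + len(uorf) - 3, lo + len(uorf))
                else:
                    hi = start_nt + 1
                    lo = hi - len(uorf)
                    seq[lo:hi] = list(revcomp(uorf))
                    _mark(hi - 3, hi)
                    _mark(lo, lo + 3)
            truths.append(
                SyntheticTruth(
                    gene_id=plan.gene_id,
                    archetype=plan.archetype,
                    contig=contig,
                    strand=plan.strand,
                    planted_events=tuple(plan.events),
                    intended_log2fc_orf=(
                        config.log2fc_orf if _orf_target(plan.archetype) else 0.0
                    ),
                    intended_log2fc_intron=(
                        config.log2fc_intron if plan.archetype == "retained_intron" else 0.0
                    ),
                    seed=seed,
                )
            )
        _cleanup_motifs(seq, protected)
        contigs[contig] = seq
        protected_by_contig[contig] = protected

    annotation = Annotation(
        genome={c: "".join(s) for c, s in contigs.items()}, genes=genes
    )
    _verify_no_confounds(annotation, truths)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(annotation, out / "genome.fa")
        write_gff3(annotation, out / "genes.gff3")
        write_truth(truths, out / "truth.tsv")
    return annotation, truths


def _orf_target(archetype: str) -> bool:
    return archetype in (
        "short_leader_uORF",
        "extended_LUTI",
        "IIT",
        "ITI",
        "long_3UTR",
        "bicistronic_pair_member",
        "pseudogene_pair_member",
    )


def _cleanup_motifs(seq: np.ndarray, protected: np.ndarray) -> None:
    """Mutate away unplanted start/stop motifs on either strand.

    Background sequence is A-free, so stray motifs can only arise where
    background abuts a planted A.  Each unprotected occurrence has a free
    base rewritten to ``C``, rejecting rewrites that would merely trade
    one motif for another; writes are monotone (only ever to ``C``), so
    the fixpoint loop terminates.
    """
    # start and stop codons, forward plus reverse-strand shadows
    patterns = ("ATG", "TAA", "TAG", "TGA", "CAT", "TTA", "CTA", "TCA")
    text = "".join(seq)
    for _ in range(20):
        changed = False
        for pattern in patterns:
            start = 0
            while True:
                i = text.find(pattern, start)
                if i < 0:
                    break
                start = i + 1
                if protected[i : i + 3].all():
                    continue  # the planted motif itself
                done = False
                for k in (1, 2, 0):
                    if protected[i + k] or done:
                        continue
                    for ch in ("C", "G"):
                        if seq[i + k] == ch:
                            continue
                        candidate = pattern[:k] + ch + pattern[k + 1 :]
                        if candidate in patterns:
                            continue  # would just trade one motif for another
                        seq[i + k] = ch
                        changed = done = True
                        break
        if not changed:
            return
        text = "".join(seq)
    raise RuntimeError("motif cleanup did not converge")


def _verify_no_confounds(annotation: Annotation, truths: List[SyntheticTruth]) -> None:
    """Every AUG found in a scored region must be a planted event."""
    thresholds = Thresholds()
    genes = list(annotation.genes.values())
    lengths = annotation.contig_lengths
    for truth in truths:
        gene = annotation.genes[truth.gene_id]
        leader = build_extended_leader(
            gene, genes, thresholds.leader_max_extension, lengths[gene.contig], thresholds
        )
        planted = {
            ev.offset
            for ev in truth.planted_events
            if ev.kind in ("leader_AUG", "orf_AUG")
        }
        found = {
            h.offset
            for h in scan_motifs(annotation.genome, gene, leader, motifs=("start",))
        }
        stray = found - planted
        if stray:
            raise RuntimeError(
                f"{truth.gene_id}: unplanted AUG at transcript offsets {sorted(stray)}"
            )


def write_fasta(annotation: Annotation, path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(annotation.genome):
            fh.write(f">{contig}\n")
            s = annotation.genome[contig]
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")


def write_gff3(annotation: Annotation, path) -> None:
    """GFF3 (1-based inclusive) with gene/CDS/intron/UTR features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        ordered = sorted(
            annotation.genes.values(), key=lambda g: (g.contig, g.orf_start)
        )
        for g in ordered:
            cls = "Dubious" if g.is_dubious else "Verified"
            if g.strand == "+":
                tx_start = g.orf_start - g.utr5_len
                tx_end = g.orf_end + g.utr3_len
                utr5 = (tx_start, g.orf_start)
                utr3 = (g.orf_end, tx_end)
            else:
                tx_start = g.orf_start - g.utr3_len
                tx_end = g.orf_end + g.utr5_len
                utr5 = (g.orf_end, tx_end)
                utr3 = (tx_start, g.orf_start)

            def _line(ftype: str, a: int, b: int, attrs: str) -> None:
                fh.write(
                    f"{g.contig}\tribopeak_sim\t{ftype}\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n"
                )

            _line("gene", tx_start, tx_end, f"ID={g.gene_id};orf_classification={cls}")
            if g.utr5_len:
                _line("five_prime_UTR", utr5[0], utr5[1], f"ID={g.gene_id}_utr5;Parent={g.gene_id}")
            prev = g.orf_start
            for n, (a, b) in enumerate(sorted(g.introns), start=1):
                _line("CDS", prev, a, f"ID={g.gene_id}_cds{n};Parent={g.gene_id}")
                _line("intron", a, b, f"ID={g.gene_id}_intron{n};Parent={g.gene_id}")
                prev = b
            _line("CDS", prev, g.orf_end, f"ID={g.gene_id}_cds{len(g.introns) + 1};Parent={g.gene_id}")
            if g.utr3_len:
                _line("three_prime_UTR", utr3[0], utr3[1], f"ID={g.gene_id}_utr3;Parent={g.gene_id}")


def write_truth(truths: Sequence[SyntheticTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tarchetype\tcontig\tstrand\tplanted_events\t"
            "intended_log2fc_orf\tintended_log2fc_intron\tseed\n"
        )
        for t in truths:
            events = ";".join(
                f"{ev.kind}:{ev.offset}:{ev.frame}:{ev.height:.6g}" for ev in t.planted_events
            )
            fh.write(
                f"{t.gene_id}\t{t.archetype}\t{t.contig}\t{t.strand}\t{events or '.'}\t"
                f"{t.intended_log2fc_orf:.6g}\t{t.intended_log2fc_intron:.6g}\t{t.seed}\n"
            )


def read_truth(path) -> List[SyntheticTruth]:
    truths = []
    df = pd.read_csv(path, sep="\t")
    for _, r in df.iterrows():
        events = []
        if r.planted_events != ".":
            for tok in r.planted_events.split(";"):
                kind, off, frame, height = tok.split(":")
                events.append(PlantedEvent(kind, int(off), int(frame), float(height)))
        truths.append(
            SyntheticTruth(
                r.gene_id,
                r.archetype,
                r.contig,
                r.strand,
                tuple(events),
                float(r.intended_log2fc_orf),
                float(r.intended_log2fc_intron),
                int(r.seed),
            )
        )
    return truths


def _covered_span(gene: GeneModel, truth: SyntheticTruth, config: SimConfig) -> Tuple[int, int]:
    """Forward-genomic interval covered by the gene's RNA-seq isoform."""
    if gene.strand == "+":
        tx = (gene.orf_start - gene.utr5_len, gene.orf_end + gene.utr3_len)
    else:
        tx = (gene.orf_start - gene.utr3_len, gene.orf_end + gene.utr5_len)
    if truth.archetype != "ITI":
        return tx
    # internal TSS: coverage only downstream of it (transcript orientation)
    tss = transcript_offset_to_genomic(gene, config.iti_tss_offset)
    if gene.strand == "+":
        return (tss, tx[1])
    return (tx[0], tss + 1)


def generate_tracks(
    annotation: Annotation,
    truths: Sequence[SyntheticTruth],
    config: Optional[SimConfig] = None,
    noise_rpm: Optional[float] = None,
    seed: int = MINI_FIXTURE_SEED,
    outdir: Optional[str] = None,
) -> Dict[str, object]:
    """Build 40S/80S/RNA-seq tracks plus DE and pair tables.

    ``noise_rpm`` adds per-nucleotide Poisson background of the given
    expected rpm to every assay track (None = noiseless).  Returns a
    dict with raw :class:`DensityTrack` objects (keys ``ribo40S``,
    ``ribo80S``, ``rnaseq_wt``, ``rnaseq_upf1``) and DataFrames
    (``de_orf``, ``de_intron``, ``bicistronic_pairs``,
    ``pseudogene_pairs``).  Writes bedGraph pairs and TSVs under
    ``outdir`` when given.
    """
    if config is None:
        config = SimConfig()
    lengths = annotation.contig_lengths
    scale = Fraction(int(config.total_reads), 1_000_000)

    def _empty() -> Dict[str, Dict[str, np.ndarray]]:
        return {
            c: {s: np.zeros(n, dtype=np.float64) for s in ("+", "-")}
            for c, n in lengths.items()
        }

    data40 = _empty()
    data80 = _empty()
    data_wt = _empty()
    data_upf1 = _empty()

    de_orf_rows: List[dict] = []
    de_intron_rows: List[dict] = []

    for truth in truths:
        gene = annotation.genes[truth.gene_id]
        arr40 = data40[gene.contig][gene.strand]
        # 40S pyramids, pre-shifted upstream so the P-site shift recenters them
        for ev in truth.planted_events:
            raw_sum = Fraction(ev.height).limit_denominator(10**9) / 200 * scale
            if raw_sum < 1:
                needed = int(-(-200 * 1_000_000 // Fraction(ev.height).limit_denominator(10**9)))
                raise ValueError(
                    f"{gene.gene_id}: intended height {ev.height} rpkm unreachable at "
                    f"{config.total_reads:.0f} reads; needs >= {needed} total reads"
                )
            motif_pos = transcript_offset_to_genomic(gene, ev.offset)
            center = _upstream_shift(gene.strand, motif_pos, config.psite_offset_40s)
            for k, w in enumerate(PYRAMID, start=-2):
                arr40[center + k] += float(raw_sum * w)
        # 80S coverage over the spliced ORF, pre-shifted
        arr80 = data80[gene.contig][gene.strand]
        if truth.archetype != "negative_control":
            pos = gene.spliced_positions()
            arr80[_upstream_shift(gene.strand, pos, config.psite_offset_80s)] += config.coverage_80s
        # RNA-seq coverage per condition (unshifted)
        lo, hi = _covered_span(gene, truth, config)
        wt_cov = config.coverage_rnaseq_wt
        fold = 2.0 ** truth.intended_log2fc_orf
        if truth.archetype == "retained_intron":
            fold = 1.0  # exonic abundance unchanged; only the intron accumulates
        upf1_cov = wt_cov * fold
        data_wt[gene.contig][gene.strand][lo:hi] += wt_cov
        data_upf1[gene.contig][gene.strand][lo:hi] += upf1_cov
        if truth.archetype == "retained_intron":
            intron_fold = 2.0 ** truth.intended_log2fc_intron
            for a, b in gene.introns:
                data_upf1[gene.contig][gene.strand][a:b] += wt_cov * (intron_fold - 1.0)
        # DE tables: exact log2fc of simulated means, padj assigned
        span = hi - lo
        wt_count, upf1_count = wt_cov * span, upf1_cov * span
        orf_target = _orf_target(truth.archetype)
        de_orf_rows.append(
            {
                "gene_id": gene.gene_id,
                "feature": "orf",
                "log2fc": truth.intended_log2fc_orf if orf_target else 0.0,
                "padj": config.padj_target if orf_target else config.padj_null,
                "mean_expression": (wt_count + upf1_count) / 2.0,
            }
        )
        if gene.introns:
            intron_target = truth.archetype == "retained_intron"
            n_int = sum(b - a for a, b in gene.introns)
            de_intron_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "feature": "intron",
                    "log2fc": truth.intended_log2fc_intron if intron_target else 0.0,
                    "padj": config.padj_target if intron_target else config.padj_null,
                    "mean_expression": wt_cov * n_int * (1 + 2.0 ** truth.intended_log2fc_intron) / 2.0,
                }
            )

    if noise_rpm is not None and noise_rpm > 0:
        lam = noise_rpm * float(scale)
        noise_rng = np.random.default_rng([seed, 7])
        for name, data in (
            ("ribo40S", data40),
            ("ribo80S", data80),
            ("rnaseq_wt", data_wt),
            ("rnaseq_upf1", data_upf1),
        ):
            for contig in sorted(data):
                for strand in ("+", "-"):
                    data[contig][strand] += noise_rng.poisson(
                        lam, size=data[contig][strand].size
                    )

    tracks = {
        "ribo40S": DensityTrack("ribo40S", data40, "raw", config.total_reads),
        "ribo80S": DensityTrack("ribo80S", data80, "raw", config.total_reads),
        "rnaseq_wt": DensityTrack("rnaseq", data_wt, "raw", config.total_reads),
        "rnaseq_upf1": DensityTrack("rnaseq", data_upf1, "raw", config.total_reads),
    }

    de_orf = pd.DataFrame(de_orf_rows, columns=["gene_id", "feature", "log2fc", "padj", "mean_expression"])
    de_intron = pd.DataFrame(de_intron_rows, columns=["gene_id", "feature", "log2fc", "padj", "mean_expression"])

    bic = [t.gene_id for t in truths if t.archetype == "bicistronic_pair_member"]
    pse = [t.gene_id for t in truths if t.archetype == "pseudogene_pair_member"]
    bic_pairs = pd.DataFrame(
        [{"gene_a": bic[i], "gene_b": bic[i + 1], "source": "synthetic"} for i in range(0, len(bic) - 1, 2)],
        columns=["gene_a", "gene_b", "source"],
    )
    pse_pairs = pd.DataFrame(
        [{"gene_a": pse[i], "gene_b": pse[i + 1], "source": "synthetic"} for i in range(0, len(pse) - 1, 2)],
        columns=["gene_a", "gene_b", "source"],
    )

    result: Dict[str, object] = dict(tracks)
    result.update(
        de_orf=de_orf,
        de_intron=de_intron,
        bicistronic_pairs=bic_pairs,
        pseudogene_pairs=pse_pairs,
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, track in tracks.items():
            write_track(track, out / f"{name}.plus.bedgraph", out / f"{name}.minus.bedgraph")
        de_orf.to_csv(out / "de_orf.tsv", sep="\t", index=False, float_format="%.6g")
        de_intron.to_csv(out / "de_intron.tsv", sep="\t", index=False, float_format="%.6g")
        bic_pairs.to_csv(out / "bicistronic_pairs.tsv", sep="\t", index=False)
        pse_pairs.to_csv(out / "pseudogene_pairs.tsv", sep="\t", index=False)
    return result


def simulate(
    config: Optional[SimConfig] = None,
    seed: int = MINI_FIXTURE_SEED,
    noise_rpm: Optional[float] = None,
    outdir: Optional[str] = None,
) -> Tuple[Annotation, List[SyntheticTruth], Dict[str, object]]:
    """Genome + tracks + tables in one call (the packaged mini fixture
    is ``simulate(seed=20250815, noise_rpm=None)``)."""
    annotation, truths = generate_genome(config, seed, outdir)
    bundle = generate_tracks(annotation, truths, config, noise_rpm, seed, outdir)
    return annotation, truths, bundle


def evaluate_recovery(
    classifications: pd.DataFrame,
    truths: Sequence[SyntheticTruth],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-archetype precision/recall and an archetype x category confusion table.

    ``classifications`` is the pipeline's per-gene table (must contain
    ``gene_id`` and a comma-joined ``rationalization`` column).  For
    archetypes whose geometry encodes a category, recall is the fraction
    of truth genes whose rationalization contains that category, and
    precision the fraction of genes assigned the category that belong to
    the archetype.  Canonical/negative-control genes are correct when
    absent from the report.  Precision is NaN (flagged) for categories
    never predicted.
    """
    truth_by_id = {t.gene_id: t for t in truths}
    unknown = set(classifications["gene_id"]) - set(truth_by_id)
    if unknown:
        raise ValueError(f"classification report contains unknown gene ids: {sorted(unknown)}")
    assigned: Dict[str, Set[str]] = {}
    for _, r in classifications.iterrows():
        assigned[r.gene_id] = set(str(r.rationalization).split(","))

    categories = sorted(set(EXPECTED_CATEGORY.values()) | {"unexplained"})
    confusion = pd.DataFrame(
        0, index=list(ARCHETYPES), columns=categories + ["not_reported"], dtype=int
    )
    for t in truths:
        cats = assigned.get(t.gene_id)
        if cats is None:
            confusion.loc[t.archetype, "not_reported"] += 1
        else:
            for c in cats:
                if c in confusion.columns:
                    confusion.loc[t.archetype, c] += 1

    rows = []
    for arch in ARCHETYPES:
        members = [t for t in truths if t.archetype == arch]
        if not members:
            continue
        expected = EXPECTED_CATEGORY.get(arch)
        if expected is None:
            hits = sum(1 for t in members if t.gene_id not in assigned)
            recall = hits / len(members)
            precision, flag = float("nan"), "precision_not_applicable"
        else:
            hits = sum(1 for t in members if expected in assigned.get(t.gene_id, set()))
            recall = hits / len(members)
            predicted = [gid for gid, cats in assigned.items() if expected in cats]
            if predicted:
                correct = sum(1 for gid in predicted if truth_by_id[gid].archetype == arch)
                precision, flag = correct / len(predicted), ""
            else:
                precision, flag = float("nan"), "precision_undefined"
        rows.append(
            {
                "archetype": arch,
                "n_genes": len(members),
                "recall": recall,
                "precision": precision,
                "flag": flag,
            }
        )
    metrics = pd.DataFrame(rows, columns=["archetype", "n_genes", "recall", "precision", "flag"])
    return metrics, confusion
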