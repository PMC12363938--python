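"""Gene models, genome access, and extended 5' leader construction.

Internally every interval is 0-based half-open on the forward genomic
strand; GFF3 (1-based inclusive) is converted at the I/O boundary.  All
transcript-relative arithmetic (leader offsets, spliced ORF positions) is
strand-aware: "upstream" means smaller genomic coordinates on ``+`` genes
and larger ones on ``-`` genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .params import Thresholds

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene's ORF, introns and UTR annotation.

    ``orf_start``/``orf_end`` span the genomic ORF interval including the
    stop codon; ``introns`` lie strictly inside it.  ``utr5_len`` and
    ``utr3_len`` are annotated transcript-leader / trailer lengths in nt.
    """

    gene_id: str
    contig: str
    strand: str
    orf_start: int
    orf_end: int
    introns: Tuple[Tuple[int, int], ...] = ()
    utr5_len: int = 0
    utr3_len: int = 0
    is_dubious: bool = False
    overlaps_other: bool = False
    malformed: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.orf_start < self.orf_end:
            raise ValueError(f"{self.gene_id}: orf_start must be < orf_end")
        for a, b in self.introns:
            if not (self.orf_start < a < b < self.orf_end):
                raise ValueError(f"{self.gene_id}: intron [{a},{b}) not inside ORF")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.gene_id}: UTR lengths must be >= 0")

    @property
    def eligible(self) -> bool:
        """Scored by the pipeline: not dubious, overlapping, or malformed."""
        return not (self.is_dubious or self.overlaps_other or self.malformed)

    @property
    def start_codon_pos(self) -> int:
        """Genomic coordinate of the first nt of the start codon."""
        return self.orf_start if self.strand == "+" else self.orf_end - 1

    @property
    def stop_codon_pos(self) -> int:
        """Genomic coordinate of the first (5'-most) nt of the stop codon."""
        return self.orf_end - 3 if self.strand == "+" else self.orf_start + 2

    @property
    def intron_length(self) -> int:
        return sum(b - a for a, b in self.introns)

    @property
    def spliced_length(self) -> int:
        return (self.orf_end - self.orf_start) - self.intron_length

    def spliced_positions(self) -> np.ndarray:
        """Genomic coordinates of spliced ORF positions in 5'->3' transcript order."""
        keep = np.ones(self.orf_end - self.orf_start, dtype=bool)
        for a, b in self.introns:
            keep[a - self.orf_start : b - self.orf_start] = False
        pos = np.nonzero(keep)[0] + self.orf_start
        return pos if self.strand == "+" else pos[::-1]

    def spliced_seq(self, genome: Dict[str, str]) -> str:
        seq = genome[self.contig]
        parts: List[str] = []
        prev = self.orf_start
        for a, b in sorted(self.introns):
            parts.append(seq[prev:a])
            prev = b
        parts.append(seq[prev : self.orf_end])
        s = "".join(parts).upper()
        return s if self.strand == "+" else revcomp(s)

    def utr3_interval(self) -> Tuple[int, int]:
        if self.strand == "+":
            return (self.orf_end, self.orf_end + self.utr3_len)
        return (self.orf_start - self.utr3_len, self.orf_start)


@dataclass(frozen=True)
class ExtendedLeader:
    """Upstream search region abutting the main start codon.

    ``region`` is the genomic half-open interval; ``length`` its width.
    ``truncated_by`` records which bound stopped the extension:
    ``upstream_orf`` (nearest eligible ORF body), ``max_extension``, or
    ``contig_edge``.  Offsets into the leader are measured upstream from
    the A of the main AUG: offset 1 is the nt immediately 5' of it.
    """

    gene_id: str
    contig: str
    strand: str
    start_codon_pos: int
    region: Tuple[int, int]
    length: int
    truncated_by: str

    def to_genomic(self, offset_from_start: int) -> int:
        """Map a leader offset (1..length, upstream from the main AUG) to a genomic position."""
        if not 0 < offset_from_start <= self.length:
            raise ValueError(
                f"{self.gene_id}: leader offset {offset_from_start} out of range 1..{self.length}"
            )
        if self.strand == "+":
            return self.start_codon_pos - offset_from_start
        return self.start_codon_pos + offset_from_start

    def from_genomic(self, pos: int) -> int:
        """Inverse of :meth:`to_genomic`."""
        off = (self.start_codon_pos - pos) if self.strand == "+" else (pos - self.start_codon_pos)
        if not 0 < off <= self.length:
            raise ValueError(f"{self.gene_id}: genomic position {pos} not in leader")
        return off

    def sequence(self, genome: Dict[str, str]) -> str:
        """Leader sequence 5'->3' in transcript orientation (ends just before the main AUG)."""
        a, b = self.region
        s = genome[self.contig][a:b].upper()
        return s if self.strand == "+" else revcomp(s)


@dataclass
class Annotation:
    """Loaded genome + gene models."""

    genome: Dict[str, str]
    genes: Dict[str, GeneModel]

    @property
    def contig_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def eligible_genes(self) -> List[GeneModel]:
        return [g for g in self.genes.values() if g.eligible]


def _utr_len(db: gffutils.FeatureDB, gene_feature, featuretype: str) -> int:
    total = 0
    for f in db.children(gene_feature, featuretype=featuretype):
        total += f.end - f.start + 1
    return total


def load_annotation(
    gff_path: str,
    fasta_path: str,
    dubious_key: str = "orf_classification",
    dubious_value: str = "Dubious",
) -> Annotation:
    """Load a GFF3 + FASTA pair into :class:`Annotation`.

    GFF3 features used: ``gene`` (with the dubious-classification
    attribute), child ``CDS`` parts (their span defines the ORF), child
    ``intron`` features, and ``five_prime_UTR`` / ``three_prime_UTR``
    whose summed lengths give the UTR annotations.  Genes whose spliced
    ORF length is not a positive multiple of 3 are loaded but flagged
    malformed and excluded from scoring; genes whose ORF intervals
    overlap another gene's ORF are flagged ``overlaps_other``.
    """
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
    }
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: Dict[str, GeneModel] = {}
    for gf in db.features_of_type("gene"):
        gene_id = gf.id
        if gf.seqid not in genome:
            raise ValueError(
                f"gene {gene_id}: contig {gf.seqid!r} missing from FASTA"
            )
        cds = list(db.children(gf, featuretype="CDS"))
        if cds:
            orf_start = min(c.start for c in cds) - 1
            orf_end = max(c.end for c in cds)
        else:
            orf_start, orf_end = gf.start - 1, gf.end
        introns = tuple(
            sorted((f.start - 1, f.end) for f in db.children(gf, featuretype="intron"))
        )
        is_dubious = dubious_value in gf.attributes.get(dubious_key, [])
        model = GeneModel(
            gene_id=gene_id,
            contig=gf.seqid,
            strand=gf.strand,
            orf_start=orf_start,
            orf_end=orf_end,
            introns=introns,
            utr5_len=_utr_len(db, gf, "five_prime_UTR"),
            utr3_len=_utr_len(db, gf, "three_prime_UTR"),
            is_dubious=is_dubious,
        )
        if model.spliced_length % 3 != 0:
            log.warning(
                "gene %s: spliced ORF length %d not a multiple of 3; flagged malformed",
                gene_id,
                model.spliced_length,
            )
            model = replace(model, malformed=True)
        genes[gene_id] = model

    # flag ORF-interval overlaps between distinct genes (either strand)
    by_contig: Dict[str, List[GeneModel]] = {}
    for g in genes.values():
        by_contig.setdefault(g.contig, []).append(g)
    overlapping: set = set()
    for contig_genes in by_contig.values():
        contig_genes.sort(key=lambda g: g.orf_start)
        for i, g in enumerate(contig_genes):
            for h in contig_genes[i + 1 :]:
                if h.orf_start >= g.orf_end:
                    break
                overlapping.add(g.gene_id)
                overlapping.add(h.gene_id)
    for gid in overlapping:
        genes[gid] = replace(genes[gid], overlaps_other=True)
    return Annotation(genome=genome, genes=genes)


def build_extended_leader(
    gene: GeneModel,
    genes: Iterable[GeneModel],
    max_extension: int,
    contig_length: int,
    thresholds: Optional[Thresholds] = None,
    length_override: Optional[int] = None,
) -> ExtendedLeader:
    """Construct the upstream search region for one gene.

    The annotated 5'UTR is extended upstream to the nearest boundary of
    an upstream ORF body, to ``max_extension`` nt, or to the contig edge,
    whichever comes first.  Extension never shrinks the annotation: a
    5'UTR annotated longer than the computed extension keeps its
    annotated length.  ``length_override`` supports per-gene hand
    annotation of outliers that extend beyond the configured maximum.
    """
    if thresholds is None:
        thresholds = Thresholds()
    if gene.is_dubious:
        raise ValueError(f"{gene.gene_id}: leaders are not built for dubious genes")
    start = gene.start_codon_pos
    # available upstream space to the contig edge
    if gene.strand == "+":
        edge_space = gene.orf_start
    else:
        edge_space = contig_length - gene.orf_end

    obstacle_space = None
    for other in genes:
        if other.gene_id == gene.gene_id:
            continue
        if other.contig != gene.contig:
            continue
        if other.is_dubious and not thresholds.obstacles_include_dubious:
            continue
        if thresholds.obstacles_same_strand_only and other.strand != gene.strand:
            continue
        if gene.strand == "+":
            if other.orf_end <= gene.orf_start:
                d = gene.orf_start - other.orf_end
            elif other.orf_start < gene.orf_start:
                d = 0  # overlapping body intrudes into the leader space
            else:
                continue
        else:
            if other.orf_start >= gene.orf_end:
                d = other.orf_start - gene.orf_end
            elif other.orf_end > gene.orf_end:
                d = 0
            else:
                continue
        obstacle_space = d if obstacle_space is None else min(obstacle_space, d)

    if length_override is not None:
        length, truncated_by = min(length_override, edge_space), "max_extension"
        if length == edge_space < length_override:
            truncated_by = "contig_edge"
    else:
        length, truncated_by = max_extension, "max_extension"
        if obstacle_space is not None and obstacle_space < length:
            length, truncated_by = obstacle_space, "upstream_orf"
        if edge_space < length:
            length, truncated_by = edge_space, "contig_edge"
        if gene.utr5_len > length:
            # the annotated UTR is never shrunk by the extension bounds
            length = min(gene.utr5_len, edge_space)
            if length == edge_space < gene.utr5_len:
                truncated_by = "contig_edge"

    if gene.strand == "+":
        region = (start - length, start)
    else:
        region = (start + 1, start + 1 + length)
    return ExtendedLeader(
        gene_id=gene.gene_id,
        contig=gene.contig,
        strand=gene.strand,
        start_codon_pos=start,
        region=region,
        length=length,
        truncated_by=truncated_by,
    )


def leader_coords_to_genomic(leader: ExtendedLeader, offset_from_start: int) -> int:
    """Functional alias for :meth:`ExtendedLeader.to_genomic`."""
    return leader.to_genomic(offset_from_start)


def read_leader_overrides(path: str) -> Dict[str, int]:
    """Read a per-gene leader-length override table (gene_id <TAB> length)."""
    overrides: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id"):
                continue
            gid, length = line.split("\t")[:2]
            overrides[gid] = int(length)
    return overrides
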