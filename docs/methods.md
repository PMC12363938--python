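# Methods

This note documents the models, parameter semantics, numerical choices
and limitations behind `ribopeak`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model of the data

The package starts from strand-specific per-nucleotide counts of
footprint 5' ends — it deliberately does not model reads. Alignment,
UMI handling and length filtering belong upstream; a `DensityTrack` is
the interface. Counts are non-negative floats per contig per strand,
with a `total_mapped` library size taken from a `#total_mapped=` header
when present (so rpm can refer to the full library even when only some
contigs are loaded) and from the count sum otherwise.

P-site assignment is a constant shift of 5'-end counts in the 5'→3'
direction of each strand: 13 nt for 80S footprints, and for 40S
footprints 14 nt in gene-level quantitation but 13 nt in peak scoring.
The two 40S offsets are deliberate: the quantitation and peak-scoring
stages are calibrated independently, and each stage reads its own
configured offset (`psite_offset_40s_quant`, `psite_offset_40s_peaks`).
RNA-seq is never shifted.

## Peak statistics

For a motif whose first nucleotide (after shifting) is position *i*:

- **Pause score** = `x_i / mean(x_{i-50..i+50})`. The denominator
  includes the motif position, so a uniform track scores exactly 1 and
  the score is bounded by the window length (101). An exclusive-window
  variant is available (`pause_include_center=False`). Windows are
  truncated at contig edges and the mean taken over the effective
  window; an all-zero window yields NaN with a `zero_window` flag.
- **Peak height** = rpm summed over the centered 5-nt window, divided
  by the window length in kb (×200 for 5 nt), i.e. the rpkm of the
  peak region. When the window is truncated the divisor is the
  effective length. The alternative reading of "height" as a
  single-position maximum is not implemented as a separate statistic;
  the summation window width is configurable (`peak_sum_window`, odd).

Leader AUG peaks are called on height alone (strictly > 92 rpkm):
background variability in 5'UTRs makes the pause-score denominator
unreliable there. ORF-internal AUG peaks must pass pause score > 10
AND height > 137 rpkm, reflecting the higher 40S background inside
ORFs caused by artifactual dissociation of 80S ribosomes during sample
preparation. All comparisons against thresholds are strict.

Artifact filters, applied as flags (peaks stay in the report, leave
the evidence set): frame-0 leader AUGs with no in-frame stop before
the main start (`frame0_misannotated_start` — the "peak" is the true
start of a misannotated ORF); frame-0 internal AUGs
(`frame0_internal_start`); AUGs whose next codon in their own frame is
a stop (`aug_adjacent_stop` — the 40S signal belongs to the
termination site, not to initiation). Curation lists can force peaks
in (`manual_add`: bypasses the pause-score conjunct, keeps the height
conjunct unless the note says `force`) or out (`manual_remove`).

Stop-codon peaks are scanned with the same height machinery but are
annotation-only: they corroborate a uORF/iORF's termination site and
never gate classification.

Main-start peak presence (the IIT/ITI discriminator) reuses the
92-rpkm leader height criterion; only "presence or absence" of the
peak matters, and a single threshold keeps the decision reproducible.

## Extended leaders

The 5'UTR search region is the annotated leader extended upstream to
the nearest ORF-body boundary, to `leader_max_extension` (2000 nt;
3000 nt variant for outlier detection), or to the contig edge —
whichever is closest. Obstacles include dubious ORFs on either strand
(configurable): peaks over another gene's body would be unattributable
regardless of that gene's annotation status. Annotated 5'UTRs longer
than the computed bound are never shrunk. A per-gene length-override
table handles hand-annotated outliers that extend beyond the maximum;
no general rule exists for them. Leader offsets are measured upstream
from the A of the main AUG (offset 1 = the adjacent nucleotide),
strand-aware.

## Classification

Selection from differential-expression tables uses strict
inequalities: `padj < 0.01` (ORF counts) or `padj < 0.05` (intron
counts) AND `log2fc > 1`. Fold change is evaluated on the table's
reported log2fc; whether shrinkage was applied upstream is the table
producer's concern. Intron-selected genes are flagged retained-intron
candidates. Records with missing padj are skipped with a warning.

The decision tree, deterministic and total over the evidence flags:

- leader class: `extended_5p` iff the 5'-most surviving leader peak is
  strictly > 100 nt upstream (the cutoff ~ the genome-average 5'UTR
  length); `short_5p_utr` iff peaks exist at or within 100 nt. The
  alternative keying on annotated 5'UTR length instead of peak
  position is config-selectable (`leader_class_by_peak_position`);
  peak position is the default because the peak, not the annotation,
  is the observed event.
- ORF class: ITI iff (ORF peaks AND no main-start peak) OR a positive
  split-count test; IIT iff ORF peaks AND main-start peak AND negative
  split test. The split test overrides IIT: direct RNA-seq evidence of
  a truncated isoform outweighs the start-peak inference.
- Split-count test (on the NMD-deficient-condition RNA-seq track): raw
  counts in the last vs first 100 nt of the spliced ORF, positive iff
  strictly > 2-fold. ORFs shorter than 200 nt are untestable. With a
  zero first window the ratio is undefined; the test is then positive
  only if the last window holds ≥ 10 raw reads
  (`min_informative_reads`) — an undocumented corner that needed a
  floor so single stray reads cannot drive calls.
- Long 3'UTR: annotated 3'UTR length > mean + 2 SD over all annotated
  genes (population SD; the sample-SD variant differs negligibly at
  genome scale and is selectable).
- Pseudo-bicistronic and pseudogene explanations are consumption-only
  (curated pair tables); a pair is counted once even when both members
  are NMD-sensitive.

A gene's rationalization reports the leader and ORF classes together
when both apply (two NMD-sensitive isoforms of one gene are common),
always appends retained_intron when flagged, and falls back to the
structural explanations — in the declared order long_3UTR →
pseudo_bicistronic → pseudogene — only when there is no peak evidence.
No ordering of multiple structural explanations is inherent to the
biology; the order is declared so outputs are stable. Anything left is
`unexplained`.

## Synthetic data

The generator emulates the *phenomenology* the pipeline consumes: 40S
peaks at start codons and at uORF stop codons, 80S coverage over
translated ORFs, per-isoform RNA-seq coverage, and condition-dependent
abundance differences. It does not emulate read-level noise sources
(ligation bias, mappability, codon-level dynamics), so a green test
establishes the correctness of the scoring/classification logic on
well-formed tracks, not robustness to library artifacts.

Stated world (defaults; chosen once, not tuned):

- ~64 genes on 2 contigs; ORFs 300 nt spliced, 5'UTRs 60 nt, 3'UTRs
  90 nt (600 nt for long-3'UTR genes), 600-nt intergenic gaps, genes
  alternating strands. Retained-intron genes carry one 90-nt intron.
- Background sequence uses only C/G/T, so every start or stop codon is
  planted; a cleanup pass removes motif shadows created where
  background abuts a planted A (on either strand), and a verification
  scan asserts that scored regions contain no unplanted AUG.
- 40S peaks are 5-nt pyramids (weights 1-2-4-2-1) — a shape that
  exercises the 5-nt summation window non-trivially — placed 13 nt
  upstream of the motif so the pipeline's P-site shift recenters them,
  with mass chosen (by exact rational arithmetic) so the pipeline's
  height equals the intended height after rpm normalization.
- Intended heights: 460 rpkm for leader/main-start/stop peaks (5× the
  92-rpkm cutoff) and 2740 rpkm for internal-ORF peaks (20× the
  137-rpkm cutoff). The internal peaks need the larger margin because
  Poisson background inflates the pause-score denominator: with
  background λ rpm/nt the score of a pyramid with 5-nt rpm sum *s* is
  ≈ 40.4·s/(s + 101λ), which for λ = 0.2 crosses the 10-fold cutoff
  only near 1330 rpkm. 460 rpkm would pass noiselessly but not under
  background; 2740 rpkm passes with a comfortable margin.
- uORFs are AUG + 6 nt + UAA, planted ~48 nt (short-leader) or ~250 nt
  (5'-extended) upstream, cycling frames across genes; internal AUGs
  sit ~151 nt into the ORF in frames 1/2; ITI genes receive RNA-seq
  coverage only downstream of an internal TSS 120 nt into the ORF
  (yielding the split-count signature with a zero first window).
- RNA-seq coverage 2 reads/nt (wild type), ×4 in the NMD-deficient
  condition for intended targets (log2fc exactly 2); retained-intron
  genes instead gain intron-only coverage. 80S coverage 3 reads/nt
  over ORFs. Library sizes 1e6 per assay, recorded in track headers.
- DE padj values are assigned (1e-6 targets, 1.0 otherwise), never
  computed: the pipeline's selection logic is under test, not an
  external statistical test's calibration.
- Optional noise: per-nucleotide Poisson background with a given
  expected rpm, added to all assays. Planted signal is additive, so
  height-gated calls cannot be lost to noise; only the ratio-based
  pause score is at risk (hence the ORF-peak margin above).
- Determinism: the generator core uses integer/rational arithmetic and
  a single seeded RNG; floats appear only at write-out, and all
  writers use fixed formats, so outputs are byte-identical across runs.

## Numerical and I/O choices

- Internal coordinates are 0-based half-open on the forward strand;
  GFF3 (1-based inclusive) and wiggle (1-based) convert at the I/O
  boundary; bedGraph is the canonical on-disk dialect (one file per
  strand, `.plus`/`.minus`).
- Peaks are reported 5'→3' in transcript orientation; the "5'-most"
  peak used by leader classification is the most upstream surviving
  one. Overlapping peak windows are scored independently (no
  non-maximum suppression): genuinely adjacent initiation sites are
  reported separately.
- `summarize` uses exact integer counting; the leader-only / ORF-only /
  both / neither counts partition the classified set by construction.
- The pipeline is deterministic end to end; `run.log` (which carries
  wall-clock timers) and `resolved_config.yaml` (which carries
  machine-specific input paths) are the only outputs excluded from
  byte-level golden comparison.

## Known limitations

- Consumes density tracks, not reads: read-length filtering, UMI
  deduplication and multimapper policy are out of scope.
- The differential-expression model is external; tables are consumed
  as-is.
- No de novo P-site offset learning; offsets are configured constants.
- Pseudogene/bicistronic pair lists are curated inputs; the package
  does not derive them from comparative genomics.
- No detection of programmed frameshifting or non-AUG initiation.
- The paper-scale headline counts (hundreds of NMD targets per
  category) require the original deep-sequencing libraries and genome
  annotation; the synthetic world validates logic, not those numbers.
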