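# ribopeak

40S ribosome-profiling peak calling and mechanistic classification of
NMD-sensitive transcripts.

## The problem

Nonsense-mediated mRNA decay (NMD) degrades transcripts that terminate
translation prematurely, but for most NMD targets the transcriptome
annotation shows no premature termination codon. Small-subunit (40S)
ribosome profiling makes the missing events visible: scanning/initiating
40S subunits pile up at start codons, so cryptic initiation sites — uORFs
in (possibly 5'-extended) transcript leaders and out-of-frame AUGs inside
coding sequences — leave sharp 40S peaks even when the resulting ORFs are
invisible in elongating-ribosome (80S) data.

`ribopeak` turns strand-specific per-nucleotide density tracks (40S, 80S,
RNA-seq) plus a genome annotation and differential-expression results
into a mechanistic account of each NMD-sensitive gene. It is a library:
you import it, or adapt the short scripts in `examples/`.

## The method

**Selection.** Genes upregulated strictly >2-fold in the NMD-deficient
condition with padj < 0.01 on main-ORF counts, or padj < 0.05 on intron
counts (intron selection also flags retained-intron candidates).

**Peak scoring.** Footprint 5' ends are rpm-normalized and shifted 13 nt
to the P-site. For a motif at position *i*,

- pause score = `x_i / mean(x_{i-50} .. x_{i+50})` (fold enrichment over a
  101-nt window),
- peak height = the rpm sum over the centered 5-nt window per kb
  (`rpm_sum x 200`), in rpkm.

AUGs are scanned in all three frames across the annotated 5'UTR extended
upstream — to the nearest upstream ORF body or at most 2 kb (3 kb variant
for outlier hunting) — and across the spliced ORF. Leader peaks are
called on height alone (> 92 rpkm); ORF-internal peaks must pass both the
pause score (> 10-fold) and a stricter height cutoff (> 137 rpkm).
Frame-0 artifacts (misannotated starts, internal starts) and AUGs
immediately abutting a stop codon are flagged and excluded; manual
curation lists can force peaks in or out.

**Classification.** The 5'-most surviving leader peak > 100 nt upstream
of the main AUG ⇒ 5'-extended (LUTI-like) uORF transcript; within 100 nt
⇒ short-leader uORF transcript. ORF peaks split into IIT (inefficient
initiation: 40S peak at the main start) versus ITI (internal transcript
isoform: no main-start peak, or a positive RNA-seq split-count test —
last-100-nt / first-100-nt ratio strictly > 2 — which overrides IIT).
Genes with no peaks fall back to structural explanations: 3'UTR longer
than mean + 2 SD of annotated lengths, pseudo-bicistronic pair
membership, or pseudogene pair membership; intron-selected genes always
report retained_intron.

**Synthetic data.** `ribopeak.simdata` generates a deterministic toy
genome in which every one of these transcript archetypes is planted with
known peak positions, heights and fold-changes, so each stage of the
pipeline is testable without sequencing data.

## Worked example

```bash
python examples/02_call_peaks.py
```

prints, for one 5'-extended gene of the synthetic fixture:

```
SYN0014: - strand, ORF 15220-15520, leader search region 720 nt (stopped by upstream_orf)
  leader AUG at  -251 (frame 1): score   20.2, height   460.0 rpkm -> CALLED
  main-start 40S peak: height 460.0 rpkm -> present
```

The leader AUG sits 251 nt upstream of the main start — beyond the
100-nt cutoff — so this gene is classified `uORF_extended_LUTI`: a
5'-extended transcript whose uORF translation terminates prematurely and
triggers NMD. Running the whole pipeline
(`python examples/04_full_pipeline.py`) classifies all 54 NMD-selected
fixture genes (100% rationalized) and prints the per-category counts and
the long-3'UTR cutoff (435.1 nt on the fixture annotation).

Other examples: `01_simulate_fixture.py` (what the generator plants),
`03_select_nmd_genes.py` (selection boundaries), `05_evaluate_recovery.py`
(precision/recall against planted truth under Poisson background noise).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic fixture under the given seed with Poisson
background noise (0.2 rpm/nt), runs every pipeline stage from scratch,
evaluates recovery against the planted truth, and prints the summary and
per-archetype precision/recall before writing the results JSON.

## Layout

- `src/ribopeak/annotation.py` — gene models, GFF3/FASTA loading, extended-leader construction
- `src/ribopeak/tracks.py` — bedGraph/wiggle tracks, P-site shift, rpm, region counts, split-count
- `src/ribopeak/peaks.py` — motif scanning, pause score/height, peak calls, curation
- `src/ribopeak/classify.py` — NMD selection, decision tree, summaries
- `src/ribopeak/simdata.py` — synthetic genome/tracks/truth generator, recovery evaluation
- `src/ribopeak/pipeline.py` — configuration and end-to-end orchestration
- `docs/methods.md` — modelling assumptions, parameter semantics, numerical choices
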