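"""Score and call 40S peaks for one gene of the synthetic fixture.

Shows the two-stage preparation (rpm normalization, 13-nt P-site shift),
the pause score and peak height of each candidate AUG, and which calls
survive the thresholds (leaders: height > 92 rpkm; ORF-internal AUGs:
pause score > 10 AND height > 137 rpkm).
"""

import ribopeak as rp

th = rp.Thresholds()
annotation, truths, bundle = rp.simulate(seed=rp.MINI_FIXTURE_SEED)

track = rp.shift_psite(rp.normalize_rpm(bundle["ribo40S"]), th.psite_offset_40s_peaks)

gene_id = next(t.gene_id for t in truths if t.archetype == "extended_LUTI")
gene = annotation.genes[gene_id]
genes = list(annotation.genes.values())
leader = rp.build_extended_leader(
    gene, genes, th.leader_max_extension, annotation.contig_lengths[gene.contig], th
)
print(f"{gene_id}: {gene.strand} strand, ORF {gene.orf_start}-{gene.orf_end}, "
      f"leader search region {leader.length} nt (stopped by {leader.truncated_by})")

peaks = rp.call_leader_peaks(gene, leader, track, annotation.genome, th)
peaks += rp.call_orf_peaks(gene, track, annotation.genome, th)
for p in peaks:
    status = "CALLED" if rp.is_surviving(p, th) else "not called"
    print(f"  {p.region:<6} AUG at {p.distance_to_main_start:+5d} (frame {p.frame}): "
          f"score {p.score:6.1f}, height {p.height:7.1f} rpkm -> {status}")

present, height = rp.detect_main_start_peak(gene, track, th)
print(f"  main-start 40S peak: height {height:.1f} rpkm -> "
      f"{'present' if present else 'absent'}")
# A leader AUG peak more than 100 nt upstream of the main start marks a
# 5'-extended (LUTI-like) transcript whose uORF translation triggers NMD.
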