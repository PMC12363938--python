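"""End-to-end orchestration: select -> leaders -> peaks -> curation ->
split-count -> classify -> summarize.

A :class:`RunConfig` names every input path and houses the full
:class:`~ribopeak.params.Thresholds` block; ``run_pipeline`` executes
the stages in order and writes a deterministic output directory —
rerunning on identical inputs is byte-identical.  A resolved-config
snapshot with all defaults materialized is written alongside the
results so a run is fully reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    Annotation,
    build_extended_leader,
    load_annotation,
    read_leader_overrides,
)
from .classify import (
    GeneEvidence,
    annotate_structures,
    classifications_to_frame,
    classify_leader,
    long_utr3_threshold,
    rationalize,
    read_de_table,
    read_pair_table,
    select_nmd_genes,
    summarize,
    upstream_window_de_input,
)
from .params import Thresholds
from .peaks import (
    apply_curation,
    call_leader_peaks,
    call_orf_peaks,
    call_stop_peaks,
    detect_main_start_peak,
    is_surviving,
    write_peaks,
)
from .tracks import count_region, normalize_rpm, read_track, shift_psite, split_count

log = logging.getLogger(__name__)

_PATH_KEYS = (
    "gff",
    "fasta",
    "track_40s_plus",
    "track_40s_minus",
    "track_80s_plus",
    "track_80s_minus",
    "track_rnaseq_wt_plus",
    "track_rnaseq_wt_minus",
    "track_rnaseq_upf1_plus",
    "track_rnaseq_upf1_minus",
    "de_orf",
    "de_intron",
    "bicistronic_pairs",
    "pseudogene_pairs",
    "curation_allowlist",
    "curation_denylist",
    "leader_overrides",
)
_REQUIRED_PATHS = (
    "gff",
    "fasta",
    "track_40s_plus",
    "track_40s_minus",
    "track_rnaseq_upf1_plus",
    "track_rnaseq_upf1_minus",
    "de_orf",
    "de_intron",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully resolved run description (paths + thresholds + seed)."""

    paths: Dict[str, Optional[str]] = field(
        default_factory=lambda: {k: None for k in _PATH_KEYS}
    )
    out_dir: str = "ribopeak_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    peak_gene_set: str = "nmd"  # "nmd" | "all"

    def validate(self) -> None:
        for key in _REQUIRED_PATHS:
            p = self.paths.get(key)
            if p is None:
                raise ConfigError(f"missing required input path: {key}")
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {key} = {p}")
        for key, p in self.paths.items():
            if key not in _PATH_KEYS:
                raise ConfigError(f"unknown path key: {key}")
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {key} = {p}")
        if self.peak_gene_set not in ("nmd", "all"):
            raise ConfigError(f"peak_gene_set must be 'nmd' or 'all', got {self.peak_gene_set}")

    # --- flat key-value (de)serialization -------------------------------
    def to_flat_dict(self) -> Dict[str, object]:
        d: Dict[str, object] = {k: self.paths.get(k) for k in _PATH_KEYS}
        d["out_dir"] = self.out_dir
        d["seed"] = self.seed
        d["peak_gene_set"] = self.peak_gene_set
        d.update(self.thresholds.to_dict())
        return d

    @classmethod
    def from_flat_dict(cls, d: Dict[str, object]) -> "RunConfig":
        d = dict(d)
        paths = {k: d.pop(k, None) for k in _PATH_KEYS}
        out_dir = d.pop("out_dir", "ribopeak_out")
        seed = int(d.pop("seed", 0))
        peak_gene_set = d.pop("peak_gene_set", "nmd")
        thresholds = Thresholds.from_dict(d) if d else Thresholds()
        return cls(paths=paths, out_dir=str(out_dir), thresholds=thresholds,
                   seed=seed, peak_gene_set=str(peak_gene_set))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        return cls.from_flat_dict(d)


def _json_default(o):
    return float(o)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Outputs: ``nmd_genes.tsv``, ``peaks.tsv`` + ``peaks.bed``,
    ``curation_log.tsv``, ``split_counts.tsv``, ``classifications.tsv``,
    ``summary.tsv``, ``report.json``, ``upstream_counts.tsv`` (when both
    RNA-seq conditions are present), ``resolved_config.yaml`` and
    ``run.log``.  Everything except ``run.log`` (which carries stage
    timers) is byte-deterministic.  A stage failure leaves partial
    outputs plus a ``FAILED`` marker naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    paths = config.paths
    stage = "init"
    log_lines: List[str] = [
        f"ribopeak {__version__}",
        f"seed\t{config.seed}",
        f"peak_gene_set\t{config.peak_gene_set}",
    ]
    log_lines += [f"threshold\t{k}\t{v}" for k, v in sorted(th.to_dict().items())]
    t0 = time.perf_counter()
    try:
        stage = "load_annotation"
        annotation = load_annotation(paths["gff"], paths["fasta"])
        lengths = annotation.contig_lengths
        genes_all = list(annotation.genes.values())
        eligible = {g.gene_id for g in annotation.eligible_genes()}
        log_lines.append(f"stage\t{stage}\tgenes={len(genes_all)}\teligible={len(eligible)}")

        stage = "select_nmd"
        de_orf = read_de_table(paths["de_orf"])
        de_intron = read_de_table(paths["de_intron"])
        nmd = select_nmd_genes(de_orf, de_intron, th)
        nmd.to_csv(out / "nmd_genes.tsv", sep="\t", index=False)
        log_lines.append(f"stage\t{stage}\tselected={len(nmd)}")

        stage = "load_tracks"
        track40 = read_track(paths["track_40s_plus"], paths["track_40s_minus"], "ribo40S", lengths)
        track40 = normalize_rpm(track40)
        track40_peaks = shift_psite(track40, th.psite_offset_40s_peaks)
        track80_q = None
        if paths.get("track_80s_plus") and paths.get("track_80s_minus"):
            track80 = read_track(paths["track_80s_plus"], paths["track_80s_minus"], "ribo80S", lengths)
            track80 = normalize_rpm(track80)
            track80_q = shift_psite(track80, th.psite_offset_80s)
        rnaseq_upf1 = read_track(
            paths["track_rnaseq_upf1_plus"], paths["track_rnaseq_upf1_minus"], "rnaseq", lengths
        )
        rnaseq_wt = None
        if paths.get("track_rnaseq_wt_plus") and paths.get("track_rnaseq_wt_minus"):
            rnaseq_wt = read_track(
                paths["track_rnaseq_wt_plus"], paths["track_rnaseq_wt_minus"], "rnaseq", lengths
            )
        log_lines.append(f"stage\t{stage}\ttotal40S={track40.total_mapped:.0f}")

        stage = "gene_set"
        if config.peak_gene_set == "all":
            scored_ids = sorted(eligible)
        else:
            scored_ids = sorted(set(nmd["gene_id"]) & eligible)
        low_expression: List[str] = []
        if track80_q is not None:
            kept = []
            for gid in scored_ids:
                rc = count_region(track80_q, annotation.genes[gid], "orf", th)
                if "below_threshold" in rc.flags:
                    low_expression.append(gid)
                else:
                    kept.append(gid)
            scored_ids = kept
        log_lines.append(
            f"stage\t{stage}\tscored={len(scored_ids)}\tlow_expression={len(low_expression)}"
        )

        stage = "leaders_and_peaks"
        overrides = (
            read_leader_overrides(paths["leader_overrides"])
            if paths.get("leader_overrides")
            else {}
        )
        all_peaks = []
        main_start: Dict[str, bool] = {}
        for gid in scored_ids:
            gene = annotation.genes[gid]
            leader = build_extended_leader(
                gene,
                genes_all,
                th.leader_max_extension,
                lengths[gene.contig],
                th,
                length_override=overrides.get(gid),
            )
            all_peaks.extend(call_leader_peaks(gene, leader, track40_peaks, annotation.genome, th))
            all_peaks.extend(call_orf_peaks(gene, track40_peaks, annotation.genome, th))
            all_peaks.extend(call_stop_peaks(gene, leader, track40_peaks, annotation.genome, th))
            main_start[gid], _ = detect_main_start_peak(gene, track40_peaks, th)
        log_lines.append(f"stage\t{stage}\tcandidates={len(all_peaks)}")

        stage = "curation"
        all_peaks, curation_log = apply_curation(
            all_peaks, paths.get("curation_allowlist"), paths.get("curation_denylist")
        )
        with open(out / "curation_log.tsv", "w") as fh:
            fh.write("action\tgene_id\tgenomic_pos\tnote\n")
            for line in curation_log:
                fh.write(line + "\n")
        write_peaks(all_peaks, annotation, out / "peaks.tsv", out / "peaks.bed")

        stage = "split_count"
        split_results = {}
        rows = []
        for gid in scored_ids:
            sc = split_count(rnaseq_upf1, annotation.genes[gid], th)
            split_results[gid] = sc
            rows.append(
                {
                    "gene_id": gid,
                    "first": sc.first,
                    "last": sc.last,
                    "ratio": sc.ratio,
                    "is_split_positive": sc.is_split_positive,
                    "flags": ",".join(sorted(sc.flags)) or ".",
                }
            )
        pd.DataFrame(
            rows, columns=["gene_id", "first", "last", "ratio", "is_split_positive", "flags"]
        ).to_csv(out / "split_counts.tsv", sep="\t", index=False, float_format="%.6g")

        stage = "classify"
        utr3_cutoff, utr3_flags = long_utr3_threshold(
            [annotation.genes[gid].utr3_len for gid in sorted(eligible)],
            th.utr3_sd_multiplier,
            th.utr3_population_sd,
        )
        nmd_ids = set(nmd["gene_id"])
        bic = read_pair_table(paths["bicistronic_pairs"]) if paths.get("bicistronic_pairs") else None
        pse = read_pair_table(paths["pseudogene_pairs"]) if paths.get("pseudogene_pairs") else None
        struct_flags, pair_report = annotate_structures(
            nmd_ids, set(annotation.genes), bic, pse
        )
        pair_report.to_csv(out / "pair_report.tsv", sep="\t", index=False)
        surv_leader: Dict[str, list] = {}
        surv_orf: Dict[str, list] = {}
        for p in all_peaks:
            if not is_surviving(p, th):
                continue
            d = surv_leader if p.region == "leader" else surv_orf
            d.setdefault(p.gene_id, []).append(p)
        nmd_via = dict(zip(nmd["gene_id"], nmd["nmd_via"]))
        retained = dict(zip(nmd["gene_id"], nmd["retained_intron"]))
        classifications = []
        for gid in sorted(nmd_ids):
            gene = annotation.genes.get(gid)
            sc = split_results.get(gid)
            ev = GeneEvidence(
                gene_id=gid,
                nmd_via=nmd_via[gid],
                leader_class=classify_leader(surv_leader.get(gid, []), th),
                has_orf_peaks=bool(surv_orf.get(gid)),
                main_start_peak=main_start.get(gid, False),
                split_positive=bool(sc.is_split_positive) if sc else False,
                long_utr3=bool(gene and gene.utr3_len > utr3_cutoff),
                bicistronic_member="bicistronic_member" in struct_flags.get(gid, set()),
                pseudogene_member="pseudogene_member" in struct_flags.get(gid, set()),
                retained_intron=bool(retained[gid]),
            )
            classifications.append(rationalize(ev, th))
        classifications_to_frame(classifications).to_csv(
            out / "classifications.tsv", sep="\t", index=False
        )
        log_lines.append(
            f"stage\t{stage}\tclassified={len(classifications)}\tutr3_cutoff={utr3_cutoff:.6g}"
        )

        stage = "summarize"
        table, rollup = summarize(classifications)
        table.to_csv(out / "summary.tsv", sep="\t", index=False)
        rollup["utr3_cutoff"] = round(utr3_cutoff, 6)
        rollup["utr3_cutoff_flags"] = sorted(utr3_flags)
        with open(out / "report.json", "w") as fh:
            json.dump(rollup, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")

        if rnaseq_wt is not None:
            stage = "upstream_window"
            up = upstream_window_de_input(
                {"wt": rnaseq_wt, "upf1": rnaseq_upf1},
                [annotation.genes[gid] for gid in scored_ids],
                th,
            )
            up.to_csv(out / "upstream_counts.tsv", sep="\t", index=False, float_format="%.6g")

        stage = "finalize"
        resolved = RunConfig(
            paths=dict(config.paths),
            out_dir=str(config.out_dir),
            thresholds=th,
            seed=config.seed,
            peak_gene_set=config.peak_gene_set,
        )
        resolved.to_yaml(out / "resolved_config.yaml")
        log_lines.append(f"elapsed_s\t{time.perf_counter() - t0:.3f}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        failed = out / "FAILED"
        if failed.exists():
            failed.unlink()
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise


# deterministic golden-compared outputs; run.log carries timers and
# resolved_config.yaml carries machine-specific input paths, so neither
# is part of the golden manifest
GOLDEN_FILES = (
    "nmd_genes.tsv",
    "peaks.tsv",
    "peaks.bed",
    "curation_log.tsv",
    "split_counts.tsv",
    "pair_report.tsv",
    "classifications.tsv",
    "summary.tsv",
    "report.json",
    "upstream_counts.tsv",
)
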