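"""Shared fixtures: the packaged mini fixture (seed 20250815, noiseless)
generated on disk once per session, plus ready-made pipeline inputs."""

from pathlib import Path

import pytest

import ribopeak as rp
from ribopeak.simdata import MINI_FIXTURE_SEED


@pytest.fixture(scope="session")
def thresholds():
    return rp.Thresholds()


@pytest.fixture(scope="session")
def mini_fixture(tmp_path_factory):
    """(annotation, truths, bundle, fixture_dir) for the packaged mini fixture."""
    fixture_dir = tmp_path_factory.mktemp("fixture")
    annotation, truths, bundle = rp.simulate(
        seed=MINI_FIXTURE_SEED, noise_rpm=None, outdir=fixture_dir
    )
    return annotation, truths, bundle, fixture_dir


def make_run_config(fixture_dir: Path, out_dir: Path) -> rp.RunConfig:
    cfg = rp.RunConfig()
    fx = Path(fixture_dir)
    cfg.paths.update(
        gff=str(fx / "genes.gff3"),
        fasta=str(fx / "genome.fa"),
        track_40s_plus=str(fx / "ribo40S.plus.bedgraph"),
        track_40s_minus=str(fx / "ribo40S.minus.bedgraph"),
        track_80s_plus=str(fx / "ribo80S.plus.bedgraph"),
        track_80s_minus=str(fx / "ribo80S.minus.bedgraph"),
        track_rnaseq_wt_plus=str(fx / "rnaseq_wt.plus.bedgraph"),
        track_rnaseq_wt_minus=str(fx / "rnaseq_wt.minus.bedgraph"),
        track_rnaseq_upf1_plus=str(fx / "rnaseq_upf1.plus.bedgraph"),
        track_rnaseq_upf1_minus=str(fx / "rnaseq_upf1.minus.bedgraph"),
        de_orf=str(fx / "de_orf.tsv"),
        de_intron=str(fx / "de_intron.tsv"),
        bicistronic_pairs=str(fx / "bicistronic_pairs.tsv"),
        pseudogene_pairs=str(fx / "pseudogene_pairs.tsv"),
    )
    cfg.out_dir = str(out_dir)
    return cfg


@pytest.fixture(scope="session")
def pipeline_run(mini_fixture, tmp_path_factory):
    """One full pipeline run on the mini fixture (shared, read-only)."""
    _, truths, _, fixture_dir = mini_fixture
    out_dir = tmp_path_factory.mktemp("pipeline_out")
    cfg = make_run_config(fixture_dir, out_dir)
    out = rp.run_pipeline(cfg)
    return out, truths


@pytest.fixture(scope="session")
def shifted_40s(mini_fixture, thresholds):
    """Peak-stage 40S track: rpm-normalized and P-site shifted by 13 nt."""
    _, _, bundle, _ = mini_fixture
    return rp.shift_psite(
        rp.normalize_rpm(bundle["ribo40S"]), thresholds.psite_offset_40s_peaks
    )
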