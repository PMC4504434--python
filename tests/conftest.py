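"""Shared fixtures: simulated scenes and pipeline runs.

The small scene keeps unit tests fast; the default scene (the generator's
out-of-the-box configuration) backs the end-to-end recovery checks.
"""

from __future__ import annotations

import pytest

from srnakit.config import PipelineConfig
from srnakit.pipeline import run_all
from srnakit.simulate import (
    SimConfig,
    build_genome,
    contaminant_fixture_path,
    load_truth,
    reference_fixture_paths,
    simulate_to_dir,
)

LIB_NAMES = ("G1_ctrl", "G1_stress", "G2_ctrl", "G2_stress")


def make_pipeline_config(sim_dir, out_dir, seed=1) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed)
    cfg.paths.genome = str(sim_dir / "genome.fa")
    cfg.paths.libraries = [str(sim_dir / f"lib_{lib}.fastq") for lib in LIB_NAMES]
    cfg.paths.contaminants = str(contaminant_fixture_path())
    same, other = reference_fixture_paths()
    cfg.paths.same_species_ref = str(same)
    cfg.paths.other_species_ref = str(other)
    cfg.paths.transcripts = str(sim_dir / "transcripts.fa")
    cfg.paths.out_dir = str(out_dir)
    return cfg


def small_sim_config(seed: int = 3) -> SimConfig:
    return SimConfig(
        seed=seed,
        genome_length=20_000,
        n_mir_loci=5,
        n_tas_loci=2,
        n_contaminant_loci=2,
        n_background_fragments=50,
    )


@pytest.fixture(scope="session")
def small_scene():
    """(genome, truth) for a 5-MIR / 2-TAS scene."""
    return build_genome(small_sim_config())


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("small_sim")
    simulate_to_dir(small_sim_config(), d)
    return d


@pytest.fixture(scope="session")
def small_run(small_sim_dir, tmp_path_factory):
    """Full pipeline on the small scene; returns (out_dir, truth)."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = make_pipeline_config(small_sim_dir, out, seed=3)
    run_all(cfg, truth_dir=small_sim_dir)
    return out, load_truth(small_sim_dir)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Default scene (20 MIR, 5 TAS, 5 contaminants, 500 background,
    4 libraries) at the canonical seed, pipeline + evaluation.

    Returns (sim_dir, out_dir, truth).
    """
    sim_dir = tmp_path_factory.mktemp("default_sim")
    out = tmp_path_factory.mktemp("default_run")
    truth = simulate_to_dir(SimConfig(seed=1), sim_dir)
    cfg = make_pipeline_config(sim_dir, out, seed=1)
    run_all(cfg, truth_dir=sim_dir)
    return sim_dir, out, truth
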