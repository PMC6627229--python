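import numpy as np
import pytest

from dotwave.cli_io import RunConfig, run_pipeline
from dotwave.synthetic_data import SimulationConfig

SEED = 11


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig(seed=SEED, outdir="unused")


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full default-conditions pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(seed=SEED, outdir=str(outdir))
    return run_pipeline(cfg, write_tracks=False)


@pytest.fixture()
def small_sim_config() -> SimulationConfig:
    """A fast, reduced genome for track-level tests."""
    return SimulationConfig(
        n_genes=40,
        n_chromosomes=2,
        chrom_length=240_000,
        n_replicates=2,
        seed=SEED,
    )


@pytest.fixture()
def pure_sim_config() -> SimulationConfig:
    """Proportional-signal mode: no antibody background, no depth equalization."""
    return SimulationConfig(
        n_genes=40,
        n_chromosomes=2,
        chrom_length=240_000,
        n_replicates=1,
        nonspecific_background=0.0,
        equalize_depth=False,
        seed=SEED,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
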