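import numpy as np
import pytest

from polycap.synthetic_tetraploid import SimConfig, simulate_references, simulate_reads
from polycap.workflow import RunConfig, run_pipeline


def recovery_sim_config(seed: int = 11) -> SimConfig:
    """High-depth, paralog-free conditions for parameter-recovery checks."""
    return SimConfig(
        n_genes=15,
        mean_depth_lambda=30.0,
        seed=seed,
        n_paralog_genes=0,
        n_homoeolog_deletions=2,
        n_pav_genes=1,
        n_duplicated_families=0,
        n_reciprocal_deletions=1,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """One full pipeline run at lambda=30 with planted structural events.

    Returns (report, truth); the truth set is regenerated deterministically
    from the same configuration.
    """
    cfg = RunConfig(sim=recovery_sim_config())
    report = run_pipeline(cfg)
    _, _, truth = simulate_references(recovery_sim_config())
    return report, truth


@pytest.fixture(scope="session")
def small_sim():
    """A small reference-only simulation with every event class planted."""
    cfg = SimConfig(n_genes=10, seed=3, n_paralog_genes=1,
                    n_homoeolog_deletions=1, n_pav_genes=1,
                    n_duplicated_families=1)
    targets, copies, truth = simulate_references(cfg)
    return cfg, targets, copies, truth


@pytest.fixture(scope="session")
def small_reads(small_sim):
    cfg, targets, copies, truth = small_sim
    return simulate_reads(truth, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
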