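import numpy as np
import pytest

from sctraj import qc
from sctraj.simulate import SimConfig, plant_qc_failures, simulate_timecourse


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_conditions=6,
        cells_per_condition=30,
        n_genes=800,
        n_spikeins=20,
        cells_per_population=20,
        archetype_signature_size=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_timecourse(small_config)


@pytest.fixture(scope="session")
def small_sim_with_failures(small_config):
    matrix, meta, truth = simulate_timecourse(small_config)
    matrix, truth = plant_qc_failures(matrix, truth, small_config)
    return matrix, meta, truth


@pytest.fixture(scope="session")
def small_qc(small_sim_with_failures):
    matrix, meta, truth = small_sim_with_failures
    filtered, expr, report, outcomes = qc.run_qc(matrix, meta, qc.QCThresholds())
    return filtered, expr, report, outcomes


@pytest.fixture
def rng():
    return np.random.default_rng(42)
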