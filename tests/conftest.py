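import numpy as np
import pytest

from minstim.detection import DetectionParams
from minstim.simulate import SimulationConfig, simulate_minstim_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One medium-sized simulated experiment with noise, shared read-only."""
    cfg = SimulationConfig(
        n_sweeps_per_potential=200, m_total=1.5, silent_fraction=0.25, seed=7
    )
    sweeps_hyper, sweeps_depol, truth = simulate_minstim_experiment(cfg)
    params = DetectionParams.for_simulation(cfg)
    return cfg, sweeps_hyper, sweeps_depol, truth, params


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Noise-free, CV-free experiment: detection must be exact."""
    cfg = SimulationConfig(
        n_sweeps_per_potential=150,
        m_total=1.5,
        silent_fraction=0.4,
        noise_sd=0.0,
        cv_q=0.0,
        seed=11,
    )
    sweeps_hyper, sweeps_depol, truth = simulate_minstim_experiment(cfg)
    params = DetectionParams.for_simulation(cfg)
    return cfg, sweeps_hyper, sweeps_depol, truth, params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
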