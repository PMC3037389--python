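import numpy as np
import pytest

from hybridcycle import default_config, simulate_cycle, simulate_flow_sample, simulate_lineage


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def det_cfg(cfg):
    """Fully deterministic configuration: no waiting times, no noise."""
    return cfg.deterministic()


@pytest.fixture(scope="session")
def det_history(det_cfg):
    """One converged deterministic life history (after a short burn-in)."""
    hists = simulate_lineage(12, 10, det_cfg, np.random.default_rng(0))
    return hists[-1]


@pytest.fixture(scope="session")
def small_histories(cfg):
    """A modest post-burn-in lineage sample for unit-level statistics."""
    return simulate_lineage(2000, 300, cfg, np.random.default_rng(123))


@pytest.fixture(scope="session")
def big_histories(cfg):
    """Full-size lineage sample: 32,500 iterations, 500 burn-in."""
    return simulate_lineage(32500, 500, cfg, np.random.default_rng(2024))


@pytest.fixture(scope="session")
def big_events(cfg, big_histories):
    """Asynchronous flow sample, one event per retained history."""
    return simulate_flow_sample(big_histories, cfg, np.random.default_rng(77))
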