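import numpy as np
import pytest

import resetfpt as rf


@pytest.fixture(scope="session")
def dw_spec():
    """Double-well surface with the shipped calibrated defaults."""
    return rf.default_spec("double_well_1d")


@pytest.fixture(scope="session")
def dw_baseline(dw_spec):
    """Reset-free double-well first-passage ensemble (n = 1500)."""
    init, crit = rf.default_experiment("double_well_1d")
    cfg = rf.default_config("double_well_1d", max_time=2e5)
    return rf.run_ensemble(1500, dw_spec, init, crit, rf.no_resetting(),
                           cfg, base_seed=101)


@pytest.fixture(scope="session")
def ig_model():
    """Benchmark inverse Gaussian: mean 1000 ps, COV 2."""
    return rf.inverse_gaussian_model()


@pytest.fixture(scope="session")
def ig_samples(ig_model):
    """5e4 reset-free draws from the benchmark inverse Gaussian."""
    return rf.sample_fpt(ig_model, 50_000, np.random.default_rng(404))
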