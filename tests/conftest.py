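import numpy as np
import pytest
from hypothesis import settings

from shrnakit import ncounter, synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def zero_noise_run():
    """Small noise-free simulated run with known integer abundances.

    Integer abundances with integer slope/background keep simulated counts
    exactly on the calibration line, so spike-in normalization must invert
    the generative model to machine precision.
    """
    abundances = tuple(float(a) for a in range(1, 21))
    cfg = synthetic.SimConfig(
        n_mirnas=20, noise_cv=0.0, abundances=abundances, seed=11
    )
    return cfg, synthetic.simulate_ncounter(cfg)


@pytest.fixture
def noisy_run():
    cfg = synthetic.SimConfig(n_mirnas=60, noise_cv=0.1, seed=5)
    return cfg, synthetic.simulate_ncounter(cfg)


@pytest.fixture
def normalized(noisy_run):
    cfg, m = noisy_run
    fits = ncounter.fit_all_samples(m, cfg.spike_concs)
    return ncounter.normalize_spikein(m, fits)


@pytest.fixture
def rng():
    return np.random.default_rng(20241215)
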