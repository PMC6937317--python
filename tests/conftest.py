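import numpy as np
import pytest

from lfpbeta.simulate import SimConfig, generate_session


@pytest.fixture(scope="session")
def quiet_config():
    """Single-channel, burst-free, respiration-free session config."""
    return SimConfig(
        structures=("OB",), n_trials=40, burst_gain=0.0,
        respiration_amplitude=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def quiet_session(quiet_config):
    return generate_session(quiet_config)


@pytest.fixture(scope="session")
def coupled_session():
    """Three channels, OB leads AP by pi/2 with zero jitter, strong bursts."""
    cfg = SimConfig(
        structures=("OB", "AP", "PP"), n_trials=44, burst_gain=3.0,
        coupled_pairs={("OB", "AP"): (np.pi / 2, 0.0)}, seed=3,
    )
    return cfg, generate_session(cfg)


@pytest.fixture(scope="session")
def beta_grid():
    from lfpbeta.timefreq import beta_freq_grid

    return beta_freq_grid()
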