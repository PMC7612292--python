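import numpy as np
import pytest

import harmfield as hf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise spec with every stochastic term switched off."""
    return hf.NoiseSpec(sensor_sigma=0.0, marker_jitter=0.0, occlusion_rate=0.0)


@pytest.fixture(scope="session")
def small_clean_scenario(quiet_noise):
    """Noiseless order-2 scenario small enough for exact-recovery tests."""
    return hf.simulate_dataset(duration=10.0, fs=60.0, n_sensors=10, seed=7, noise=quiet_noise)


@pytest.fixture(scope="session")
def small_noisy_scenario():
    noise = hf.NoiseSpec(sensor_sigma=0.02, marker_jitter=1e-4, occlusion_rate=0.0)
    return hf.simulate_dataset(duration=20.0, fs=60.0, n_sensors=10, seed=11, noise=noise)
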