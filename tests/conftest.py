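import numpy as np
import pytest

from refless4dflow.phantom import PhantomConfig, generate_phantom, simulate_encodings


@pytest.fixture(scope="session")
def noiseless_cfg() -> PhantomConfig:
    return PhantomConfig(grid_shape=(32, 32, 32), n_timeframes=6, noise_sd=0.0,
                         seed=7)


@pytest.fixture(scope="session")
def noiseless_gt(noiseless_cfg):
    return generate_phantom(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_encodings(noiseless_gt, noiseless_cfg):
    return simulate_encodings(noiseless_gt, noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_cfg() -> PhantomConfig:
    return PhantomConfig(grid_shape=(32, 32, 32), n_timeframes=6, noise_sd=0.02,
                         seed=11)


@pytest.fixture(scope="session")
def noisy_gt(noisy_cfg):
    return generate_phantom(noisy_cfg)


@pytest.fixture(scope="session")
def noisy_encodings(noisy_gt, noisy_cfg):
    return simulate_encodings(noisy_gt, noisy_cfg)


def uniform_velocity_gt(cfg: PhantomConfig, v: tuple[float, float, float],
                        sigma: float = 0.0):
    """Ground truth with spatially uniform velocity/sigma, for closed forms."""
    gt = generate_phantom(cfg)
    gt.velocity[:] = np.asarray(v)[:, None, None, None, None]
    gt.sigma[:] = sigma
    gt.background_phase[:] = 0.0
    gt.magnitude[:] = 1.0
    return gt
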