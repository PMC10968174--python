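import numpy as np
import pytest

from parotidseg.phantom import PhantomConfig, make_head_phantom


def small_phantom_config(seed: int = 0, noise_sd: float = 8.0) -> PhantomConfig:
    """A compact isotropic head phantom that keeps unit tests fast."""
    return PhantomConfig(
        shape=(32, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        gland_center_frac=(0.5, 0.5, 0.3),
        gland_semi_axes_mm=(10.0, 12.0, 9.0),
        noise_sd_hu=noise_sd,
        seed=seed,
    )


def fine_phantom_config(seed: int = 0) -> PhantomConfig:
    """1 mm isotropic phantom for analytic-volume checks."""
    return PhantomConfig(
        shape=(64, 80, 128),
        spacing=(1.0, 1.0, 1.0),
        gland_center_frac=(0.5, 0.5, 0.26),
        gland_semi_axes_mm=(10.0, 15.0, 20.0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_phantom():
    return make_head_phantom(small_phantom_config())


@pytest.fixture(scope="session")
def fine_phantom():
    return make_head_phantom(fine_phantom_config())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
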