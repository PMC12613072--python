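import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Desk-scale config: short recording, few cells, quiet noise."""
    from organoid_calcium import SynthConfig

    return SynthConfig(n_frames=900, n_cells=6, active_fraction=0.5,
                       noise_sd=1.0, seed=7)


def gaussian_bump(n, center, height, fwhm):
    """A smooth single-peak test trace (dF/F0-like)."""
    t = np.arange(n)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return height * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def random_dff_like(rng, n, n_bumps=None, quantize=False):
    """Random smooth dF/F0-like traces with occasional plateaus/ties."""
    if n_bumps is None:
        n_bumps = int(rng.integers(0, 8))
    x = np.zeros(n)
    for _ in range(n_bumps):
        x += gaussian_bump(n, rng.uniform(0, n), rng.uniform(0.05, 0.8),
                           rng.uniform(8, 120))
    # slow correlated noise floor
    noise = np.convolve(rng.normal(0, 0.02, n), np.ones(25) / 25, mode="same")
    x += noise
    if quantize:  # force exact ties and flat plateaus
        x = np.round(x, 2)
    return x
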