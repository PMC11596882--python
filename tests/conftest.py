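import numpy as np
import pytest

from nirpls import simulate
from nirpls.spectra import SpectrumSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def coarse_grid():
    """10,000..4,000 cm^-1 at an 8 cm^-1 step (751 points): fast tests."""
    return simulate.default_grid(8.0)


@pytest.fixture(scope="session")
def noiseless_calibration(coarse_grid):
    return simulate.generate_mixture_set(
        grid=coarse_grid, noise=simulate.NoiseModel.zero(seed=7))


@pytest.fixture(scope="session")
def noisy_calibration(coarse_grid):
    return simulate.generate_mixture_set(
        grid=coarse_grid, noise=simulate.NoiseModel(seed=7))


@pytest.fixture
def small_set():
    """Tiny hand-made transmittance set: 2 samples x 2 replicates."""
    w = np.linspace(10000.0, 4000.0, 41)
    rng = np.random.default_rng(3)
    base = 60.0 + 20.0 * np.exp(-0.5 * ((w - 6000.0) / 300.0) ** 2)
    rows = np.vstack([base + rng.normal(0, 0.5, w.size) for _ in range(4)])
    return SpectrumSet(
        wavenumbers=w,
        intensities=rows,
        sample_ids=("a", "a", "b", "b"),
        fractions=np.array([10.0, 10.0, 60.0, 60.0]),
        resolution=4.0,
        mode="transmittance",
    )
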