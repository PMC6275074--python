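import numpy as np
import pytest

from mangospec.hsi_io import WavelengthGrid, default_grid
from mangospec.preprocess import SpectraMatrix
from mangospec.quality import records_to_frame
from mangospec.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.linspace(900.0, 1700.0, 32))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_spectra(small_grid, rng):
    n, p = 12, small_grid.count
    values = 0.5 + 0.1 * rng.standard_normal((n, p))
    return SpectraMatrix([f"s{i}" for i in range(n)], small_grid, values)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study (240 fruits) shared across tests."""
    return generate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_quality(default_dataset):
    return records_to_frame(default_dataset.records)
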