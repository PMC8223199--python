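import numpy as np
import pytest

from msiadducts.msi_io import IntensityMatrix, PeakList


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_matrix():
    """4 peaks x 6 pixels with a zero column and a constant row."""
    mz = np.array([100.0, 150.0, 200.0, 250.0])
    coords = np.array([(x, y) for y in (1, 2) for x in (1, 2, 3)])
    values = np.array(
        [
            [10.0, 0.0, 5.0, 2.0, 0.0, 1.0],
            [3.0, 3.0, 3.0, 3.0, 3.0, 3.0],   # constant
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # never detected
            [20.0, 0.0, 10.0, 4.0, 0.0, 2.0],  # 2x the first row
        ]
    )
    return IntensityMatrix(mz, coords, values)


@pytest.fixture
def random_matrix(rng):
    """60 peaks x 50 pixels of sparse log-normal intensities."""
    mz = np.sort(rng.uniform(100, 1000, size=60))
    coords = np.array([(x, y) for y in range(1, 6) for x in range(1, 11)])
    values = rng.lognormal(3, 1, size=(60, 50)) * (rng.random((60, 50)) < 0.6)
    return IntensityMatrix(mz, coords, values)


@pytest.fixture
def peaklist():
    return PeakList(np.array([100.0, 200.0, 336.016]), np.array([5.0, 3.0, 1.0]))
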