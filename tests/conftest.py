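import numpy as np
import pytest

from duomsi import SpectralImage
from duomsi.synthetic import PhantomConfig


def make_spectral(pixels, width, height, mz_range=(200.0, 1000.0), pixel_size=30.0):
    """Build a SpectralImage from a row-major list of (mz, intensity) pair lists."""
    mzs, intens = [], []
    for peaks in pixels:
        if peaks:
            mz, it = zip(*sorted(peaks))
            mzs.append(np.asarray(mz, dtype=float))
            intens.append(np.asarray(it, dtype=float))
        else:
            mzs.append(np.empty(0))
            intens.append(np.empty(0))
    return SpectralImage(
        width=width, height=height, pixel_size=pixel_size,
        mzs=mzs, intensities=intens, mz_range=mz_range,
    )


def random_spectral(rng, width=5, height=5, max_peaks=8, mz_range=(200.0, 1000.0)):
    """Random small centroided image (some pixels empty)."""
    pixels = []
    for _ in range(width * height):
        n = int(rng.integers(0, max_peaks + 1))
        if n == 0:
            pixels.append([])
            continue
        mz = np.sort(rng.uniform(*mz_range, size=n))
        mz = mz[np.concatenate([[True], np.diff(mz) > 1e-9])]
        inten = rng.uniform(0.0, 100.0, size=mz.size)
        pixels.append(list(zip(mz, inten)))
    return make_spectral(pixels, width, height, mz_range)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Small, fast phantom for unit tests (geometry scales with the grid)."""
    return PhantomConfig(width=80, height=60)
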