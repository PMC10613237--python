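import numpy as np
import pytest

import mstrace as ms


@pytest.fixture(scope="session")
def grid16():
    return ms.make_grid(16, 0.45, 0.9, 1.0)


@pytest.fixture(scope="session")
def grid24():
    return ms.make_grid(24, 0.45, 0.9, 1.0)


@pytest.fixture(scope="session")
def grid32():
    return ms.make_grid(32, 0.45, 0.9, 1.0)


def passband_field(grid, seed=0):
    """Random complex field restricted to the pupil passband."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((grid.n, grid.n)) \
        + 1j * rng.standard_normal((grid.n, grid.n))
    spec = np.fft.fft2(f)
    spec[~grid.pupil_mask()] = 0.0
    return ms.ComplexField(grid, np.fft.ifft2(spec))


@pytest.fixture
def single_plate_phantom(grid24):
    """One random plate above a spoke target, with the exact ground truth."""
    depth = 8.0
    med = ms.build_medium(grid24, [depth], correlation_length=2.5,
                          phase_std=0.8, seed=7)
    obj = ms.make_target_object("siemens_star", {"n_spokes": 6}, grid24)
    r = ms.reflection_from_medium(med, obj, reference_plane="z0")
    return med, obj, r
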