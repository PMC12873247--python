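import numpy as np
import pytest

import paleochron as pc


@pytest.fixture(scope="session")
def identity_curve():
    """Identity curve (mu = theta, sigma_c = 0) on 0-10,000 cal BP."""
    return pc.make_curve("identity", age_max=10_000)


@pytest.fixture(scope="session")
def identity_curve_55k():
    return pc.make_curve("identity", age_max=55_000, resolution=5)


@pytest.fixture(scope="session")
def wiggly_curve():
    return pc.make_curve(
        "wiggly", age_max=10_000, slope=1.1, intercept=200.0,
        wiggle_amplitude=40.0, wiggle_period=700.0, curve_sigma=15.0,
    )


@pytest.fixture(scope="session")
def intcal20():
    return pc.load_intcal20()


@pytest.fixture()
def selby_cu():
    from importlib import resources

    path = resources.files("paleochron").joinpath("data/selby_cu4417.json")
    return pc.read_collection(str(path))


def uniform_density(grid_lo, grid_hi, lo, hi, resolution=1):
    """Discrete density uniform over [lo, hi] embedded in a wider grid."""
    grid = np.arange(grid_lo, grid_hi + 1, resolution)
    p = ((grid >= lo) & (grid <= hi)).astype(float)
    return pc.CalibratedDensity(grid=grid, p=p / p.sum())
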