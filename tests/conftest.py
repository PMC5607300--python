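import numpy as np
import pytest

from neodem.calcurve import CalibrationCurve
from neodem.synth import toy_curve


@pytest.fixture(scope="session")
def identity_curve():
    """mu(t) = t with no curve error: calibration reduces to a Gaussian."""
    grid = np.arange(3_000.0, 13_001.0)
    return CalibrationCurve(grid=grid, mu=grid.copy(),
                            sigma_curve=np.zeros(grid.size), name="identity")


@pytest.fixture(scope="session")
def identity_curve_sig30():
    """mu(t) = t with a constant 30-yr curve error."""
    grid = np.arange(3_000.0, 13_001.0)
    return CalibrationCurve(grid=grid, mu=grid.copy(),
                            sigma_curve=np.full(grid.size, 30.0), name="identity30")


@pytest.fixture(scope="session")
def wiggle_curve():
    return toy_curve()
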