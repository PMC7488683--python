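import numpy as np
import pytest

from ringcycles.atlas import build_period_curve
from ringcycles.stability import hopf_report


@pytest.fixture(scope="session")
def hopf1000():
    """Hopf report of the reference strong-promoter autorepressor."""
    return hopf_report(1000.0, 10.0)


@pytest.fixture(scope="session")
def curve_small():
    """Short period curve for the reference parameters (fast to build)."""
    return build_period_curve(1000.0, 10.0, tau_max=8.0, n_points=60)


@pytest.fixture(scope="session")
def census_curve():
    """Period curve long enough for the full n=2..9 delay-free census.

    The descending tail of T(tau)/tau must drop below the smallest ratio
    above 2 that the census queries (9/4), which happens near tau ~ 28.
    """
    return build_period_curve(1000.0, 10.0, tau_max=34.0, n_points=150)


@pytest.fixture(scope="session")
def gentle_curve():
    """Period curve at mild nonlinearity (alpha=10, h=4), where profiles can
    be resolved to very high accuracy for residual checks."""
    return build_period_curve(10.0, 4.0, tau_max=5.0, n_points=50)
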