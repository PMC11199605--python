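import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from fogbands.nonlocal_model import NonlocalParams
from fogbands.reduced_model import ReducedParams


@pytest.fixture(scope="session")
def nonlocal_ref() -> NonlocalParams:
    """Printed parameter set of the nonlocal-model banded patterns."""
    return NonlocalParams(
        mu=0.98, chi_f=2.1, chi_c=1.2, D=0.2,
        x0c=-0.2, x0f=0.5, y0f=0.0, y0c=0.0,
        lfx=0.9, lfy=0.9, lcx=5.0, lcy=3.5,
    )


@pytest.fixture(scope="session")
def reduced_ref() -> ReducedParams:
    """Printed parameter set of the reduced-model banded patterns."""
    return ReducedParams(eta=-0.02, kappa=0.3, d=0.3, alpha=0.27, gamma=2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
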