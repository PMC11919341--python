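import numpy as np
import pytest

from dcsflow import (
    LagGrid,
    SemiInfiniteMedium,
    ThreeLayerMedium,
    semi_infinite_g1,
    siegert_g2,
)

#: Baseline semi-infinite tissue optics (mm^-1) used throughout the tests.
BASELINE_SEMI = dict(mu_s_prime=1.6, mu_a=0.0027)
#: Baseline three-layer (scalp/skull/brain) optics.
BASELINE_THREE = dict(
    mu_s_prime=(0.635, 0.851, 1.099),
    mu_a=(0.019, 0.014, 0.019),
    thickness=(5.0, 7.0),
)
RHO = 25.0


@pytest.fixture(scope="session")
def default_grid():
    return LagGrid.logspaced()


@pytest.fixture(scope="session")
def semi_medium():
    return SemiInfiniteMedium(bfi=1e-6, **BASELINE_SEMI)


@pytest.fixture(scope="session")
def three_layer_medium():
    return ThreeLayerMedium(bfi=(1e-6, 0.0, 6e-6), **BASELINE_THREE)


@pytest.fixture(scope="session")
def homogeneous_three_layer():
    """Three-layer medium with all layers equal to the semi-infinite baseline."""
    return ThreeLayerMedium(
        mu_s_prime=(1.6,) * 3, mu_a=(0.0027,) * 3, bfi=(1e-6,) * 3,
        thickness=(5.0, 7.0))


@pytest.fixture(scope="session")
def baseline_g2_curve(semi_medium, default_grid):
    """Noiseless baseline g2: semi-infinite, BFI = 1e-6 mm^2/s, beta = 0.5."""
    return siegert_g2(semi_infinite_g1(semi_medium, RHO, default_grid), 0.5)
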