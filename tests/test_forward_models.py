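import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcsflow import (
    CorrelationCurve,
    LagGrid,
    QuadratureSettings,
    SemiInfiniteMedium,
    ThreeLayerMedium,
    effective_reflection_coeff,
    read_curve_csv,
    semi_infinite_g1,
    siegert_g2,
    three_layer_g1,
    write_curve_csv,
)
from dcsflow.errors import InvalidParameterError
from dcsflow.forward_models import _semi_infinite_g1_values

from conftest import BASELINE_SEMI, RHO


@pytest.mark.parametrize("n0, expected", [
    # direct arithmetic evaluation of the four-term polynomial (mpmath oracle)
    (1.35, 0.4896624691358025),
    (1.0, 0.0016),
    (1.4, 0.5294889795918367),
])
def test_effective_reflection_coeff(n0, expected):
    assert effective_reflection_coeff(n0) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
def test_effective_reflection_coeff_rejects_nonpositive(bad):
    with pytest.raises(InvalidParameterError):
        effective_reflection_coeff(bad)


class TestSemiInfiniteG1:
    def test_zero_lag_normalization(self, semi_medium):
        # g1 is normalized by G1(tau=0), so tau -> 0 gives exactly 1
        g1 = _semi_infinite_g1_values(semi_medium, RHO, np.array([0.0, 1e-7]))
        assert g1[0] == 1.0

    def test_static_medium_has_no_decay(self, default_grid):
        medium = SemiInfiniteMedium(bfi=0.0, **BASELINE_SEMI)
        curve = semi_infinite_g1(medium, RHO, default_grid)
        np.testing.assert_allclose(curve.g1, 1.0, rtol=1e-15)

    def test_regression_fixture(self, semi_medium):
        # frozen value from a 40-digit mpmath term-by-term evaluation
        g1 = _semi_infinite_g1_values(semi_medium, RHO, np.array([1e-5]))
        assert g1[0] == pytest.approx(0.2965483281881718, rel=1e-12)

    def test_strictly_decreasing_in_tau(self, semi_medium, default_grid):
        curve = semi_infinite_g1(semi_medium, RHO, default_grid)
        assert np.all(np.diff(curve.g1) < 0)
        assert np.all(curve.g1 > 0) and np.all(curve.g1 <= 1)

    def test_decreasing_in_bfi(self, default_grid):
        tau = np.array([1e-5])
        vals = [
            _semi_infinite_g1_values(
                SemiInfiniteMedium(bfi=b, **BASELINE_SEMI), RHO, tau)[0]
            for b in (1e-7, 1e-6, 1e-5)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_rejects_nonpositive_rho(self, semi_medium, default_grid):
        with pytest.raises(InvalidParameterError):
            semi_infinite_g1(semi_medium, 0.0, default_grid)


class TestThreeLayerG1:
    def test_homogeneous_limit_matches_semi_infinite(
            self, homogeneous_three_layer, semi_medium):
        grid = LagGrid.logspaced(128, 1e-7, 1e-2)
        tl = three_layer_g1(homogeneous_three_layer, RHO, grid)
        semi = semi_infinite_g1(semi_medium, RHO, grid)
        live = semi.g1 >= 1e-6
        np.testing.assert_allclose(tl.g1[live], semi.g1[live], rtol=0.01)
        np.testing.assert_allclose(tl.g1[~live], semi.g1[~live], atol=1e-6)

    def test_static_layers_have_no_decay(self):
        medium = ThreeLayerMedium(
            mu_s_prime=(0.635, 0.851, 1.099), mu_a=(0.019, 0.014, 0.019),
            bfi=(0.0, 0.0, 0.0))
        curve = three_layer_g1(medium, RHO, LagGrid.logspaced(32))
        np.testing.assert_allclose(curve.g1, 1.0, atol=1e-12)

    def test_quadrature_convergence_check(self, three_layer_medium):
        grid = LagGrid.logspaced(32)
        a = three_layer_g1(three_layer_medium, RHO, grid, check_convergence=True)
        b = three_layer_g1(three_layer_medium, RHO, grid,
                           QuadratureSettings(nodes=4096))
        np.testing.assert_allclose(a.g1, b.g1, atol=1e-9)

    def test_rejects_too_few_nodes(self):
        with pytest.raises(InvalidParameterError):
            QuadratureSettings(nodes=32)

    def test_monotone_nonincreasing(self, three_layer_medium, default_grid):
        curve = three_layer_g1(three_layer_medium, RHO, default_grid)
        assert np.all(np.diff(curve.g1) <= 0)


class TestSiegert:
    @pytest.mark.parametrize("g1, beta, expected", [
        (1.0, 0.5, 1.5),     # zero-lag limit
        (0.0, 0.3, 1.0),     # full decorrelation
        (0.6, 0.5, 1.18),    # 1 + 0.5*0.36
    ])
    def test_values(self, g1, beta, expected):
        grid = LagGrid(np.array([1e-6, 1e-5]))
        curve = CorrelationCurve(grid=grid,
                                 g1=np.array([1.0, max(g1, 1e-12)]))
        out = siegert_g2(curve, beta)
        assert out.g2[1] == pytest.approx(1.0 + beta * max(g1, 1e-12) ** 2)
        assert out.g2[0] == pytest.approx(expected if g1 == 1.0 else 1 + beta)

    @pytest.mark.parametrize("beta", [0.0, -0.1, 1.5])
    def test_rejects_bad_beta(self, baseline_g2_curve, beta):
        with pytest.raises(InvalidParameterError):
            siegert_g2(baseline_g2_curve, beta)

    def test_bounds(self, baseline_g2_curve):
        g2 = baseline_g2_curve.g2
        beta = baseline_g2_curve.beta
        assert np.all(g2 >= 1.0) and np.all(g2 <= 1.0 + beta)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    mu_s=st.floats(0.4, 3.0),
    mu_a=st.floats(1e-4, 0.05),
    bfi=st.floats(1e-8, 1e-5),
    beta=st.floats(0.01, 1.0),
)
def test_random_media_satisfy_g1_and_siegert_invariants(mu_s, mu_a, bfi, beta):
    """g1 in (0, 1], non-increasing; g2 within the Siegert band [1, 1+beta]."""
    grid = LagGrid.logspaced(64)
    medium = SemiInfiniteMedium(mu_s_prime=mu_s, mu_a=mu_a, bfi=bfi)
    curve = semi_infinite_g1(medium, RHO, grid)
    assert np.all(curve.g1 > 0) and np.all(curve.g1 <= 1.0)
    assert np.all(np.diff(curve.g1) <= 0)
    g2 = siegert_g2(curve, beta).g2
    assert np.all(g2 >= 1.0 - 1e-12) and np.all(g2 <= 1.0 + beta + 1e-12)


class TestLagGrid:
    def test_logspaced_defaults(self):
        grid = LagGrid.logspaced()
        assert grid.count == 128
        assert grid.tau_min == pytest.approx(1e-7)
        assert grid.tau_max == pytest.approx(1e-1)
        assert np.all(np.diff(grid.tau) > 0)

    @pytest.mark.parametrize("tau", [
        [1e-5, 1e-6],            # decreasing
        [-1e-6, 1e-5],           # negative
        [1e-6, 1e-6],            # duplicate
    ])
    def test_rejects_invalid(self, tau):
        with pytest.raises(InvalidParameterError):
            LagGrid(np.array(tau))


def test_curve_csv_round_trip(tmp_path, baseline_g2_curve):
    path = tmp_path / "curve.csv"
    write_curve_csv(baseline_g2_curve, path)
    back = read_curve_csv(path)
    np.testing.assert_allclose(back.grid.tau, baseline_g2_curve.grid.tau,
                               rtol=1e-14)
    np.testing.assert_allclose(back.g2, baseline_g2_curve.g2, rtol=1e-14)
    np.testing.assert_allclose(back.g1, baseline_g2_curve.g1, rtol=1e-14)
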