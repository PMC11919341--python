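"""Multi-tau correlator noise model.

The standard deviation of a measured g2 at lag ``tau`` follows the classical
photon-correlation noise model (Koppel-type), driven by the photon rate I,
the correlator bin width Tb, the integration time t, the coherence factor
beta and the effective exponential decay rate Gamma of g1.  Gamma is obtained
by fitting ``g2(tau) ~ 1 + beta*exp(-2*Gamma*tau)`` to the curve at hand.
Noise is injected as independent zero-mean Gaussian draws per lag with the
modeled standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateCurveError, InvalidParameterError
from .forward_models import CorrelationCurve, LagGrid

__all__ = [
    "AcquisitionParams",
    "DecayFit",
    "fit_decay_rate",
    "noise_sigma",
    "add_noise",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Photon-counting acquisition settings.

    Parameters
    ----------
    intensity : float
        Detected photon rate I (counts/s), > 0.
    integration_time : float
        Total averaging time t (s), > 0.
    bin_width : float
        Correlator bin width Tb (s); defaults to the first lag of the
        standard grid (1e-7 s).
    beta : float
        Coherence factor in (0, 1].
    """

    intensity: float
    integration_time: float
    bin_width: float = 1e-7
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise InvalidParameterError("intensity must be > 0")
        if self.integration_time <= 0:
            raise InvalidParameterError("integration_time must be > 0")
        if self.bin_width <= 0:
            raise InvalidParameterError("bin_width must be > 0")
        if not 0 < self.beta <= 1:
            raise InvalidParameterError("beta must be in (0, 1]")

    @property
    def mean_photons_per_bin(self) -> float:
        """<n> = I * Tb."""
        return self.intensity * self.bin_width


@dataclass(frozen=True)
class DecayFit:
    """Result of the single-exponential g2 decay fit."""

    gamma: float
    beta_hat: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise InvalidParameterError("gamma must be >= 0")
        if not 0 < self.beta_hat <= 1.5:
            raise InvalidParameterError("beta_hat out of plausible range (0, 1.5]")


def fit_decay_rate(curve: CorrelationCurve) -> DecayFit:
    """Fit ``g2(tau) ~ 1 + beta*exp(-2*Gamma*tau)`` by bounded least squares.

    Initialization: ``beta0 = max(g2) - 1`` and ``Gamma0`` from the lag at
    which ``g2 - 1`` first drops below ``beta0/e`` (0 if it never does).

    Returns
    -------
    DecayFit
        The fitted ``(Gamma, beta_hat)``.

    Raises
    ------
    DegenerateCurveError
        If fewer than 8 lags carry contrast (g2 - 1 > 0).
    """
    if curve.g2 is None:
        raise InvalidParameterError("curve has no g2 values")
    tau = curve.grid.tau
    y = curve.g2 - 1.0
    if np.count_nonzero(y > 0) < 8:
        raise DegenerateCurveError("need at least 8 lags with g2 - 1 > 0")
    beta0 = float(np.clip(np.max(y), 1e-6, 1.5))
    below = np.nonzero(y < beta0 / np.e)[0]
    gamma0 = 1.0 / (2.0 * tau[below[0]]) if below.size else 0.0

    def resid(p):
        beta, gamma = p
        return beta * np.exp(-2.0 * gamma * tau) - y

    def jac(p):
        beta, gamma = p
        e = np.exp(-2.0 * gamma * tau)
        return np.column_stack([e, -2.0 * beta * tau * e])

    sol = least_squares(
        resid, x0=[beta0, gamma0], jac=jac,
        bounds=([1e-12, 0.0], [1.5, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return DecayFit(gamma=float(sol.x[1]), beta_hat=float(sol.x[0]))


def noise_sigma(acq: AcquisitionParams, fit: DecayFit, grid: LagGrid) -> np.ndarray:
    """Per-lag noise standard deviation delta(tau).

    Evaluates

    ``delta(tau) = sqrt(Tb/t) * [ beta^2*((1+e^{-2*G*Tb})*(1+e^{-2*G*tau})
    + 2*m*(1-e^{-2*G*Tb})*e^{-2*G*tau}) / (1-e^{-2*G*Tb})
    + 2*<n>^-1*beta*(1+e^{-2*G*tau}) + <n>^-2*(1+e^{-2*G*tau}) ]^{1/2}``

    with ``<n> = I*Tb`` and the (real-valued) bin index ``m = tau/Tb``.
    The prefactor makes ``delta`` scale exactly as ``sqrt(Tb/t)``.

    Raises
    ------
    InvalidParameterError
        If ``Tb >= t`` (no averaging) or ``Gamma == 0`` (the bracket
        diverges as 1/(Gamma*Tb): a non-decaying curve has no well-defined
        correlator noise in this model).
    """
    if acq.bin_width >= acq.integration_time:
        raise InvalidParameterError("bin_width must be smaller than integration_time")
    if fit.gamma <= 0:
        raise InvalidParameterError("noise model requires a positive decay rate")
    tau = grid.tau
    tb = acq.bin_width
    beta = acq.beta
    n_inv = 1.0 / acq.mean_photons_per_bin
    m = tau / tb
    e_tb = np.exp(-2.0 * fit.gamma * tb)
    e_tau = np.exp(-2.0 * fit.gamma * tau)
    one_m_etb = -np.expm1(-2.0 * fit.gamma * tb)  # 1 - e^{-2*G*Tb}, stable
    bracket = (
        beta**2 * ((1.0 + e_tb) * (1.0 + e_tau) + 2.0 * m * one_m_etb * e_tau)
        / one_m_etb
        + 2.0 * n_inv * beta * (1.0 + e_tau)
        + n_inv**2 * (1.0 + e_tau)
    )
    return np.sqrt(tb / acq.integration_time) * np.sqrt(bracket)


def add_noise(curve: CorrelationCurve, sigma: np.ndarray,
              seed: int) -> CorrelationCurve:
    """Add independent zero-mean Gaussian noise with per-lag std ``sigma``.

    Deterministic under ``seed``; identical seeds give identical curves.
    """
    if curve.g2 is None:
        raise InvalidParameterError("curve has no g2 values")
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != curve.g2.shape:
        raise InvalidParameterError("sigma length must match the curve")
    if np.any(sigma < 0):
        raise InvalidParameterError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    g2_noisy = curve.g2 + sigma * rng.standard_normal(curve.g2.size)
    return replace(curve, g2=g2_noisy, noisy=True)
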