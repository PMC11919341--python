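"""Analytical CW-DCS forward models.

Continuous-wave diffuse correlation spectroscopy (DCS) measures the temporal
autocorrelation of multiply scattered coherent near-infrared light.  The
normalized field autocorrelation ``g1(rho, tau)`` obeys the correlation
diffusion equation; the measured intensity autocorrelation ``g2`` follows from
``g1`` through the Siegert relation ``g2 = 1 + beta * g1**2``.

Two tissue geometries are implemented:

* a semi-infinite homogeneous medium, whose Green's function is the classical
  two-image-source closed form with an extrapolated boundary, and
* a three-layer slab model of the adult head (scalp, skull, brain), whose
  Green's function is known in radial spatial-frequency (q) space and is
  brought back to real space by a zeroth-order Hankel (Fourier-Bessel)
  inversion evaluated with fixed Gauss-Legendre quadrature.

All lengths are in mm, times in seconds, blood flow indices (BFI = alpha*DB)
in mm^2/s.  Wavelengths are given in nm and converted internally.  The
wavenumber convention is the in-medium one, ``k0 = 2*pi*n0/lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import j0, roots_legendre

from .errors import (
    ConvergenceError,
    InvalidParameterError,
    NumericalRangeError,
)

__all__ = [
    "SemiInfiniteMedium",
    "ThreeLayerMedium",
    "LagGrid",
    "CorrelationCurve",
    "QuadratureSettings",
    "effective_reflection_coeff",
    "semi_infinite_g1",
    "three_layer_g1",
    "siegert_g2",
    "extrapolated_boundary",
    "write_curve_csv",
    "read_curve_csv",
]

#: nm -> mm conversion factor.
_NM_TO_MM = 1e-6


def effective_reflection_coeff(n0: float) -> float:
    """Effective reflection coefficient R_eff of the tissue-air interface.

    Uses the standard rational polynomial in the refractive index ratio
    ``n0 = n_tissue / n_air``:

    ``R_eff = -1.440*n0**-2 + 0.710*n0**-1 + 0.668 + 0.0636*n0``

    Parameters
    ----------
    n0 : float
        Refractive index ratio, > 0.

    Returns
    -------
    float
        The (unitless) effective reflection coefficient.
    """
    if not np.isfinite(n0) or n0 <= 0:
        raise InvalidParameterError(f"n0 must be positive, got {n0!r}")
    return -1.440 / n0**2 + 0.710 / n0 + 0.668 + 0.0636 * n0


def extrapolated_boundary(mu_s_prime: float, n0: float) -> float:
    """Extrapolated boundary distance z_b = 2*(1+R_eff)/(3*mu_s'*(1-R_eff))."""
    reff = effective_reflection_coeff(n0)
    return 2.0 * (1.0 + reff) / (3.0 * mu_s_prime * (1.0 - reff))


def _wavenumber(wavelength_nm: float, n0: float) -> float:
    """In-medium wavenumber k0 = 2*pi*n0/lambda, with lambda in mm."""
    return 2.0 * np.pi * n0 / (wavelength_nm * _NM_TO_MM)


@dataclass(frozen=True)
class SemiInfiniteMedium:
    """Optical and dynamic properties of a semi-infinite homogeneous medium.

    Parameters
    ----------
    mu_s_prime : float
        Reduced scattering coefficient (mm^-1), > 0.
    mu_a : float
        Absorption coefficient (mm^-1), >= 0.
    bfi : float
        Blood flow index alpha*DB (mm^2/s), >= 0.  The product alpha*DB is
        the quantity entering the decay term, so ``bfi`` already folds the
        dynamic-scatterer fraction in.
    alpha : float, optional
        Fraction of dynamic scatterers in (0, 1]; retained as metadata
        (``bfi`` is the product alpha*DB).
    n0 : float, optional
        Tissue/air refractive index ratio, >= 1.
    wavelength : float, optional
        Source wavelength lambda_DCS in nm.
    """

    mu_s_prime: float
    mu_a: float
    bfi: float
    alpha: float = 1.0
    n0: float = 1.35
    wavelength: float = 785.0

    def __post_init__(self) -> None:
        if self.mu_s_prime <= 0:
            raise InvalidParameterError("mu_s_prime must be > 0")
        if self.mu_a < 0:
            raise InvalidParameterError("mu_a must be >= 0")
        if not 0 < self.alpha <= 1:
            raise InvalidParameterError("alpha must be in (0, 1]")
        if self.n0 < 1:
            raise InvalidParameterError("n0 must be >= 1")
        if self.bfi < 0:
            raise InvalidParameterError("bfi must be >= 0")
        if self.wavelength <= 0:
            raise InvalidParameterError("wavelength must be > 0")

    @property
    def k0(self) -> float:
        """In-medium wavenumber (mm^-1)."""
        return _wavenumber(self.wavelength, self.n0)

    @property
    def z0(self) -> float:
        """Depth of the virtual isotropic point source, 1/mu_s' (mm)."""
        return 1.0 / self.mu_s_prime

    @property
    def zb(self) -> float:
        """Extrapolated boundary distance (mm)."""
        return extrapolated_boundary(self.mu_s_prime, self.n0)


@dataclass(frozen=True)
class ThreeLayerMedium:
    """Three-layer slab model of the adult head (scalp / skull / brain).

    Layer 3 is semi-infinite.  Per-layer sequences are ordered from the
    surface inward.

    Parameters
    ----------
    mu_s_prime : sequence of 3 floats
        Per-layer reduced scattering coefficients (mm^-1), all > 0.
    mu_a : sequence of 3 floats
        Per-layer absorption coefficients (mm^-1), all > 0.
    bfi : sequence of 3 floats
        Per-layer blood flow indices alpha*DB (mm^2/s), all >= 0.
    thickness : sequence of 2 floats
        Thicknesses L1, L2 of the two finite layers (mm), > 0.
    """

    mu_s_prime: Sequence[float]
    mu_a: Sequence[float]
    bfi: Sequence[float]
    thickness: Sequence[float] = (5.0, 7.0)
    n0: float = 1.35
    wavelength: float = 785.0

    def __post_init__(self) -> None:
        mus = tuple(float(v) for v in self.mu_s_prime)
        mua = tuple(float(v) for v in self.mu_a)
        bfi = tuple(float(v) for v in self.bfi)
        thick = tuple(float(v) for v in self.thickness)
        if len(mus) != 3 or len(mua) != 3 or len(bfi) != 3:
            raise InvalidParameterError("three layers of mu_s_prime, mu_a, bfi required")
        if len(thick) != 2:
            raise InvalidParameterError("exactly two finite thicknesses (L1, L2) expected")
        if any(v <= 0 for v in mus) or any(v <= 0 for v in mua):
            raise InvalidParameterError("optical coefficients must be > 0")
        if any(v < 0 for v in bfi):
            raise InvalidParameterError("bfi values must be >= 0")
        if any(v <= 0 for v in thick):
            raise InvalidParameterError("layer thicknesses must be > 0")
        if self.n0 < 1 or self.wavelength <= 0:
            raise InvalidParameterError("n0 must be >= 1 and wavelength > 0")
        object.__setattr__(self, "mu_s_prime", mus)
        object.__setattr__(self, "mu_a", mua)
        object.__setattr__(self, "bfi", bfi)
        object.__setattr__(self, "thickness", thick)

    @property
    def k0(self) -> float:
        """In-medium wavenumber (mm^-1)."""
        return _wavenumber(self.wavelength, self.n0)

    @property
    def diffusion_coeffs(self) -> tuple[float, float, float]:
        """Photon diffusion coefficients D_l = 1/(3*mu_s'(l)) (mm)."""
        return tuple(1.0 / (3.0 * m) for m in self.mu_s_prime)

    @property
    def zs(self) -> float:
        """Isotropic source depth in layer 1, 1/mu_s'(1) (mm)."""
        return 1.0 / self.mu_s_prime[0]

    @property
    def zb(self) -> float:
        """Extrapolated boundary distance of layer 1 (mm)."""
        return extrapolated_boundary(self.mu_s_prime[0], self.n0)


@dataclass(frozen=True)
class LagGrid:
    """Ordered grid of correlation lag times (s)."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 1 or tau.size == 0:
            raise InvalidParameterError("tau must be a non-empty 1-D array")
        if not np.all(np.isfinite(tau)) or tau[0] <= 0:
            raise InvalidParameterError("lag times must be finite and positive")
        if np.any(np.diff(tau) <= 0):
            raise InvalidParameterError("lag times must be strictly increasing")
        tau = tau.copy()
        tau.setflags(write=False)
        object.__setattr__(self, "tau", tau)

    @classmethod
    def logspaced(cls, count: int = 128, tau_min: float = 1e-7,
                  tau_max: float = 1e-1) -> "LagGrid":
        """Default multi-tau-style grid: ``count`` log-spaced lags."""
        if count < 2 or tau_min <= 0 or tau_max <= tau_min:
            raise InvalidParameterError("need count >= 2 and 0 < tau_min < tau_max")
        return cls(np.logspace(np.log10(tau_min), np.log10(tau_max), count))

    @property
    def count(self) -> int:
        return int(self.tau.size)

    @property
    def tau_min(self) -> float:
        return float(self.tau[0])

    @property
    def tau_max(self) -> float:
        return float(self.tau[-1])


@dataclass(frozen=True)
class CorrelationCurve:
    """A lag grid paired with g1 and/or g2 values for one acquisition."""

    grid: LagGrid
    g1: Optional[np.ndarray] = None
    g2: Optional[np.ndarray] = None
    beta: Optional[float] = None
    noisy: bool = False

    def __post_init__(self) -> None:
        for name in ("g1", "g2"):
            vals = getattr(self, name)
            if vals is None:
                continue
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.grid.tau.shape:
                raise InvalidParameterError(f"{name} length must match the lag grid")
            if not np.all(np.isfinite(vals)):
                raise NumericalRangeError(f"{name} contains non-finite values")
            object.__setattr__(self, name, vals)
        if self.g1 is None and self.g2 is None:
            raise InvalidParameterError("curve must carry g1 and/or g2")
        if not self.noisy:
            tol = 1e-9
            if self.g1 is not None and (np.any(self.g1 <= 0) or np.any(self.g1 > 1 + tol)):
                raise InvalidParameterError("noiseless g1 must lie in (0, 1]")
            if self.g2 is not None:
                hi = 1.0 + (self.beta if self.beta is not None else 1.0)
                if np.any(self.g2 < 1 - tol) or np.any(self.g2 > hi + tol):
                    raise InvalidParameterError("noiseless g2 must lie in [1, 1+beta]")


@dataclass(frozen=True)
class QuadratureSettings:
    """Gauss-Legendre settings for the q-space Hankel inversion.

    The q-space Green's function decays like exp(-q*(zs+zb))*sinh(q*zb)/q
    at large q, so a fixed interval [0, q_max] with q_max = 40 mm^-1
    captures the integral far below the 1e-6 normalization tolerance for
    source-detector separations of 10-35 mm; 2048 nodes resolve the
    J0(rho*q) oscillations (~13 nodes per period at rho = 25 mm).  Both
    halving checks (node doubling, q_max extension) move g1 by < 1e-9 at
    the defaults.
    """

    q_max: float = 40.0
    nodes: int = 2048

    def __post_init__(self) -> None:
        if self.q_max <= 0:
            raise InvalidParameterError("q_max must be > 0")
        if self.nodes < 64:
            raise InvalidParameterError("quadrature needs at least 64 nodes")


def _semi_infinite_g1_values(medium: SemiInfiniteMedium, rho: float,
                             tau: np.ndarray,
                             bfi: Optional[np.ndarray] = None) -> np.ndarray:
    """g1 values of the two-image-source closed form.

    ``bfi`` optionally overrides the medium BFI with an array broadcastable
    against ``tau`` (used for vectorized dataset generation).
    """
    mus, mua = medium.mu_s_prime, medium.mu_a
    k0 = medium.k0
    z0, zb = medium.z0, medium.zb
    r1 = np.hypot(rho, z0)
    r2 = np.hypot(rho, z0 + 2.0 * zb)
    b = medium.bfi if bfi is None else np.asarray(bfi, dtype=float)
    ksq = 3.0 * mua * mus + 6.0 * mus**2 * k0**2 * b * tau
    with np.errstate(over="raise"):
        try:
            K = np.sqrt(ksq)
            num = np.exp(-K * r1) / r1 - np.exp(-K * r2) / r2
        except FloatingPointError as exc:  # extreme tau*BFI
            raise NumericalRangeError("decay exponent overflow") from exc
    k0sq = np.sqrt(3.0 * mua * mus)
    den = np.exp(-k0sq * r1) / r1 - np.exp(-k0sq * r2) / r2
    g1 = num / den
    if not np.all(np.isfinite(g1)):
        raise NumericalRangeError("non-finite g1 for extreme parameters")
    # strong decay underflows exp(-K*r) to 0; clamp so 0 < g1 <= 1 holds
    return np.clip(g1, 1e-300, 1.0)


def semi_infinite_g1(medium: SemiInfiniteMedium, rho: float,
                     grid: LagGrid) -> CorrelationCurve:
    """Normalized field autocorrelation for the semi-infinite medium.

    Evaluates

    ``G1(rho, tau) = (3*mu_s'/4pi) * (exp(-K*r1)/r1 - exp(-K*r2)/r2)``

    with ``K(tau) = sqrt(3*mu_a*mu_s' + 6*mu_s'^2*k0^2*BFI*tau)``,
    ``r1 = sqrt(rho^2 + z0^2)``, ``r2 = sqrt(rho^2 + (z0 + 2*zb)^2)``,
    and returns ``g1 = G1(tau)/G1(0)``.

    Parameters
    ----------
    medium : SemiInfiniteMedium
    rho : float
        Source-detector separation (mm), > 0.
    grid : LagGrid

    Returns
    -------
    CorrelationCurve
        With ``g1`` populated; ``g1(0) = 1`` exactly by construction.
    """
    if rho <= 0:
        raise InvalidParameterError("rho must be > 0")
    g1 = _semi_infinite_g1_values(medium, rho, grid.tau)
    return CorrelationCurve(grid=grid, g1=g1)


def _three_layer_ghat(medium: ThreeLayerMedium, qsq: np.ndarray,
                      tau: np.ndarray) -> np.ndarray:
    """q-space Green's function of the three-layer medium at the surface.

    Solves the one-dimensional two-point boundary problem of the correlation
    diffusion equation in q-space for an isotropic point source at depth
    ``zs`` in layer 1, with a Dirichlet (extrapolated-boundary) condition at
    ``z = -zb`` and flux/value continuity at the two internal interfaces:

    ``Ghat0 = 3*mu_s1' * sinh(phi1*zb)/phi1
              * [a1*cosh(phi1*(L1-zs))*(a2*c2 + a3*s2)
                 + a2*sinh(phi1*(L1-zs))*(a3*c2 + a2*s2)]
              / [a1*(a2*c2 + a3*s2)*cosh(phi1*(L1+zb))
                 + a2*(a2*s2 + a3*c2)*sinh(phi1*(L1+zb))]``

    with ``a_l = phi_l*D_l``, ``c2/s2 = cosh/sinh(phi2*L2)`` and
    ``phi_l = sqrt(3*mu_a(l)*mu_s'(l) + 6*k0^2*mu_s'(l)^2*DB(l)*tau + q^2)``.

    Numerator and denominator are both scaled by
    ``exp(-(phi1*(L1+zb) + phi2*L2))``; the scale cancels in the ratio and
    keeps every hyperbolic term bounded, so the evaluation never overflows.
    ``qsq`` has shape (nq, 1) and ``tau`` shape (nt,); result is (nq, nt).
    """
    k0sq = medium.k0**2
    L1, L2 = medium.thickness
    D1, D2, D3 = medium.diffusion_coeffs
    zs, zb = medium.zs, medium.zb

    phi = []
    for mus, mua, db in zip(medium.mu_s_prime, medium.mu_a, medium.bfi):
        phi.append(np.sqrt(3.0 * mua * mus + 6.0 * k0sq * mus**2 * db * tau + qsq))
    p1, p2, p3 = phi
    a1, a2, a3 = p1 * D1, p2 * D2, p3 * D3

    # Both Num and Denom are scaled by exp(-(p1*(L1+zb) + p2*L2)).  In the
    # numerator that scale splits as [sinh(p1*zb)*e^{-p1*zb}/p1] times
    # [cosh/sinh(p1*(L1-zs))*e^{-p1*L1}] times [c2/s2 scaled by e^{-p2*L2}].
    # Every factor below is bounded, so the evaluation never overflows.
    e_zs = np.exp(-p1 * zs)
    e_mir = np.exp(-p1 * (2.0 * L1 - zs))
    e_2zb = np.exp(-2.0 * p1 * zb)
    e_2L1b = np.exp(-2.0 * p1 * (L1 + zb))
    e_2L2 = np.exp(-2.0 * p2 * L2)
    c1 = 0.5 * (e_zs + e_mir)        # cosh(p1*(L1-zs)) * exp(-p1*L1)
    s1 = 0.5 * (e_zs - e_mir)        # sinh(p1*(L1-zs)) * exp(-p1*L1)
    c1b = 0.5 * (1.0 + e_2L1b)       # cosh(p1*(L1+zb)) * exp(-p1*(L1+zb))
    s1b = 0.5 * (1.0 - e_2L1b)       # sinh(p1*(L1+zb)) * exp(-p1*(L1+zb))
    c2 = 0.5 * (1.0 + e_2L2)         # cosh(p2*L2) * exp(-p2*L2)
    s2 = 0.5 * (1.0 - e_2L2)         # sinh(p2*L2) * exp(-p2*L2)
    sb = 0.5 * (1.0 - e_2zb) / p1    # sinh(p1*zb) * exp(-p1*zb) / p1

    inner2 = a2 * c2 + a3 * s2
    num = 3.0 * medium.mu_s_prime[0] * sb * (
        a1 * c1 * inner2 + a2 * (a3 * c2 + a2 * s2) * s1)
    den = a1 * inner2 * c1b + a2 * (a2 * s2 + a3 * c2) * s1b
    return num / den


def _three_layer_g1_values(medium: ThreeLayerMedium, rho: float,
                           tau: np.ndarray,
                           quad: QuadratureSettings) -> np.ndarray:
    """Hankel-inverted g1: G0(rho, tau)/G0(rho, 0) on the given lags."""
    x, w = roots_legendre(quad.nodes)
    q = 0.5 * quad.q_max * (x + 1.0)
    wq = 0.5 * quad.q_max * w
    tau_ext = np.concatenate(([0.0], tau))
    ghat = _three_layer_ghat(medium, (q**2)[:, None], tau_ext[None, :])
    kernel = wq * q * j0(rho * q)          # (nq,)
    G = kernel @ ghat                      # (nt+1,), 1/(2*pi) factor cancels
    if not np.all(np.isfinite(G)) or G[0] <= 0:
        raise NumericalRangeError("three-layer Hankel inversion produced "
                                  "non-finite or non-positive G0")
    return G[1:] / G[0]


class ThreeLayerDeepBfiSolver:
    """Fast repeated three-layer g1 evaluation when only the brain-layer
    BFI varies (dataset generation, NLSF iterations).

    The scalp/skull (layer 1/2) factors of the q-space Green's function do
    not depend on the deep BFI, and the semi-infinite third layer enters
    only algebraically through ``a3 = phi3*D3`` (no hyperbolics of phi3), so
    ``Ghat0 = (P1 + P2*a3) / (Q1 + Q2*a3)`` with coefficient arrays P1, P2,
    Q1, Q2 that are precomputed once per (medium, rho, lag grid).  Each
    subsequent g1 evaluation costs one square root and a few multiply-adds
    per quadrature point, and is numerically identical to
    :func:`three_layer_g1`.
    """

    def __init__(self, medium: ThreeLayerMedium, rho: float, tau: np.ndarray,
                 quad: QuadratureSettings = QuadratureSettings()):
        if rho <= 0:
            raise InvalidParameterError("rho must be > 0")
        x, w = roots_legendre(quad.nodes)
        q = 0.5 * quad.q_max * (x + 1.0)
        self._kernel = (0.5 * quad.q_max * w) * q * j0(rho * q)
        qsq = (q**2)[:, None]
        tau_ext = np.concatenate(([0.0], np.asarray(tau, dtype=float)))[None, :]

        k0sq = medium.k0**2
        L1, L2 = medium.thickness
        D1, D2, D3 = medium.diffusion_coeffs
        zs, zb = medium.zs, medium.zb
        mus, mua, bfi = medium.mu_s_prime, medium.mu_a, medium.bfi
        p1 = np.sqrt(3.0 * mua[0] * mus[0]
                     + 6.0 * k0sq * mus[0]**2 * bfi[0] * tau_ext + qsq)
        p2 = np.sqrt(3.0 * mua[1] * mus[1]
                     + 6.0 * k0sq * mus[1]**2 * bfi[1] * tau_ext + qsq)
        a1, a2 = p1 * D1, p2 * D2
        e_zs = np.exp(-p1 * zs)
        e_mir = np.exp(-p1 * (2.0 * L1 - zs))
        e_2zb = np.exp(-2.0 * p1 * zb)
        e_2L1b = np.exp(-2.0 * p1 * (L1 + zb))
        e_2L2 = np.exp(-2.0 * p2 * L2)
        c1 = 0.5 * (e_zs + e_mir)
        s1 = 0.5 * (e_zs - e_mir)
        c1b = 0.5 * (1.0 + e_2L1b)
        s1b = 0.5 * (1.0 - e_2L1b)
        c2 = 0.5 * (1.0 + e_2L2)
        s2 = 0.5 * (1.0 - e_2L2)
        sb = 0.5 * (1.0 - e_2zb) / p1
        pref = 3.0 * mus[0] * sb
        self._P1 = pref * (a1 * c1 * a2 * c2 + a2 * a2 * s2 * s1)
        self._P2 = pref * (a1 * c1 * s2 + a2 * c2 * s1)
        self._Q1 = a1 * a2 * c2 * c1b + a2**2 * s2 * s1b
        self._Q2 = a1 * c1b * s2 + a2 * c2 * s1b
        self._phi3_base = 3.0 * mua[2] * mus[2] + qsq
        self._phi3_flow = 6.0 * k0sq * mus[2]**2 * tau_ext
        self._D3 = D3

    def g1(self, deep_bfi: float) -> np.ndarray:
        """g1 on the lag grid for one brain-layer BFI (mm^2/s)."""
        if deep_bfi < 0:
            raise InvalidParameterError("bfi must be >= 0")
        a3 = self._D3 * np.sqrt(self._phi3_base + self._phi3_flow * deep_bfi)
        ghat = (self._P1 + self._P2 * a3) / (self._Q1 + self._Q2 * a3)
        G = self._kernel @ ghat
        if not np.all(np.isfinite(G)) or G[0] <= 0:
            raise NumericalRangeError("three-layer Hankel inversion produced "
                                      "non-finite or non-positive G0")
        return np.clip(G[1:] / G[0], 1e-300, 1.0)


def three_layer_g1(medium: ThreeLayerMedium, rho: float, grid: LagGrid,
                   quad: QuadratureSettings = QuadratureSettings(),
                   check_convergence: bool = False) -> CorrelationCurve:
    """Normalized field autocorrelation for the three-layer head model.

    The q-space Green's function Ghat0(q, tau) = Num/Denom is inverted to
    real space through ``G0(rho, tau) = (1/2pi) * Int dq Ghat0 * q * J0(rho*q)``
    on a fixed Gauss-Legendre rule, then self-normalized at tau = 0 (where
    the flow term of every phi_l vanishes exactly).

    Parameters
    ----------
    medium : ThreeLayerMedium
    rho : float
        Source-detector separation (mm), > 0.
    grid : LagGrid
    quad : QuadratureSettings, optional
    check_convergence : bool, optional
        When true, re-evaluate with doubled node count and raise
        :class:`ConvergenceError` if any g1 value moves by more than 1e-6.

    Returns
    -------
    CorrelationCurve
        With ``g1`` populated.
    """
    if rho <= 0:
        raise InvalidParameterError("rho must be > 0")
    g1 = _three_layer_g1_values(medium, rho, grid.tau, quad)
    if check_convergence:
        fine = _three_layer_g1_values(
            medium, rho, grid.tau, replace(quad, nodes=2 * quad.nodes))
        err = float(np.max(np.abs(fine - g1)))
        if err > 1e-6:
            raise ConvergenceError(
                f"quadrature not converged: doubling nodes moved g1 by {err:.2e}")
    # Fully decorrelated lags sit below the quadrature noise floor (~1e-12
    # absolute); clamp round-off there so the noiseless-curve invariants
    # 0 < g1 <= 1 hold exactly.
    g1 = np.clip(g1, 1e-300, 1.0)
    return CorrelationCurve(grid=grid, g1=g1)


def siegert_g2(curve: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Map g1 to g2 through the Siegert relation ``g2 = 1 + beta*g1**2``.

    Parameters
    ----------
    curve : CorrelationCurve
        Must have ``g1`` populated.
    beta : float
        Coherence factor in (0, 1].
    """
    if not 0 < beta <= 1:
        raise InvalidParameterError("beta must be in (0, 1]")
    if curve.g1 is None:
        raise InvalidParameterError("curve has no g1 values")
    g2 = 1.0 + beta * curve.g1**2
    return replace(curve, g2=g2, beta=float(beta))


def write_curve_csv(curve: CorrelationCurve, path) -> None:
    """Serialize a curve as CSV with header ``tau,g1,g2`` (15 sig. digits)."""
    df = pd.DataFrame({
        "tau": curve.grid.tau,
        "g1": curve.g1 if curve.g1 is not None else np.full(curve.grid.count, np.nan),
        "g2": curve.g2 if curve.g2 is not None else np.full(curve.grid.count, np.nan),
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_curve_csv(path) -> CorrelationCurve:
    """Read a curve CSV written by :func:`write_curve_csv`.

    Curves read from disk are treated as measured (``noisy=True``), so no
    noiseless-model invariants are enforced on their values.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("tau", "g1", "g2"):
        if col not in df.columns:
            from .errors import FormatError
            raise FormatError(f"curve CSV missing column {col!r}")
    grid = LagGrid(df["tau"].to_numpy())
    g1 = df["g1"].to_numpy()
    g2 = df["g2"].to_numpy()
    return CorrelationCurve(
        grid=grid,
        g1=None if np.all(np.isnan(g1)) else g1,
        g2=None if np.all(np.isnan(g2)) else g2,
        noisy=True,
    )
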