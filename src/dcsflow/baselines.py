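"""Nonlinear least-squares fitting (NLSF) of (BFI, beta) from g2 curves.

The classical route to the blood flow index: fix the tissue optics and
geometry, then fit the two free parameters of the analytical g2 model — the
(deepest-layer) BFI and the coherence factor beta — to a measured curve by
minimizing the sum of squared residuals.  Two solver families are provided:
a bounded trust-region least-squares solver ("least-squares") and a
derivative-free Nelder-Mead simplex ("simplex").  Both optimize BFI on a
log10 scale internally for conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .errors import InvalidParameterError
from .forward_models import (
    CorrelationCurve,
    QuadratureSettings,
    SemiInfiniteMedium,
    ThreeLayerMedium,
    ThreeLayerDeepBfiSolver,
    _semi_infinite_g1_values,
)

__all__ = ["FitResult", "nlsf_fit", "write_fit_results_csv"]

#: Default BFI search bounds (mm^2/s) and initial guess.
DEFAULT_BFI_BOUNDS = (1e-9, 1e-4)
DEFAULT_BETA_BOUNDS = (1e-6, 1.0)
DEFAULT_INIT = (1e-6, 0.5)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one NLSF inversion."""

    bfi_hat: float
    beta_hat: float
    residual_norm: float
    iterations: int
    converged: bool
    method: str

    def __post_init__(self) -> None:
        if self.bfi_hat < 0 or not 0 < self.beta_hat <= 1:
            raise InvalidParameterError("fit result outside parameter bounds")


def _g2_model_factory(medium, rho, tau, quad):
    """Return f(bfi, beta) -> model g2 with only the deep BFI and beta free."""
    if isinstance(medium, SemiInfiniteMedium):
        def g2_of(bfi, beta):
            m = dc_replace(medium, bfi=bfi)
            g1 = _semi_infinite_g1_values(m, rho, tau)
            return 1.0 + beta * g1**2
    elif isinstance(medium, ThreeLayerMedium):
        solver = ThreeLayerDeepBfiSolver(medium, rho, tau, quad)

        def g2_of(bfi, beta):
            return 1.0 + beta * solver.g1(bfi) ** 2
    else:
        raise InvalidParameterError(f"unsupported medium type {type(medium).__name__}")
    return g2_of


def nlsf_fit(curve: CorrelationCurve, medium, rho: float = 25.0,
             method: str = "least-squares",
             init: tuple = DEFAULT_INIT,
             bfi_bounds: tuple = DEFAULT_BFI_BOUNDS,
             beta_bounds: tuple = DEFAULT_BETA_BOUNDS,
             quad: QuadratureSettings = QuadratureSettings(),
             max_iter: int = 2000) -> FitResult:
    """Fit (deep-layer BFI, beta) to a measured g2 curve.

    Minimizes ``sum_tau (g2_model(tau; BFI, beta) - g2_meas(tau))^2`` within
    bounds.  The tissue optics, layer thicknesses and geometry of ``medium``
    are held fixed; only the (deepest-layer) BFI and beta are free, and BFI
    is optimized as log10(BFI).

    Parameters
    ----------
    curve : CorrelationCurve
        Must carry g2 values.
    medium : SemiInfiniteMedium or ThreeLayerMedium
        Template medium; its BFI entry for the fitted layer is ignored.
    rho : float
        Source-detector separation (mm).
    method : {"least-squares", "simplex"}
        Bounded trust-region solver or Nelder-Mead simplex.
    init : (bfi0, beta0)
        Initial guess (mm^2/s, unitless).
    max_iter : int
        Iteration/evaluation cap; exceeding it returns the best iterate
        with ``converged=False``.

    Returns
    -------
    FitResult
    """
    if curve.g2 is None:
        raise InvalidParameterError("curve has no g2 values")
    if method not in ("least-squares", "simplex"):
        raise InvalidParameterError(
            f"method must be 'least-squares' or 'simplex', got {method!r}")
    tau = curve.grid.tau
    y = curve.g2
    g2_of = _g2_model_factory(medium, rho, tau, quad)
    lb = [np.log10(bfi_bounds[0]), beta_bounds[0]]
    ub = [np.log10(bfi_bounds[1]), beta_bounds[1]]
    x0 = np.clip([np.log10(init[0]), init[1]], lb, ub)

    if method == "least-squares":
        sol = least_squares(
            lambda p: g2_of(10.0 ** p[0], p[1]) - y,
            x0=x0, bounds=(lb, ub),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_iter,
        )
        bfi_hat, beta_hat = 10.0 ** sol.x[0], float(sol.x[1])
        resid = float(np.sum(sol.fun**2))
        iters = int(sol.nfev)
        converged = bool(sol.status > 0)
    else:
        def objective(p):
            pc = np.clip(p, lb, ub)
            r = g2_of(10.0 ** pc[0], pc[1]) - y
            # quadratic penalty keeps the simplex inside the box
            return float(np.sum(r**2)) + 1e3 * float(np.sum((p - pc) ** 2))

        sol = minimize(objective, x0=x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": max_iter, "maxfev": max_iter})
        pc = np.clip(sol.x, lb, ub)
        bfi_hat, beta_hat = 10.0 ** pc[0], float(pc[1])
        resid = float(np.sum((g2_of(bfi_hat, beta_hat) - y) ** 2))
        iters = int(sol.nit)
        converged = bool(sol.success)

    return FitResult(bfi_hat=float(bfi_hat), beta_hat=beta_hat,
                     residual_norm=resid, iterations=iters,
                     converged=converged, method=method)


def write_fit_results_csv(results, path) -> None:
    """Emit fit results as CSV rows: sample_id,method,bfi_hat,beta_hat,residual,converged."""
    df = pd.DataFrame([
        {"sample_id": i, "method": r.method, "bfi_hat": r.bfi_hat,
         "beta_hat": r.beta_hat, "residual": r.residual_norm,
         "converged": r.converged}
        for i, r in enumerate(results)
    ])
    df.to_csv(path, index=False, float_format="%.15g")
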