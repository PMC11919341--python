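"""Metrics, relative-BFI computation, and sweep experiments.

Covers the quantitative evaluation toolbox: per-target mean absolute error
and R^2, residual summaries, signed percent error with normal-approximation
confidence intervals, relative BFI time series, noise-level sweeps (photon
rate / integration time) and hyperparameter sweeps (hidden nodes, ridge
regularizer, training-set size, lag-grid length).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .dataset import BFI_LABEL_SCALE, DatasetSpec, generate_dataset
from .errors import InvalidParameterError
from .forward_models import CorrelationCurve, siegert_g2
from .noise_model import AcquisitionParams, fit_decay_rate, noise_sigma
from .rvfl import init_random_layer, predict, train_elm, train_rvfl

__all__ = [
    "MetricsReport",
    "SweepResult",
    "compute_metrics",
    "rbfi_series",
    "run_noise_sweep",
    "run_hyperparam_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    """Per-target accuracy summary for an N x m prediction matrix.

    ``error_pct`` statistics are signed percent errors 100*(Yhat-Y)/Y;
    entries with zero truth are excluded (``n_excluded`` counts them) and
    the 95% CI is the normal approximation mean +/- 1.96*std/sqrt(N).
    """

    mae: np.ndarray
    mae_sum: float
    r2: np.ndarray
    residual_mean: np.ndarray
    residual_std: np.ndarray
    error_pct_mean: np.ndarray
    error_pct_ci_low: np.ndarray
    error_pct_ci_high: np.ndarray
    n_excluded: int = 0


def compute_metrics(Yhat: np.ndarray, Y: np.ndarray) -> MetricsReport:
    """Compute MAE, R^2, residual summaries and Error% CI per column.

    ``R^2 = 1 - SS_res/SS_tot`` per column; zero-variance truth columns
    make R^2 undefined and raise.
    """
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Yhat.shape != Y.shape:
        raise InvalidParameterError("Yhat and Y shapes must match")
    resid = Yhat - Y
    mae = np.abs(resid).mean(axis=0)
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    if np.any(ss_tot == 0):
        raise InvalidParameterError("R^2 undefined for zero-variance truth column")
    r2 = 1.0 - np.sum(resid**2, axis=0) / ss_tot

    m = Y.shape[1]
    epm = np.empty(m)
    lo = np.empty(m)
    hi = np.empty(m)
    n_excluded = 0
    for j in range(m):
        mask = Y[:, j] != 0
        n_excluded += int((~mask).sum())
        if not np.any(mask):
            raise InvalidParameterError(f"all truth values in column {j} are zero")
        ep = 100.0 * resid[mask, j] / Y[mask, j]
        epm[j] = ep.mean()
        half = 1.96 * ep.std(ddof=0) / np.sqrt(ep.size)
        lo[j], hi[j] = epm[j] - half, epm[j] + half
    if n_excluded:
        logger.info("Error%%: excluded %d zero-truth entries", n_excluded)
    return MetricsReport(
        mae=mae, mae_sum=float(mae.sum()), r2=r2,
        residual_mean=resid.mean(axis=0), residual_std=resid.std(axis=0, ddof=0),
        error_pct_mean=epm, error_pct_ci_low=lo, error_pct_ci_high=hi,
        n_excluded=n_excluded,
    )


def rbfi_series(bfi: np.ndarray, bfi0: float) -> np.ndarray:
    """Relative BFI: elementwise ``BFI / BFI0``.

    ``BFI0`` is the baseline (e.g. initial) blood flow index, > 0.
    """
    if not np.isfinite(bfi0) or bfi0 <= 0:
        raise InvalidParameterError("bfi0 must be positive")
    return np.asarray(bfi, dtype=float) / bfi0


@dataclass(frozen=True)
class SweepResult:
    """Grid values paired with per-point evaluation records."""

    swept: str
    values: tuple
    records: tuple  # one dict per grid point

    def __post_init__(self) -> None:
        if len(self.values) != len(self.records):
            raise InvalidParameterError("values and records must have equal length")
        object.__setattr__(self, "values", tuple(self.values))
        object.__setattr__(self, "records", tuple(self.records))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{"axis_value": v, **r}
                             for v, r in zip(self.values, self.records)])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.15g")


def run_noise_sweep(axis: str, grid_values, models: dict,
                    spec: DatasetSpec | None = None,
                    truth_bfi: float = 6e-6, truth_beta: float = 0.5,
                    fixed_intensity: float = 2.5e4, fixed_time: float = 20.0,
                    n_curves: int = 100, seed: int = 0) -> SweepResult:
    """Reconstruction dispersion versus noise level.

    For each grid value of the swept acquisition parameter (photon rate
    ``intensity`` in cps or ``integration_time`` in s), ``n_curves`` noisy
    replicates of one fixed-truth curve are generated and inverted with
    every model in ``models`` (name -> trained RVFL/ELM); the mean, std and
    95% CI of the reconstructed (deep) BFI — in 1e-6 mm^2/s units — are
    recorded per point.

    The default truth is the three-layer fixed evaluation condition
    (scalp/skull/brain BFIs 1e-6, 0, 6e-6 mm^2/s and beta 0.5); pass a
    semi-infinite ``spec`` to sweep that geometry instead.
    """
    if axis not in ("intensity", "integration_time"):
        raise InvalidParameterError(
            "axis must be 'intensity' or 'integration_time'")
    grid_values = list(grid_values)
    if grid_values != sorted(grid_values):
        raise InvalidParameterError("grid values must be ordered")
    if spec is None:
        spec = DatasetSpec(model_kind="three-layer", n_samples=1)
    # one noiseless truth curve shared by every grid point
    medium = spec.medium(truth_bfi)
    grid = spec.grid
    from .forward_models import semi_infinite_g1, three_layer_g1
    if spec.model_kind == "semi-infinite":
        base = semi_infinite_g1(medium, spec.rho, grid)
    else:
        base = three_layer_g1(medium, spec.rho, grid)
    curve = siegert_g2(base, truth_beta)
    decay = fit_decay_rate(curve)

    rng = np.random.default_rng(seed)
    records = []
    for value in grid_values:
        intensity = value if axis == "intensity" else fixed_intensity
        t_int = value if axis == "integration_time" else fixed_time
        acq = AcquisitionParams(intensity=intensity, integration_time=t_int,
                                bin_width=spec.tau_min, beta=truth_beta)
        sigma = noise_sigma(acq, decay, grid)
        noisy = curve.g2 + sigma * rng.standard_normal((n_curves, grid.count))
        rec = {}
        for name, model in models.items():
            bfi_hat = predict(model, noisy)[:, 0]  # 1e-6 mm^2/s units
            mean = float(bfi_hat.mean())
            std = float(bfi_hat.std(ddof=0))
            half = 1.96 * std / np.sqrt(n_curves)
            rec[f"{name}_mean"] = mean
            rec[f"{name}_std"] = std
            rec[f"{name}_ci_low"] = mean - half
            rec[f"{name}_ci_high"] = mean + half
        records.append(rec)
    return SweepResult(swept=axis, values=tuple(grid_values), records=tuple(records))


_SWEEP_AXES = ("hidden_nodes", "lambda", "train_size", "lag_length")


def run_hyperparam_sweep(axis: str, grid_values, spec: DatasetSpec,
                         archs=("rvfl", "elm"), hidden_nodes: int = 500,
                         lam: float = 1e-6, activation: str = "sigmoid",
                         layer_seed: int = 0, test_size: int | None = None,
                         test_seed_offset: int = 10_000,
                         n_seeds: int = 1) -> SweepResult:
    """Train/test accuracy versus one network or data hyperparameter.

    One random-layer seed is shared across grid points so curves reflect
    the swept axis rather than seed noise; ``n_seeds > 1`` repeats each
    point with shifted data/layer seeds and adds across-seed std columns.

    Per grid point the records carry, for each architecture, the summed
    (BFI + beta) train and test MAE plus informational train wall-time.
    The ``lambda`` axis retrains only the RVFL (the ELM has no ridge
    hyperparameter); ``train_size`` subsets one fixed dataset from the
    front so points are nested; ``lag_length`` regenerates the datasets on
    shorter log grids spanning the same lag range.
    """
    if axis not in _SWEEP_AXES:
        raise InvalidParameterError(f"axis must be one of {_SWEEP_AXES}")
    grid_values = list(grid_values)
    if test_size is None:
        test_size = max(1, spec.n_samples // 10)
    archs = ("rvfl",) if axis == "lambda" else tuple(archs)

    cache: dict = {}  # spec -> dataset; axes like train_size reuse data across points

    def _dataset(ds: DatasetSpec):
        if ds not in cache:
            cache[ds] = generate_dataset(ds)
        return cache[ds]

    records = []
    for value in grid_values:
        per_seed = {f"{a}_{s}": [] for a in archs for s in ("mae_train", "mae_test")}
        times = {a: [] for a in archs}
        for k in range(n_seeds):
            dspec = dc_replace(spec, seed=spec.seed + k)
            tspec = dc_replace(spec, n_samples=test_size,
                               seed=spec.seed + test_seed_offset + k)
            L, cur_lam = hidden_nodes, lam
            if axis == "lambda":
                cur_lam = float(value)
            elif axis == "hidden_nodes":
                L = int(value)
            elif axis == "train_size":
                pass  # handled by subsetting below
            elif axis == "lag_length":
                dspec = dc_replace(dspec, n_lags=int(value))
                tspec = dc_replace(tspec, n_lags=int(value))
            train = _dataset(dspec)
            test = _dataset(tspec)
            Xtr, Ytr = train.X, train.Y
            if axis == "train_size":
                Xtr, Ytr = Xtr[: int(value)], Ytr[: int(value)]
            layer = init_random_layer(Xtr.shape[1], L, activation,
                                      seed=layer_seed + k)
            for arch in archs:
                t0 = time.perf_counter()
                if arch == "rvfl":
                    model = train_rvfl(Xtr, Ytr, layer, cur_lam)
                else:
                    model = train_elm(Xtr, Ytr, layer)
                times[arch].append(time.perf_counter() - t0)
                per_seed[f"{arch}_mae_train"].append(
                    float(np.abs(predict(model, Xtr) - Ytr).mean(axis=0).sum()))
                per_seed[f"{arch}_mae_test"].append(
                    float(np.abs(predict(model, test.X) - test.Y).mean(axis=0).sum()))
        rec = {}
        for key, vals in per_seed.items():
            rec[key] = float(np.mean(vals))
            if n_seeds > 1:
                rec[f"{key}_seed_std"] = float(np.std(vals, ddof=1))
        for arch in archs:
            rec[f"{arch}_train_time"] = float(np.mean(times[arch]))
        records.append(rec)
    return SweepResult(swept=axis, values=tuple(grid_values), records=tuple(records))
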