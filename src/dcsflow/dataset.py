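"""Labeled dataset generation for g2 inversion networks.

Each sample is one noisy g2 curve on a shared log-spaced lag grid; its labels
are the blood flow index (deepest-layer BFI for the three-layer model) and
the coherence factor beta.  BFI labels are stored and regressed in units of
1e-6 mm^2/s so the two label columns have comparable magnitudes.

The generation pipeline per sample is: forward model -> Siegert relation ->
single-exponential decay fit on the noiseless curve -> correlator noise
sigma -> Gaussian noise injection.  Everything is deterministic under the
dataset seed.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .errors import FormatError, InvalidParameterError
from .forward_models import (
    CorrelationCurve,
    LagGrid,
    QuadratureSettings,
    SemiInfiniteMedium,
    ThreeLayerDeepBfiSolver,
    ThreeLayerMedium,
    _semi_infinite_g1_values,
)
from .noise_model import AcquisitionParams, add_noise, fit_decay_rate, noise_sigma

__all__ = [
    "BFI_LABEL_SCALE",
    "DatasetSpec",
    "LabeledDataset",
    "sample_labels",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger(__name__)

#: BFI labels are expressed in units of 1e-6 mm^2/s (mm^2/s * BFI_LABEL_SCALE).
BFI_LABEL_SCALE = 1e6

#: Fixed tissue optics used for generation (mm^-1).
SEMI_INFINITE_OPTICS = {"mu_s_prime": 1.6, "mu_a": 0.0027}
THREE_LAYER_OPTICS = {
    "mu_s_prime": (0.635, 0.851, 1.099),
    "mu_a": (0.019, 0.014, 0.019),
    "thickness": (5.0, 7.0),
}


@dataclass(frozen=True)
class DatasetSpec:
    """Full recipe for one labeled dataset.

    Defaults reproduce the standard study conditions: N = 5,000 training
    curves of n = 128 log-spaced lags in [1e-7, 1e-1] s at rho = 25 mm,
    785 nm, n0 = 1.35; BFI uniform in [1e-8, 1e-5] mm^2/s, beta uniform in
    [0.01, 1]; photon rate uniform in [1.5e4, 2.5e4] cps and integration
    time uniform in [5, 25] s.  For the three-layer model the superficial
    (scalp, skull) BFIs are fixed at 1e-6 and 0 mm^2/s and the label is the
    cerebral (layer-3) BFI.
    """

    model_kind: str = "semi-infinite"
    n_samples: int = 5000
    n_lags: int = 128
    tau_min: float = 1e-7
    tau_max: float = 1e-1
    bfi_range: tuple = (1e-8, 1e-5)
    beta_range: tuple = (0.01, 1.0)
    intensity_range: tuple = (1.5e4, 2.5e4)
    time_range: tuple = (5.0, 25.0)
    rho: float = 25.0
    wavelength: float = 785.0
    n0: float = 1.35
    superficial_bfi: tuple = (1e-6, 0.0)
    seed: int = 0
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.model_kind not in ("semi-infinite", "three-layer"):
            raise InvalidParameterError(
                f"model_kind must be 'semi-infinite' or 'three-layer', "
                f"got {self.model_kind!r}")
        if self.n_samples <= 0 or self.n_lags < 2:
            raise InvalidParameterError("n_samples and n_lags must be positive")
        for name in ("bfi_range", "beta_range", "intensity_range", "time_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi or lo <= 0:
                raise InvalidParameterError(f"{name} must satisfy 0 < low <= high")

    @property
    def grid(self) -> LagGrid:
        return LagGrid.logspaced(self.n_lags, self.tau_min, self.tau_max)

    def medium(self, bfi: float):
        """Medium object for one sample with the given (deep) BFI in mm^2/s."""
        if self.model_kind == "semi-infinite":
            return SemiInfiniteMedium(
                bfi=bfi, n0=self.n0, wavelength=self.wavelength,
                **SEMI_INFINITE_OPTICS)
        return ThreeLayerMedium(
            bfi=(*self.superficial_bfi, bfi), n0=self.n0,
            wavelength=self.wavelength, **THREE_LAYER_OPTICS)


@dataclass(frozen=True)
class LabeledDataset:
    """N x n matrix of g2 samples with N x 2 labels [BFI, beta].

    ``Y[:, 0]`` is BFI in units of 1e-6 mm^2/s; ``Y[:, 1]`` is beta.
    """

    X: np.ndarray
    Y: np.ndarray
    grid: LagGrid
    spec: DatasetSpec
    bfi_units: str = "1e-6 mm^2/s"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise InvalidParameterError("X and Y must be 2-D with equal row counts")
        if X.shape[1] != self.grid.count:
            raise InvalidParameterError("X column count must match the lag grid")
        if Y.shape[1] != 2:
            raise InvalidParameterError("Y must have 2 columns [BFI, beta]")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def n_samples(self) -> int:
        return int(self.X.shape[0])


def sample_labels(spec: DatasetSpec, seed: int | None = None):
    """Draw per-sample labels and acquisition settings.

    Independent uniform draws on the linear scale within each spec range.

    Returns
    -------
    dict of ndarray
        Keys ``bfi`` (mm^2/s), ``beta``, ``intensity`` (cps), ``time`` (s),
        each of length ``spec.n_samples``.  Deterministic under ``seed``
        (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_samples
    return {
        "bfi": rng.uniform(*spec.bfi_range, n),
        "beta": rng.uniform(*spec.beta_range, n),
        "intensity": rng.uniform(*spec.intensity_range, n),
        "time": rng.uniform(*spec.time_range, n),
    }


def generate_dataset(spec: DatasetSpec,
                     quad: QuadratureSettings = QuadratureSettings()) -> LabeledDataset:
    """Generate a labeled dataset of (noisy) g2 curves per the spec.

    The semi-infinite path evaluates the closed-form g1 for all samples in
    one vectorized pass; the three-layer path runs the Hankel quadrature
    per sample (only the deep-layer BFI varies).  Noise seeds derive from
    ``spec.seed`` so identical specs give bit-identical datasets.
    """
    grid = spec.grid
    tau = grid.tau
    draws = sample_labels(spec)
    n = spec.n_samples

    if spec.model_kind == "semi-infinite":
        medium = spec.medium(bfi=0.0)
        g1 = _semi_infinite_g1_values(
            medium, spec.rho, tau[None, :], bfi=draws["bfi"][:, None])
    else:
        solver = ThreeLayerDeepBfiSolver(spec.medium(0.0), spec.rho, tau, quad)
        g1 = np.empty((n, tau.size))
        for i, bfi in enumerate(draws["bfi"]):
            try:
                g1[i] = solver.g1(bfi)
            except Exception as exc:
                raise type(exc)(f"sample {i}: {exc}") from exc

    g2 = 1.0 + draws["beta"][:, None] * g1**2

    X = g2.copy()
    if not spec.noiseless:
        noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
        for i in range(n):
            curve = CorrelationCurve(grid=grid, g2=g2[i], beta=draws["beta"][i],
                                     noisy=True)
            try:
                fit = fit_decay_rate(curve)
                acq = AcquisitionParams(
                    intensity=draws["intensity"][i],
                    integration_time=draws["time"][i],
                    bin_width=spec.tau_min,
                    beta=draws["beta"][i],
                )
                sigma = noise_sigma(acq, fit, grid)
            except Exception as exc:
                raise type(exc)(f"sample {i}: {exc}") from exc
            X[i] = g2[i] + sigma * noise_rng.standard_normal(tau.size)

    Y = np.column_stack([draws["bfi"] * BFI_LABEL_SCALE, draws["beta"]])
    return LabeledDataset(X=X, Y=Y, grid=grid, spec=spec)


def write_dataset(ds: LabeledDataset, path) -> None:
    """Serialize a dataset as CSV with a commented metadata header.

    Header lines carry the model kind, seed, BFI units, the full lag list
    and the JSON-encoded spec; each data row is the n g2 values followed by
    ``bfi,beta`` (full float round-trip precision).
    """
    buf = io.StringIO()
    buf.write("# dcsflow-dataset v1\n")
    buf.write(f"# model={ds.spec.model_kind}\n")
    buf.write(f"# seed={ds.spec.seed}\n")
    buf.write(f"# bfi_units={ds.bfi_units}\n")
    buf.write("# tau=" + ",".join(f"{t:.17g}" for t in ds.grid.tau) + "\n")
    buf.write("# spec=" + json.dumps(asdict(ds.spec)) + "\n")
    np.savetxt(buf, np.hstack([ds.X, ds.Y]), fmt="%.17g", delimiter=",")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_dataset(path) -> LabeledDataset:
    """Read a dataset CSV written by :func:`write_dataset`.

    Files lacking the metadata block are accepted with default metadata
    (a warning is logged); malformed rows raise :class:`FormatError`.
    """
    meta = {}
    data_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            data_lines.append((lineno, line))
    if not data_lines:
        raise FormatError(f"{path}: no data rows")

    ncols = len(data_lines[0][1].split(","))
    rows = np.empty((len(data_lines), ncols))
    for i, (lineno, line) in enumerate(data_lines):
        parts = line.split(",")
        if len(parts) != ncols:
            raise FormatError(
                f"{path}:{lineno}: expected {ncols} columns, found {len(parts)}")
        try:
            rows[i] = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc

    if "spec" in meta:
        spec_dict = json.loads(meta["spec"])
        for key in ("bfi_range", "beta_range", "intensity_range", "time_range",
                    "superficial_bfi"):
            spec_dict[key] = tuple(spec_dict[key])
        spec = DatasetSpec(**spec_dict)
    else:
        logger.warning("%s: no metadata block; applying default dataset spec", path)
        spec = DatasetSpec(n_samples=rows.shape[0], n_lags=ncols - 2)
    if "tau" in meta:
        grid = LagGrid(np.array([float(t) for t in meta["tau"].split(",")]))
    else:
        grid = LagGrid.logspaced(ncols - 2, spec.tau_min, spec.tau_max)
    if grid.count != ncols - 2:
        raise FormatError(
            f"{path}: {ncols - 2} g2 columns but {grid.count} lag times")
    # spec.n_samples describes the recipe; the file may hold a subset
    if rows.shape[0] != spec.n_samples:
        spec = DatasetSpec(**{**asdict(spec), "n_samples": rows.shape[0]})
    return LabeledDataset(X=rows[:, :-2], Y=rows[:, -2:], grid=grid, spec=spec)
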