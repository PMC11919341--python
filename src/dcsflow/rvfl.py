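"""Single-hidden-layer networks with closed-form training.

Two architectures for regressing (BFI, beta) from g2 curves:

* ELM (extreme learning machine): a random frozen hidden layer; the output
  weights are the minimum-norm least-squares solution via the Moore-Penrose
  pseudoinverse.
* RVFL (random vector functional link): the same random hidden layer plus
  direct input-to-output links; the output weights solve a ridge problem in
  closed form, using the primal normal equations when n + L <= N and the
  dual (sample-space Gram) form otherwise.

Neither architecture updates the random layer: training is a single linear
solve, which is what makes re-training effectively instantaneous.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import linalg

from .errors import DimensionError, FormatError, InvalidConfigError, InvalidParameterError

__all__ = [
    "RandomLayer",
    "RVFLModel",
    "ELMModel",
    "ACTIVATIONS",
    "init_random_layer",
    "design_matrix",
    "train_rvfl",
    "train_elm",
    "predict",
    "count_params_flops",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1

ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "sine": np.sin,
    "rbf": lambda z: np.exp(-(z**2)),
}

#: Label scaling metadata attached to every saved model.
LABEL_SCALING = {"bfi": "1e-6 mm^2/s", "beta": "unitless"}


@dataclass(frozen=True)
class RandomLayer:
    """Frozen random input-to-hidden mapping.

    ``W`` is L x n with entries ~ Uniform(-1, 1); ``sigma_bias`` holds the L
    hidden biases ~ Uniform(0, 1).  Never updated by training.
    """

    W: np.ndarray
    sigma_bias: np.ndarray
    activation: str
    seed: int

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        b = np.asarray(self.sigma_bias, dtype=float)
        if W.ndim != 2 or b.ndim != 1 or W.shape[0] != b.size:
            raise DimensionError("W must be L x n with L matching sigma_bias")
        if self.activation not in ACTIVATIONS:
            raise InvalidConfigError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(ACTIVATIONS)}")
        W = W.copy(); W.setflags(write=False)
        b = b.copy(); b.setflags(write=False)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "sigma_bias", b)

    @property
    def n(self) -> int:
        return int(self.W.shape[1])

    @property
    def L(self) -> int:
        return int(self.W.shape[0])


@dataclass(frozen=True)
class RVFLModel:
    """Trained RVFL: random layer + (n+L) x m output weights."""

    layer: RandomLayer
    omega: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        if omega.ndim != 2 or omega.shape[0] != self.layer.n + self.layer.L:
            raise DimensionError("omega must have n + L rows (direct links included)")
        object.__setattr__(self, "omega", omega)

    @property
    def arch(self) -> str:
        return "rvfl"


@dataclass(frozen=True)
class ELMModel:
    """Trained ELM: random layer + L x m output weights."""

    layer: RandomLayer
    omega: np.ndarray
    rcond: float = 1e-15

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        if omega.ndim != 2 or omega.shape[0] != self.layer.L:
            raise DimensionError("omega must have L rows")
        object.__setattr__(self, "omega", omega)

    @property
    def arch(self) -> str:
        return "elm"


Model = Union[RVFLModel, ELMModel]


def init_random_layer(n: int, L: int, activation: str = "sigmoid",
                      seed: int = 0) -> RandomLayer:
    """Draw a frozen random layer: W ~ U(-1, 1), biases ~ U(0, 1).

    ``L = 0`` is allowed and makes the RVFL a pure linear model on the
    direct links.
    """
    if n < 1 or L < 0:
        raise InvalidParameterError("need n >= 1 and L >= 0")
    if activation not in ACTIVATIONS:
        raise InvalidConfigError(
            f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, n))
    sigma = rng.uniform(0.0, 1.0, size=L)
    return RandomLayer(W=W, sigma_bias=sigma, activation=activation, seed=seed)


def design_matrix(layer: RandomLayer, X: np.ndarray, arch: str) -> np.ndarray:
    """Hidden-layer design matrix.

    ELM: ``H = theta(X W^T + sigma)`` of shape N x L.  RVFL: ``[X | H2]``
    of shape N x (n+L) — raw inputs as direct links, hidden outputs after.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.n:
        raise DimensionError(f"X has {X.shape[1]} columns, layer expects {layer.n}")
    if arch not in ("elm", "rvfl"):
        raise InvalidConfigError(f"arch must be 'elm' or 'rvfl', got {arch!r}")
    theta = ACTIVATIONS[layer.activation]
    H2 = theta(X @ layer.W.T + layer.sigma_bias) if layer.L else np.empty((X.shape[0], 0))
    if arch == "elm":
        return H2
    return np.hstack([X, H2])


def train_rvfl(X: np.ndarray, Y: np.ndarray, layer: RandomLayer,
               lam: float = 1e-6) -> RVFLModel:
    """Closed-form ridge solution for the RVFL output weights.

    Primal branch for n + L <= N:
    ``omega = (H^T H + lam*I_{n+L})^{-1} H^T Y``;
    dual branch for N < n + L:
    ``omega = H^T (H H^T + lam*I_N)^{-1} Y``.
    The identity matrix is sized to whichever Gram matrix is inverted.
    """
    if lam <= 0:
        raise InvalidParameterError(
            "ridge regularizer lam must be > 0 (lam = 0 makes the Gram "
            "system singular whenever H is rank-deficient)")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise DimensionError("X and Y must have equal row counts")
    H = design_matrix(layer, X, "rvfl")
    N, p = H.shape
    if p <= N:
        omega = linalg.solve(H.T @ H + lam * np.eye(p), H.T @ Y, assume_a="pos")
    else:
        omega = H.T @ linalg.solve(H @ H.T + lam * np.eye(N), Y, assume_a="pos")
    return RVFLModel(layer=layer, omega=omega, lam=float(lam))


def train_elm(X: np.ndarray, Y: np.ndarray, layer: RandomLayer,
              rcond: float = 1e-15) -> ELMModel:
    """Minimum-norm least-squares ELM training, ``omega = pinv(H) Y``.

    The pseudoinverse is computed by SVD with relative rank tolerance
    ``rcond`` (recorded in the model).  An all-zero design matrix degrades
    to the zero solution with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise DimensionError("X and Y must have equal row counts")
    H = design_matrix(layer, X, "elm")
    if not np.any(H):
        warnings.warn("design matrix is identically zero; returning the "
                      "minimum-norm (zero) solution", RuntimeWarning)
    omega = np.linalg.pinv(H, rcond=rcond) @ Y
    return ELMModel(layer=layer, omega=omega, rcond=rcond)


def predict(model: Model, X: np.ndarray) -> np.ndarray:
    """Network output ``Yhat = H(X) omega`` (N x m).

    The BFI column is on the trained label scale (1e-6 mm^2/s units).
    """
    H = design_matrix(model.layer, X, model.arch)
    return H @ model.omega


def count_params_flops(n: int, L: int, m: int, arch: str) -> tuple[int, int]:
    """Parameter and inference-FLOP counts.

    Parameters: random input weights (n*L) + hidden biases (L) + trained
    output weights (L*m for ELM, (n+L)*m for RVFL).

    FLOPs (per sample, documented convention): multiplies and adds counted
    separately for every weight (2 per weight), one add per hidden bias,
    one evaluation per activation.
    """
    if n < 1 or L < 0 or m < 1:
        raise InvalidParameterError("dimensions must be positive")
    if arch == "elm":
        out_rows = L
    elif arch == "rvfl":
        out_rows = n + L
    else:
        raise InvalidConfigError(f"arch must be 'elm' or 'rvfl', got {arch!r}")
    params = n * L + L + out_rows * m
    flops = 2 * n * L + 2 * L + 2 * out_rows * m
    return params, flops


def save_model(model: Model, path) -> None:
    """Serialize a trained model to JSON (arrays as nested lists)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "arch": model.arch,
        "n": model.layer.n,
        "L": model.layer.L,
        "m": int(model.omega.shape[1]),
        "activation": model.layer.activation,
        "seed": model.layer.seed,
        "label_scaling": LABEL_SCALING,
        "W": model.layer.W.tolist(),
        "sigma_bias": model.layer.sigma_bias.tolist(),
        "omega": model.omega.tolist(),
    }
    if model.arch == "rvfl":
        payload["lambda"] = model.lam
    else:
        payload["rcond"] = model.rcond
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> Model:
    """Load a model saved by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise FormatError(f"unsupported model format: {payload.get('format_version')}")
    layer = RandomLayer(
        W=np.array(payload["W"], dtype=float).reshape(payload["L"], payload["n"]),
        sigma_bias=np.array(payload["sigma_bias"], dtype=float),
        activation=payload["activation"],
        seed=payload["seed"],
    )
    omega = np.array(payload["omega"], dtype=float)
    if payload["arch"] == "rvfl":
        return RVFLModel(layer=layer, omega=omega, lam=payload["lambda"])
    return ELMModel(layer=layer, omega=omega, rcond=payload["rcond"])
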