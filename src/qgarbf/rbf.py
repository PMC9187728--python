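"""Self-organizing radial-basis-function regression network.

Hidden-unit centers come from k-means clustering of the (normalized) inputs,
widths either from the spread hyperparameter or from the classical rule
sigma = c_max / sqrt(2h), and output weights from a linear least-squares
solve of the hidden activations against the targets.  The spread is the
single scalar the optimizers search.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .preprocess import FEATURE_ORDER, NormalizationParams

__all__ = [
    "RBFConfig",
    "RBFModel",
    "kmeans_centers",
    "default_widths",
    "activations",
    "fit_weights",
    "train",
    "predict",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RBFConfig:
    """Training configuration.

    ``hidden_count=None`` applies the rule that the hidden layer matches the
    training-set size (each sample its own prototype).  ``spread`` is the
    scalar width hyperparameter; the string ``"auto"`` falls back to the
    self-organizing width c_max / sqrt(2h).  ``spread_mode`` decides whether
    a numeric spread *is* the width ("width", default) or multiplies the
    self-organizing width ("scale").
    """

    hidden_count: int | None = None
    spread: float | str = "auto"
    spread_mode: str = "width"
    kmeans_max_iter: int = 100
    kmeans_tol: float = 1e-8
    ridge: float = 1e-10
    bias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_count is not None and self.hidden_count < 1:
            raise ValueError("hidden_count must be >= 1")
        if isinstance(self.spread, str):
            if self.spread != "auto":
                raise ValueError("spread must be a positive number or 'auto'")
        elif self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.spread_mode not in ("width", "scale"):
            raise ValueError("spread_mode must be 'width' or 'scale'")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


@dataclass(frozen=True)
class RBFModel:
    """Trained network: everything needed to map (pi, par, T) to Pn."""

    centers: np.ndarray  # (h, d) in normalized input space
    widths: np.ndarray  # (h,)
    weights: np.ndarray  # (h,) or (h+1,) with bias
    spread: float | str
    bias: bool
    norm: NormalizationParams
    feature_order: tuple[str, ...] = FEATURE_ORDER
    config: RBFConfig | None = None

    @property
    def hidden_count(self) -> int:
        return self.centers.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "model_type": "rbf",
                "centers": self.centers.tolist(),
                "widths": self.widths.tolist(),
                "weights": self.weights.tolist(),
                "spread": self.spread,
                "bias": self.bias,
                "normalization": self.norm.to_dict(),
                "feature_order": list(self.feature_order),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RBFModel":
        d = json.loads(text)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')}")
        if d.get("model_type") != "rbf":
            raise ValueError(f"not an RBF model: {d.get('model_type')}")
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            widths=np.asarray(d["widths"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            spread=d["spread"],
            bias=bool(d["bias"]),
            norm=NormalizationParams.from_dict(d["normalization"]),
            feature_order=tuple(d["feature_order"]),
        )


def kmeans_centers(
    X: np.ndarray,
    h: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Lloyd's k-means on the rows of X.

    Initialization samples ``h`` distinct rows; assignment is by minimum
    Euclidean distance with ties to the lowest center index; centers update
    to cluster means until no center moves more than ``tol``.  A cluster
    left empty is re-seeded from the sample farthest from its center.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        raise ValueError("empty input")
    distinct = np.unique(X, axis=0)
    if h > distinct.shape[0]:
        raise ValueError(f"h={h} exceeds {distinct.shape[0]} distinct rows")
    rng = np.random.default_rng(seed)
    centers = distinct[rng.choice(distinct.shape[0], size=h, replace=False)].copy()
    for _ in range(max_iter):
        d = cdist(X, centers)
        assign = np.argmin(d, axis=1)  # argmin ties break to lowest index
        new_centers = centers.copy()
        for j in range(h):
            members = X[assign == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:
                farthest = np.argmax(d[np.arange(len(X)), assign])
                new_centers[j] = X[farthest]
                logger.debug("re-seeded empty cluster %d from farthest sample", j)
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        if shift <= tol:
            break
    return centers


def _c_max(centers: np.ndarray) -> float:
    return float(cdist(centers, centers).max())


def default_widths(centers: np.ndarray) -> np.ndarray:
    """Self-organizing widths sigma_i = c_max / sqrt(2h) (all equal)."""
    centers = np.asarray(centers, dtype=float)
    h = centers.shape[0]
    if h < 2:
        raise ValueError(
            "c_max is undefined for a single center; supply an explicit spread"
        )
    return np.full(h, _c_max(centers) / np.sqrt(2.0 * h))


def activations(X: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Gaussian hidden-layer activations Phi[p, i] = exp(-||x_p - c_i||^2 / (2 sigma_i^2))."""
    X = np.asarray(X, dtype=float)
    centers = np.asarray(centers, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("widths must be positive")
    if X.shape[1] != centers.shape[1]:
        raise ValueError("dimension mismatch between inputs and centers")
    d2 = cdist(X, centers, "sqeuclidean")
    return np.exp(-d2 / (2.0 * widths**2))


def fit_weights(phi: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Least-squares output weights, optionally ridge-regularized.

    ridge = 0 uses an SVD-based minimum-norm solve (rank deficiency is
    tolerated and logged); ridge > 0 solves the regularized normal equations
    by Cholesky with an SVD fallback.
    """
    phi = np.asarray(phi, dtype=float)
    y = np.asarray(y, dtype=float)
    if phi.shape[0] != y.shape[0]:
        raise ValueError("row mismatch between activations and targets")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if ridge == 0:
        w, _, rank, _ = np.linalg.lstsq(phi, y, rcond=None)
        if rank < phi.shape[1]:
            logger.warning("rank-deficient activation matrix (rank %d < %d); "
                           "minimum-norm solution used", rank, phi.shape[1])
        return w
    a = phi.T @ phi
    a[np.diag_indices_from(a)] += ridge
    try:
        from scipy.linalg import cho_factor, cho_solve

        return cho_solve(cho_factor(a, lower=True), phi.T @ y)
    except np.linalg.LinAlgError:  # pragma: no cover - extreme conditioning
        w, *_ = np.linalg.lstsq(
            np.vstack([phi, np.sqrt(ridge) * np.eye(phi.shape[1])]),
            np.concatenate([y, np.zeros(phi.shape[1])]),
            rcond=None,
        )
        return w


def _resolve_widths(centers: np.ndarray, config: RBFConfig) -> np.ndarray:
    if config.spread == "auto":
        return default_widths(centers)
    if config.spread_mode == "width":
        return np.full(centers.shape[0], float(config.spread))
    return float(config.spread) * default_widths(centers)


def train(
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    config: RBFConfig = RBFConfig(),
    norm: NormalizationParams | None = None,
) -> RBFModel:
    """Fit the network on normalized inputs/targets.

    When the hidden count equals the sample count the clustering step is a
    fixed point and is skipped: every sample is its own prototype.
    ``norm`` is stored on the model so that :func:`predict` can accept and
    emit original units; pass None for an already-normalized workflow.
    """
    X = np.asarray(train_inputs, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    n = X.shape[0]
    h = config.hidden_count if config.hidden_count is not None else n
    if h == n:
        centers = X.copy()
    else:
        centers = kmeans_centers(
            X, h, seed=config.seed, max_iter=config.kmeans_max_iter, tol=config.kmeans_tol
        )
    widths = _resolve_widths(centers, config)
    phi = activations(X, centers, widths)
    if config.bias:
        phi = np.column_stack([phi, np.ones(n)])
    weights = fit_weights(phi, y, config.ridge)
    return RBFModel(
        centers=centers,
        widths=widths,
        weights=weights,
        spread=config.spread,
        bias=config.bias,
        norm=norm if norm is not None else _identity_norm(X, y),
        config=config,
    )


def _identity_norm(X: np.ndarray, y: np.ndarray) -> NormalizationParams:
    """Pass-through scaling ([0,1] -> [0,1]) for pre-normalized workflows."""
    d = np.atleast_2d(X).shape[1]
    names = FEATURE_ORDER if d == len(FEATURE_ORDER) else tuple(f"x{j}" for j in range(d))
    mins = {name: 0.0 for name in names}
    maxs = {name: 1.0 for name in names}
    mins["pn"], maxs["pn"] = 0.0, 1.0
    return NormalizationParams(mins, maxs, names)


def predict(model: RBFModel, inputs: np.ndarray) -> np.ndarray:
    """Predict Pn (umol m-2 s-1) for inputs in original units.

    Columns follow the model's feature order (blue ratio, PPFD, temperature).
    Inputs far from every prototype decay to the denormalized zero of the
    target scale (there is no bias term by default).
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    Xn = model.norm.normalize_inputs(X)
    phi = activations(Xn, model.centers, model.widths)
    if model.bias:
        phi = np.column_stack([phi, np.ones(phi.shape[0])])
    yn = phi @ model.weights
    return np.asarray(model.norm.denormalize(yn, "pn"), dtype=float)
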