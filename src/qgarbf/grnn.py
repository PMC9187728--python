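"""Generalized regression neural network baseline.

A GRNN is a Nadaraya-Watson kernel regressor: the prediction is the
kernel-weighted average of the stored training targets, with an isotropic
Gaussian kernel on the normalized inputs and a single smoothing parameter
sigma (the spread).  Exponents are shifted by their maximum before
exponentiation so that predictions stay finite at any spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .preprocess import FEATURE_ORDER, NormalizationParams
from .rbf import MODEL_FORMAT_VERSION, _identity_norm

__all__ = ["GRNNModel", "grnn_train", "grnn_predict"]


@dataclass(frozen=True)
class GRNNModel:
    """Stored training set plus the smoothing parameter."""

    X: np.ndarray  # (n, d) normalized inputs
    y: np.ndarray  # (n,) normalized targets
    spread: float
    norm: NormalizationParams
    feature_order: tuple[str, ...] = FEATURE_ORDER

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if len(self.y) < 1:
            raise ValueError("need at least one stored sample")

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "model_type": "grnn",
                "X": self.X.tolist(),
                "y": self.y.tolist(),
                "spread": self.spread,
                "normalization": self.norm.to_dict(),
                "feature_order": list(self.feature_order),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GRNNModel":
        d = json.loads(text)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')}")
        if d.get("model_type") != "grnn":
            raise ValueError(f"not a GRNN model: {d.get('model_type')}")
        return cls(
            X=np.asarray(d["X"], dtype=float),
            y=np.asarray(d["y"], dtype=float),
            spread=float(d["spread"]),
            norm=NormalizationParams.from_dict(d["normalization"]),
            feature_order=tuple(d["feature_order"]),
        )


def grnn_train(
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    spread: float = 1.0,
    norm: NormalizationParams | None = None,
) -> GRNNModel:
    """Store the (normalized) training set; GRNN training is memorization."""
    X = np.asarray(train_inputs, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    return GRNNModel(X, y, float(spread), norm if norm is not None else _identity_norm(X, y))


def kernel_weights(model: GRNNModel, Xn: np.ndarray) -> np.ndarray:
    """Normalized Gaussian kernel weights, one probability vector per row."""
    log_k = -cdist(Xn, model.X, "sqeuclidean") / (2.0 * model.spread**2)
    log_k -= log_k.max(axis=1, keepdims=True)  # guard underflow of every kernel
    k = np.exp(log_k)
    return k / k.sum(axis=1, keepdims=True)


def grnn_predict(model: GRNNModel, inputs: np.ndarray) -> np.ndarray:
    """Predict Pn (umol m-2 s-1) for inputs in original units.

    y_hat(x) = sum_i y_i K_i / sum_i K_i with K_i = exp(-||x - x_i||^2 / (2 sigma^2)):
    a convex combination of stored targets, hence always within their range.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    Xn = model.norm.normalize_inputs(X)
    yn = kernel_weights(model, Xn) @ model.y
    return np.asarray(model.norm.denormalize(yn, "pn"), dtype=float)
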