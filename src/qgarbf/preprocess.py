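"""Data preparation: Dixon outlier removal, averaging, scaling, splitting.

Replicate triples are screened with the Dixon Q test (r10 variant); any
condition group containing a flagged replicate is dropped whole, surviving
groups are averaged, features and target are min-max scaled to [0, 1] with
parameters fitted on the training portion only, and the condition-level
dataset is partitioned 80/20 by a seeded shuffle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MeasurementRecord

__all__ = [
    "ConditionGroup",
    "CleanResult",
    "NormalizationParams",
    "SplitDataset",
    "dixon_flag",
    "clean",
    "split",
    "DIXON_R10_CRITICAL_005",
]

logger = logging.getLogger(__name__)

#: Critical values of the Dixon r10 (Q) statistic at alpha = 0.05, n = 3..10.
DIXON_R10_CRITICAL_005 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
    8: 0.526, 9: 0.493, 10: 0.466,
}

#: Input feature order used throughout: blue-light ratio, PPFD, temperature.
FEATURE_ORDER = ("blue_ratio", "par", "temperature")


@dataclass(frozen=True)
class ConditionGroup:
    """All replicates of one experimental condition."""

    temperature: float
    par: float
    blue_ratio: float
    replicate_values: tuple[float, ...]

    @property
    def mean_pn(self) -> float:
        return float(np.mean(self.replicate_values))


@dataclass(frozen=True)
class CleanResult:
    """Outcome of gross-error screening."""

    groups: tuple[ConditionGroup, ...]  # surviving groups, replicates intact
    removed: tuple[tuple[float, float, float], ...]  # deleted condition triples

    @property
    def removed_count(self) -> int:
        return len(self.removed)


def dixon_flag(values, alpha_level: float = 0.05) -> int | None:
    """Index of the value flagged by the two-sided Dixon r10 test, or None.

    The statistic is Q = gap / range for whichever extreme (max or min) is
    farther from its nearest neighbour; the extreme is flagged when Q exceeds
    the critical value for the sample size.  Zero range never flags.
    """
    if alpha_level != 0.05:
        raise ValueError("only the alpha = 0.05 critical table is provided")
    values = np.asarray(values, dtype=float)
    n = values.size
    if n not in DIXON_R10_CRITICAL_005:
        raise ValueError(f"Dixon r10 requires 3 <= n <= 10, got n={n}")
    order = np.argsort(values, kind="stable")
    sorted_v = values[order]
    rng = sorted_v[-1] - sorted_v[0]
    if rng == 0:
        return None
    q_low = (sorted_v[1] - sorted_v[0]) / rng
    q_high = (sorted_v[-1] - sorted_v[-2]) / rng
    q, pos = (q_high, order[-1]) if q_high >= q_low else (q_low, order[0])
    if q > DIXON_R10_CRITICAL_005[n]:
        return int(pos)
    return None


def group_records(records: list[MeasurementRecord]) -> list[ConditionGroup]:
    """Collect replicates by condition triple, preserving first-seen order."""
    acc: dict[tuple[float, float, float], list[float]] = {}
    for r in records:
        acc.setdefault((r.temperature, r.par, r.blue_ratio), []).append(r.pn)
    return [
        ConditionGroup(t, par, b, tuple(vals)) for (t, par, b), vals in acc.items()
    ]


def clean(records: list[MeasurementRecord], alpha_level: float = 0.05) -> CleanResult:
    """Screen every condition group with the Dixon test; drop flagged groups.

    Groups with fewer than three replicates cannot be tested and pass through
    with a warning.  Surviving groups keep their replicate values unaltered;
    downstream code uses the replicate mean as the group value.
    """
    groups = group_records(records)
    kept: list[ConditionGroup] = []
    removed: list[tuple[float, float, float]] = []
    for g in groups:
        n = len(g.replicate_values)
        if n < 3:
            logger.warning(
                "condition (%.3g, %.3g, %.3g) has %d replicate(s); Dixon test skipped",
                g.temperature, g.par, g.blue_ratio, n,
            )
            kept.append(g)
            continue
        if dixon_flag(g.replicate_values, alpha_level) is not None:
            removed.append((g.temperature, g.par, g.blue_ratio))
        else:
            kept.append(g)
    logger.info("Dixon screening removed %d of %d groups", len(removed), len(groups))
    return CleanResult(tuple(kept), tuple(removed))


class NormalizationParams:
    """Per-feature min-max maps z' = (z - z_min) / (z_max - z_min).

    Fitted on training data; inputs outside the fitted range map outside
    [0, 1] without clipping.
    """

    def __init__(
        self,
        mins: dict[str, float],
        maxs: dict[str, float],
        input_features: tuple[str, ...] | None = None,
    ):
        for name in mins:
            if maxs[name] <= mins[name]:
                raise ValueError(f"degenerate feature {name!r}: z_max <= z_min")
        self.mins = dict(mins)
        self.maxs = dict(maxs)
        if input_features is None:
            input_features = tuple(n for n in mins if n != "pn")
        self.input_features = tuple(input_features)

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray) -> "NormalizationParams":
        mins = {name: float(X[:, j].min()) for j, name in enumerate(FEATURE_ORDER)}
        maxs = {name: float(X[:, j].max()) for j, name in enumerate(FEATURE_ORDER)}
        mins["pn"] = float(np.min(y))
        maxs["pn"] = float(np.max(y))
        return cls(mins, maxs, FEATURE_ORDER)

    def normalize(self, value, feature: str):
        value = np.asarray(value, dtype=float)
        lo, hi = self.mins[feature], self.maxs[feature]
        out = (value - lo) / (hi - lo)
        if out.ndim and (np.any(out < 0) or np.any(out > 1)):
            logger.debug("feature %r has values outside the fitted range", feature)
        return out if out.ndim else float(out)

    def denormalize(self, value, feature: str):
        value = np.asarray(value, dtype=float)
        lo, hi = self.mins[feature], self.maxs[feature]
        out = value * (hi - lo) + lo
        return out if out.ndim else float(out)

    def normalize_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.input_features):
            raise ValueError(
                f"expected {len(self.input_features)} input columns, got {X.shape[1]}"
            )
        return np.column_stack(
            [self.normalize(X[:, j], name) for j, name in enumerate(self.input_features)]
        )

    def to_dict(self) -> dict:
        return {
            "mins": self.mins,
            "maxs": self.maxs,
            "feature_order": list(self.input_features),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(d["mins"], d["maxs"], tuple(d.get("feature_order") or ()) or None)


def _groups_to_arrays(groups) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[g.blue_ratio, g.par, g.temperature] for g in groups], dtype=float)
    y = np.array([g.mean_pn for g in groups], dtype=float)
    return X, y


@dataclass(frozen=True)
class SplitDataset:
    """Condition-level train/verification partition with fitted scaling.

    ``X_*`` columns follow :data:`FEATURE_ORDER` (blue ratio, PPFD,
    temperature) in original units; ``y_*`` is mean Pn in umol m-2 s-1.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_verify: np.ndarray
    y_verify: np.ndarray
    norm: NormalizationParams

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    @property
    def n_verify(self) -> int:
        return len(self.y_verify)


def split(groups, train_fraction: float = 0.8, seed: int = 0) -> SplitDataset:
    """Seeded uniform partition into train and verification sets.

    The training size is round-half-away-from-zero of ``train_fraction * n``
    (0.8 * 675 = 540 exactly).  Normalization parameters are fitted on the
    training portion only.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    groups = list(groups)
    n = len(groups)
    if n < 2:
        raise ValueError("need at least 2 groups to split")
    n_train = int(math.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx, verify_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    X_tr, y_tr = _groups_to_arrays([groups[i] for i in train_idx])
    X_ve, y_ve = _groups_to_arrays([groups[i] for i in verify_idx])
    norm = NormalizationParams.fit(X_tr, y_tr)
    logger.info("split %d groups into %d train / %d verification", n, len(y_tr), len(y_ve))
    return SplitDataset(X_tr, y_tr, X_ve, y_ve, norm)
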