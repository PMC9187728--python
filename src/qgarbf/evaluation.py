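"""Model evaluation: error metrics, spread sweeps, multi-model comparison.

Errors are reported in the original Pn units (umol m-2 s-1).  The agreement
line is the ordinary least-squares fit of predicted on measured; its slope,
intercept and coefficient of determination summarize calibration the way a
predicted-vs-measured scatter plot would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import grnn as grnn_mod
from . import rbf as rbf_mod
from .optimizers import GAConfig, QGAConfig, optimize_spread
from .preprocess import SplitDataset

__all__ = [
    "EvaluationReport",
    "ComparisonTable",
    "metrics",
    "spread_sweep",
    "compare_models",
    "MODEL_COMBOS",
    "DEFAULT_SWEEP_SPREADS",
]

logger = logging.getLogger(__name__)

#: The six family x optimizer combinations of the comparison harness.
MODEL_COMBOS = (
    ("RBF", "rbf", "none"),
    ("GA-RBF", "rbf", "ga"),
    ("QGA-RBF", "rbf", "qga"),
    ("GRNN", "grnn", "none"),
    ("GA-GRNN", "grnn", "ga"),
    ("QGA-GRNN", "grnn", "qga"),
)

#: Spread grid of the sensitivity sweep: 0.1 to 15.1 in steps of 1.0.
DEFAULT_SWEEP_SPREADS = tuple(round(0.1 + k, 1) for k in range(16))


@dataclass(frozen=True)
class EvaluationReport:
    """Error and calibration summary of one model on one evaluation set."""

    mse: float
    max_abs_error: float
    mean_abs_error: float
    r_squared: float
    slope: float
    intercept: float
    pearson_r2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "max_abs_error": self.max_abs_error,
            "mean_abs_error": self.mean_abs_error,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r2": self.pearson_r2,
            "n": self.n,
        }


def metrics(measured, predicted) -> EvaluationReport:
    """Compute MSE, MaxAE, MAE and the predicted-on-measured OLS line.

    ``r_squared`` is 1 - SS_res/SS_tot of that fit.  A constant measured
    vector leaves the line undefined; slope, intercept and both R^2 values
    are then NaN.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape:
        raise ValueError("length mismatch")
    if measured.size < 2:
        raise ValueError("need at least 2 points")
    err = predicted - measured
    mse = float(np.mean(err**2))
    max_ae = float(np.max(np.abs(err)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(measured) == 0:
        logger.warning("constant measured vector: agreement line undefined")
        slope = intercept = r2 = pr2 = float("nan")
    else:
        fit = stats.linregress(measured, predicted)
        slope, intercept = float(fit.slope), float(fit.intercept)
        resid = predicted - (slope * measured + intercept)
        ss_tot = float(np.sum((predicted - predicted.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
        pr2 = float(fit.rvalue**2)
    return EvaluationReport(mse, max_ae, mae, r2, slope, intercept, pr2, int(measured.size))


def _train_predict(dataset: SplitDataset, model_family: str, spread: float, model_config):
    Xtr = dataset.norm.normalize_inputs(dataset.X_train)
    ytr = np.asarray(dataset.norm.normalize(dataset.y_train, "pn"))
    if model_family == "rbf":
        base = model_config if model_config is not None else rbf_mod.RBFConfig()
        model = rbf_mod.train(Xtr, ytr, replace(base, spread=float(spread)), norm=dataset.norm)
        return rbf_mod.predict(model, dataset.X_verify)
    model = grnn_mod.grnn_train(Xtr, ytr, spread, norm=dataset.norm)
    return grnn_mod.grnn_predict(model, dataset.X_verify)


def spread_sweep(
    dataset: SplitDataset,
    spreads=DEFAULT_SWEEP_SPREADS,
    model_family: str = "rbf",
    model_config=None,
) -> pd.DataFrame:
    """Train one model per spread on a fixed split; tabulate its errors.

    Rows follow the input grid order.  Errors are on the verification set in
    original units.
    """
    spreads = list(spreads)
    if not spreads:
        raise ValueError("empty spread list")
    rows = []
    for s in spreads:
        pred = _train_predict(dataset, model_family, s, model_config)
        rep = metrics(dataset.y_verify, pred)
        rows.append(
            {
                "spread": s,
                "mse": rep.mse,
                "max_abs_error": rep.max_abs_error,
                "mean_abs_error": rep.mean_abs_error,
                "r_squared": rep.r_squared,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ComparisonTable:
    """One report per model combination, all on the identical verification set."""

    reports: dict[str, EvaluationReport | None] = field(default_factory=dict)
    spreads: dict[str, float] = field(default_factory=dict)
    predictions: dict[str, np.ndarray] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    measured: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.reports.items():
            row = {"model": name, "spread": self.spreads.get(name, float("nan"))}
            if rep is None:
                row.update({"status": "failed", "error": self.failures.get(name, "")})
            else:
                row.update({"status": "ok", **rep.to_dict()})
            rows.append(row)
        return pd.DataFrame(rows)

    def scatter_frame(self, name: str) -> pd.DataFrame:
        return pd.DataFrame({"measured": self.measured, "predicted": self.predictions[name]})


def compare_models(
    dataset: SplitDataset,
    model_config=None,
    qga_config: QGAConfig | None = None,
    ga_config: GAConfig | None = None,
    default_spread: float = 1.0,
    seed: int = 0,
) -> ComparisonTable:
    """Run the six-model comparison on one shared train/verification split.

    Each optimizer run gets a seed derived from ``seed``; a failure in one
    combination marks that row failed without aborting the others.
    """
    table = ComparisonTable(measured=dataset.y_verify.copy())
    qga_base = qga_config if qga_config is not None else QGAConfig()
    ga_base = ga_config if ga_config is not None else GAConfig()
    for i, (name, family, opt) in enumerate(MODEL_COMBOS):
        try:
            if opt == "qga":
                opt_cfg = replace(qga_base, seed=(qga_base.seed + 1000 * i + seed) % 2**31)
            elif opt == "ga":
                opt_cfg = replace(ga_base, seed=(ga_base.seed + 1000 * i + seed) % 2**31)
            else:
                opt_cfg = None
            result = optimize_spread(
                dataset,
                model_family=family,
                optimizer=opt,
                model_config=model_config if family == "rbf" else None,
                opt_config=opt_cfg,
                default_spread=default_spread,
            )
            if family == "rbf":
                pred = rbf_mod.predict(result.model, dataset.X_verify)
            else:
                pred = grnn_mod.grnn_predict(result.model, dataset.X_verify)
            table.reports[name] = metrics(dataset.y_verify, pred)
            table.spreads[name] = result.spread
            table.predictions[name] = np.asarray(pred)
        except Exception as exc:  # one bad row must not sink the table
            logger.exception("model %s failed", name)
            table.reports[name] = None
            table.failures[name] = str(exc)
    return table
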