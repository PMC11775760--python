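"""Model evaluation and pipeline glue: LOOCV accuracy metrics, the
15-model x 2-data-source comparison, wall-to-wall LAI map prediction and
permutation-importance contribution reporting."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optimizers import (
    LOOCVObjective,
    MODEL_KINDS,
    OPTIMIZER_NAMES,
    default_space,
    optimize,
    predict,
)

log = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """R2 / RMSE / MAE / P1 for one prediction vector."""

    r2: float
    rmse: float
    mae: float
    p1_percent: float
    n: int
    y_mean: float

    def as_dict(self) -> dict:
        return {
            "R2": self.r2,
            "RMSE": self.rmse,
            "MAE": self.mae,
            "P1_percent": self.p1_percent,
            "n": self.n,
            "y_mean": self.y_mean,
        }


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricsReport:
    """R2 = 1 - SSE/SST, RMSE = sqrt(SSE/n), MAE = mean |e|,
    P1 = (1 - RMSE / mean(y)) * 100.

    Degenerate denominators (constant y, or mean(y) = 0 for P1) yield NaN
    for the affected metric rather than an error.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length vectors")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    err = y - yhat
    sse = float(np.sum(err**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / n))
    mae = float(np.mean(np.abs(err)))
    ybar = float(y.mean())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else float("nan"))
    if sst == 0 and sse > 0:
        log.warning("compute_metrics: constant y, R2 undefined")
    p1 = (1.0 - rmse / ybar) * 100.0 if ybar != 0 else float("nan")
    if ybar == 0:
        log.warning("compute_metrics: mean(y) = 0, P1 undefined")
    return MetricsReport(r2=r2, rmse=rmse, mae=mae, p1_percent=p1, n=n, y_mean=ybar)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

DATA_SOURCES = ("atlas_only", "multisource")


def run_comparison(
    features: pd.DataFrame,
    atlas_columns: list[str],
    multisource_columns: list[str],
    budget: int = 60,
    seed: int = 0,
    target: str = "lai",
    spaces: dict[str, object] | None = None,
    optimizers: tuple[str, ...] = OPTIMIZER_NAMES,
) -> pd.DataFrame:
    """Evaluate {RFR, GBRT, SVR} x {none, BO, PSO, GA, SA} on each data
    source by LOOCV; returns one row per combination (30 with both sources).

    ``budget`` is the shared objective-evaluation budget; ``budget=0`` skips
    tuning so optimized rows coincide with the untuned defaults. A failing
    combination is flagged rather than aborting the sweep.
    """
    for cols, name in ((atlas_columns, "atlas_only"), (multisource_columns, "multisource")):
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise KeyError(f"{name} columns missing from features: {missing}")
    y = features[target].to_numpy(dtype=float)
    rows = []
    for source, cols in (("atlas_only", atlas_columns), ("multisource", multisource_columns)):
        X = features[cols].to_numpy(dtype=float)
        for kind in MODEL_KINDS:
            objective = LOOCVObjective(kind, X, y, seed=seed)
            untuned_yhat: np.ndarray | None = None  # computed once, reused
            for opt in ("none",) + tuple(optimizers):
                row = {
                    "data_source": source,
                    "model": kind,
                    "optimizer": opt,
                    "seed": seed,
                    "budget": 0 if opt == "none" else budget,
                    "failed": False,
                }
                try:
                    if opt == "none" or budget == 0:
                        params: dict | None = None
                        if untuned_yhat is None:
                            from .optimizers import loocv_predictions

                            untuned_yhat = loocv_predictions(kind, None, X, y, seed=seed)
                        yhat = untuned_yhat
                    else:
                        space = (spaces or {}).get(kind) or default_space(kind)
                        best, trace = optimize(opt, space, objective, budget=budget, seed=seed)
                        params = best.params
                        yhat = objective.predictions_for(params)
                        row["n_evaluations"] = trace.n_evaluations
                    m = compute_metrics(y, yhat)
                    row.update(m.as_dict())
                    row["params"] = params
                except Exception as e:
                    log.warning("comparison row %s/%s/%s failed: %s", source, kind, opt, e)
                    row["failed"] = True
                rows.append(row)
    return pd.DataFrame(rows)


def comparison_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Ranked summary (radar-style export): combinations sorted by R2."""
    ok = table[~table["failed"]].copy()
    ok["label"] = np.where(
        ok["optimizer"] == "none", ok["model"], ok["optimizer"] + "-" + ok["model"]
    )
    cols = ["data_source", "label", "R2", "RMSE", "MAE", "P1_percent"]
    return ok[cols].sort_values(["data_source", "R2"], ascending=[True, False]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


@dataclass
class LAIMap:
    values: np.ndarray
    mask: np.ndarray  # True where the pixel is masked out
    model_id: str
    vmin: float
    vmax: float
    vmean: float


def predict_map(model, stack, columns: list[str], model_id: str = "model") -> LAIMap:
    """Per-pixel prediction from raster layers taken in the exact training
    column order; pixels with any NaN layer value are masked."""
    missing = [c for c in columns if c not in stack]
    if missing:
        raise KeyError(f"missing layer(s) in stack: {missing}")
    layers = [np.asarray(stack[c], dtype=float) for c in columns]
    X = np.stack([l.ravel() for l in layers], axis=1)
    mask = ~np.isfinite(X).all(axis=1)
    values = np.full(X.shape[0], np.nan)
    if (~mask).any():
        values[~mask] = predict(model, X[~mask])
    shape = layers[0].shape
    values = values.reshape(shape)
    mask = mask.reshape(shape)
    valid = values[~mask]
    return LAIMap(
        values=values,
        mask=mask,
        model_id=model_id,
        vmin=float(np.min(valid)) if valid.size else float("nan"),
        vmax=float(np.max(valid)) if valid.size else float("nan"),
        vmean=float(np.mean(valid)) if valid.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# contribution rates
# ---------------------------------------------------------------------------

GROUPS = ("ATLAS", "SAR", "optical")


def variable_group(name: str) -> str:
    from .screening import ATLAS_VARIABLES

    if name in ATLAS_VARIABLES:
        return "ATLAS"
    if name.startswith(("VV", "VH")):
        return "SAR"
    return "optical"


def contribution_report(
    model,
    features: pd.DataFrame,
    columns: list[str],
    target: str = "lai",
    n_shuffles: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-importance contribution rates, normalized to sum 100% and
    tagged with their sensor group."""
    from sklearn.inspection import permutation_importance

    X = features[columns].to_numpy(dtype=float)
    y = features[target].to_numpy(dtype=float)
    res = permutation_importance(
        model, X, y, n_repeats=n_shuffles, random_state=seed,
        scoring="neg_mean_squared_error",
    )
    imp = np.maximum(res.importances_mean, 0.0)
    total = imp.sum()
    pct = imp / total * 100.0 if total > 0 else np.full(len(imp), 100.0 / len(imp))
    out = pd.DataFrame(
        {
            "variable": columns,
            "contribution_percent": pct,
            "group": [variable_group(c) for c in columns],
        }
    )
    return out.sort_values("contribution_percent", ascending=False).reset_index(drop=True)


def group_contributions(report: pd.DataFrame) -> pd.Series:
    return report.groupby("group")["contribution_percent"].sum()
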