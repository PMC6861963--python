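"""Model evaluation: accuracy metrics, 10-fold cross-validation and the
variable-ablation harness.

Metric conventions (the dominant ones in the satellite-PM2.5 literature):

* R² = 1 − SS_res / SS_tot (coefficient of determination);
* RMSE = √(Σ(y−ŷ)²/n), μg/m³;
* MPE = mean absolute prediction error (1/n)Σ|y−ŷ|, μg/m³;
* RPE = 100 · RMSE / mean(y), percent;
* the fit line (slope, intercept) regresses predictions on observations.

Cross-validation reports both the pooled metrics (all held-out predictions
scored once) and the mean of the per-fold metrics; a model-fitting report
(train on all, score on all) accompanies them.  Ablation runs share fold
assignments so combo differences are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .dbn import DBNModel, TrainConfig, train_dbn
from .grid import expand_combo


@dataclass
class MetricReport:
    r2: float
    rmse: float
    mpe: float
    rpe: float
    n: int
    fit_line_slope: float = float("nan")
    fit_line_intercept: float = float("nan")
    valid: bool = True

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mpe": self.mpe,
                "rpe": self.rpe, "n": self.n,
                "fit_line_slope": self.fit_line_slope,
                "fit_line_intercept": self.fit_line_intercept}


def compute_metrics(observed, predicted) -> MetricReport:
    """All four accuracy metrics plus the prediction-on-observation fit line."""
    y = np.asarray(observed, float).ravel()
    yhat = np.asarray(predicted, float).ravel()
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values in metric inputs")
    resid = y - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rmse = float(np.sqrt(ss_res / len(y)))
    mpe = float(np.abs(resid).mean())
    ybar = float(y.mean())
    rpe = 100.0 * rmse / ybar if ybar != 0 else float("nan")
    if ss_tot == 0:
        return MetricReport(float("nan"), rmse, mpe, rpe, len(y), valid=False)
    slope, intercept = np.polyfit(y, yhat, 1)
    return MetricReport(1.0 - ss_res / ss_tot, rmse, mpe, rpe, len(y),
                        float(slope), float(intercept))


def kfold_split(n: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded random partition into k disjoint folds with sizes differing by
    at most one; their union is range(n)."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# model wrappers

def _fit_predict(x_tr, y_tr, x_te, model: str, train_cfg: TrainConfig,
                 fold_seed: int, feature_names) -> np.ndarray:
    if model == "dbn":
        cfg = replace(train_cfg, seed=fold_seed)
        m = train_dbn(x_tr, y_tr, cfg, feature_names=list(feature_names))
        return m.predict(x_te)
    if model == "linear":  # main-effects least squares baseline
        lm = LinearRegression().fit(x_tr, y_tr)
        return lm.predict(x_te)
    if model == "intercept":
        return np.full(len(x_te), float(np.mean(y_tr)))
    raise ValueError(f"unknown model {model!r}")


@dataclass
class CVResult:
    pooled: MetricReport
    fold_mean: dict
    per_fold: list[MetricReport]
    fitting: MetricReport
    predictions: pd.DataFrame
    combo: list[str] = field(default_factory=list)
    model: str = "dbn"


def station_blocked_folds(station_ids, k: int = 10,
                          seed: int = 0) -> list[np.ndarray]:
    """Folds that never split a station between training and validation.

    Sample-level random splits share every station across folds, so spatial
    information leaks from training into validation; blocking by station
    removes that optimism at the cost of coarser folds.
    """
    station_ids = np.asarray(station_ids)
    uniq = pd.unique(station_ids)
    if len(uniq) < k:
        raise ValueError(f"cannot block {len(uniq)} stations into {k} folds")
    perm = np.random.default_rng(seed).permutation(len(uniq))
    groups = np.array_split(uniq[perm], k)
    return [np.sort(np.flatnonzero(np.isin(station_ids, g))) for g in groups]


def cross_validate(samples: pd.DataFrame, combo, train_cfg: TrainConfig | None = None,
                   k: int = 10, seed: int = 0, model: str = "dbn",
                   folds: list[np.ndarray] | None = None,
                   fit_full: bool = True, block_by_station: bool = False) -> CVResult:
    """k-fold cross-validation of one variable combination.

    ``samples`` must carry a ``label`` column and the combo's feature columns
    (rows with any missing requested feature are dropped — the grid-matching
    contract).  Pass precomputed ``folds`` to pair several runs on identical
    splits.  ``block_by_station`` switches from sample-level folds (the
    default, matching the usual practice in this literature) to
    station-blocked folds.  Returns pooled and fold-averaged CV metrics plus
    a model-fitting report (trained and evaluated on the full set).
    """
    train_cfg = train_cfg or TrainConfig()
    features = expand_combo(combo)
    if not features:
        raise ValueError("empty variable combination")
    data = samples.dropna(subset=list(features) + ["label"]).reset_index(drop=True)
    x = data[features].to_numpy(float)
    y = data["label"].to_numpy(float)
    if folds is None:
        if block_by_station:
            folds = station_blocked_folds(data["station_id"].to_numpy(), k,
                                          seed)
        else:
            folds = kfold_split(len(data), k, seed)
    yhat = np.full(len(data), np.nan)
    fold_id = np.full(len(data), -1)
    per_fold = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(data)), test_idx)
        fold_seed = (train_cfg.seed * 1009 + i) % (2**31)
        pred = _fit_predict(x[train_idx], y[train_idx], x[test_idx],
                            model, train_cfg, fold_seed, features)
        yhat[test_idx] = pred
        fold_id[test_idx] = i
        if len(test_idx) >= 2:  # single-sample folds (LOO) have no fold R²
            per_fold.append(compute_metrics(y[test_idx], pred))
    pooled = compute_metrics(y, yhat)
    fold_mean = {m: (float(np.mean([getattr(r, m) for r in per_fold]))
                     if per_fold else float("nan"))
                 for m in ("r2", "rmse", "mpe", "rpe")}
    if fit_full:
        pred_full = _fit_predict(x, y, x, model, train_cfg,
                                 train_cfg.seed % (2**31), features)
        fitting = compute_metrics(y, pred_full)
    else:
        fitting = pooled
    preds = data[["row", "col", "hour", "station_id"]].copy() if {
        "row", "col", "hour", "station_id"}.issubset(data.columns) else pd.DataFrame(
        index=data.index)
    preds["observed"] = y
    preds["predicted"] = yhat
    preds["fold"] = fold_id
    return CVResult(pooled, fold_mean, per_fold, fitting, preds,
                    combo=features, model=model)


def ablation_experiment(samples: pd.DataFrame, combos: dict[str, object],
                        train_cfg: TrainConfig | None = None, k: int = 10,
                        seed: int = 0, model: str = "dbn",
                        fit_full: bool = False) -> pd.DataFrame:
    """Paired cross-validation of several variable combinations.

    All combos share the same fold assignment (rows are aligned by dropping
    records missing any feature used by *any* combo first, so every run sees
    identical sample sets and splits).  Returns a table with one row per
    combo: pooled and fold-averaged CV metrics, plus fitting metrics when
    ``fit_full``.
    """
    if not combos:
        raise ValueError("no combos given")
    all_feats = sorted({f for c in combos.values() for f in expand_combo(c)})
    data = samples.dropna(subset=all_feats + ["label"]).reset_index(drop=True)
    folds = kfold_split(len(data), k, seed)
    rows = []
    for name, combo in combos.items():
        res = cross_validate(data, combo, train_cfg, k=k, seed=seed,
                             model=model, folds=folds, fit_full=fit_full)
        row = {"combo": name, "n": res.pooled.n,
               "cv_r2": res.pooled.r2, "cv_rmse": res.pooled.rmse,
               "cv_mpe": res.pooled.mpe, "cv_rpe": res.pooled.rpe,
               "cv_r2_foldmean": res.fold_mean["r2"]}
        if fit_full:
            row.update({"fit_r2": res.fitting.r2, "fit_rmse": res.fitting.rmse,
                        "fit_mpe": res.fitting.mpe, "fit_rpe": res.fitting.rpe})
        rows.append(row)
    return pd.DataFrame(rows)


def ablation_markdown(table: pd.DataFrame) -> str:
    """Render the ablation table in the usual fitting/CV column layout."""
    cols = [c for c in ("combo", "n", "fit_r2", "fit_rmse", "fit_mpe", "fit_rpe",
                        "cv_r2", "cv_rmse", "cv_mpe", "cv_rpe") if c in table]
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "---|" * len(cols)]
    for _, r in table.iterrows():
        cells = [f"{r[c]:.3f}" if isinstance(r[c], float) else str(r[c])
                 for c in cols]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
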