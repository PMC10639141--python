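"""Model fitting and validation for plot-level biomass regression.

Two learners are configured the way the study design fixes them: a random
forest (100 trees, at most 15 candidate features per split, clamped to the
available predictor count) and an RBF-kernel support vector regression with
regularization C = 1.  Both are evaluated with

* leave-one-out cross-validation (LOOCV): n fits, held-out predictions pooled
  into one vector before computing metrics (the pooled RMSE is the root of
  the mean of the n squared validation errors), and
* repeated random 70/30 splits (default 10 repeats): metrics computed per
  repeat on the training and test partitions, then averaged; the repeat with
  the highest test R² is flagged.

Accuracy metrics: R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², RMSE = sqrt(Σ(y−ŷ)²/m),
rRMSE = 100·RMSE/ȳ (percent of the observed mean), MAE = Σ|y−ŷ|/m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR as _SKSVR

from . import plsr

__all__ = [
    "ModelSpec",
    "EvaluationMetrics",
    "ValidationReport",
    "TARGETS",
    "compute_metrics",
    "fit_model",
    "loocv",
    "repeated_split",
    "run_study",
]

#: response columns of a biomass table, in reporting order
TARGETS = ("total", "stem", "bark", "branch", "leaf")


@dataclass(frozen=True)
class ModelSpec:
    """Learner configuration.

    ``algorithm``: "rf", "svr", or "mean" (the intercept-only baseline).
    ``max_features`` is clamped to the number of available predictors at fit
    time.  ``scale`` standardizes X (and, for SVR, the response, so the epsilon
    tube is on a comparable scale) — RF is scale-invariant and ignores it.
    """

    algorithm: str = "rf"
    n_trees: int = 100
    max_features: int = 15
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    scale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("rf", "svr", "mean"):
            raise ValueError(f"algorithm must be 'rf', 'svr' or 'mean', got {self.algorithm!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.svr_c <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class EvaluationMetrics:
    r2: float
    rmse: float
    rrmse: float
    mae: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "rmse": self.rmse, "rrmse": self.rrmse, "mae": self.mae, "n": self.n}


class _ScaledYModel:
    """Wraps a model fit on standardized y; predictions are back-transformed."""

    def __init__(self, inner, y_mean: float, y_sd: float):
        self.inner, self.y_mean, self.y_sd = inner, y_mean, y_sd

    def predict(self, X) -> np.ndarray:
        return self.inner.predict(X) * self.y_sd + self.y_mean


def compute_metrics(y_true, y_pred) -> EvaluationMetrics:
    """The four accuracy indicators from observed and predicted vectors."""
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.size == 0 or yt.size != yp.size:
        raise ValueError(f"need equal nonzero lengths, got {yt.size} and {yp.size}")
    resid = yt - yp
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    ybar = float(yt.mean())
    rrmse = 100.0 * rmse / ybar if ybar != 0 else np.nan
    return EvaluationMetrics(r2=r2, rmse=rmse, rrmse=rrmse, mae=mae, n=yt.size)


def fit_model(spec: ModelSpec, X, y):
    """Train the configured learner; returns an object with ``predict``."""
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.any(~np.isfinite(Xm)):
        if isinstance(X, pd.DataFrame):
            bad = [c for c, has in zip(X.columns, (~np.isfinite(Xm)).any(axis=0)) if has]
            raise ValueError(f"non-finite values in predictor columns: {bad}")
        raise ValueError("non-finite values in X")
    if spec.algorithm == "rf":
        model = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=min(spec.max_features, Xm.shape[1]),
            random_state=spec.seed,
        )
        model.fit(Xm, yv)
        return model
    if spec.algorithm == "svr":
        svr = _SKSVR(kernel="rbf", C=spec.svr_c, epsilon=spec.svr_epsilon)
        model = make_pipeline(StandardScaler(), svr) if spec.scale else svr
        if spec.scale:
            sd = float(yv.std()) or 1.0
            mean = float(yv.mean())
            model.fit(Xm, (yv - mean) / sd)
            return _ScaledYModel(model, mean, sd)
        model.fit(Xm, yv)
        return model
    model = DummyRegressor(strategy="mean")
    model.fit(Xm, yv)
    return model


def loocv(spec: ModelSpec, X, y) -> tuple[EvaluationMetrics, np.ndarray]:
    """Leave-one-out: m fits, pooled held-out predictions and their metrics."""
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    m = Xm.shape[0]
    if m < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    preds = np.empty(m)
    for i in range(m):
        mask = np.ones(m, dtype=bool)
        mask[i] = False
        try:
            model = fit_model(spec, Xm[mask], yv[mask])
        except ValueError as exc:
            raise ValueError(f"fold {i}: {exc}") from exc
        preds[i] = float(model.predict(Xm[i : i + 1])[0])
    return compute_metrics(yv, preds), preds


@dataclass(frozen=True)
class SplitResult:
    train: EvaluationMetrics
    test: EvaluationMetrics
    best_repeat: int
    per_repeat_test: tuple[EvaluationMetrics, ...]
    per_repeat_train: tuple[EvaluationMetrics, ...]


def repeated_split(
    spec: ModelSpec,
    X,
    y,
    train_fraction: float = 0.7,
    repeats: int = 10,
    seed: int = 0,
) -> SplitResult:
    """Repeated random train/test splits with averaged metrics.

    Each repeat draws an independent uniform split (train size =
    round(train_fraction·m)) from a per-repeat child seed of ``seed``; the
    averaged train and test metrics are reported along with the index of the
    repeat with the highest test R².
    """
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    m = Xm.shape[0]
    if m < 4:
        raise ValueError("repeated_split needs at least 4 samples")
    n_train = int(round(train_fraction * m))
    if n_train < 1 or n_train >= m:
        raise ValueError(f"train_fraction {train_fraction} leaves an empty partition for m={m}")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(2**31, size=repeats)
    train_metrics, test_metrics = [], []
    for r in range(repeats):
        rng = np.random.default_rng(child_seeds[r])
        perm = rng.permutation(m)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_model(replace(spec, seed=int(child_seeds[r])), Xm[tr], yv[tr])
        train_metrics.append(compute_metrics(yv[tr], model.predict(Xm[tr])))
        test_metrics.append(compute_metrics(yv[te], model.predict(Xm[te])))

    def _avg(ms: list[EvaluationMetrics]) -> EvaluationMetrics:
        return EvaluationMetrics(
            r2=float(np.mean([x.r2 for x in ms])),
            rmse=float(np.mean([x.rmse for x in ms])),
            rrmse=float(np.mean([x.rrmse for x in ms])),
            mae=float(np.mean([x.mae for x in ms])),
            n=ms[0].n,
        )

    best = int(np.argmax([x.r2 for x in test_metrics]))
    return SplitResult(
        train=_avg(train_metrics),
        test=_avg(test_metrics),
        best_repeat=best,
        per_repeat_test=tuple(test_metrics),
        per_repeat_train=tuple(train_metrics),
    )


@dataclass(frozen=True)
class ValidationReport:
    """Per-target, per-algorithm, per-protocol metrics plus wiring details."""

    rows: pd.DataFrame  # columns: target, algorithm, protocol, r2, rmse, rrmse, mae, n
    selected_features: dict[str, list[str]]
    loocv_predictions: pd.DataFrame  # index plot_id, one column per (target, algorithm)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows": self.rows.to_dict(orient="records"),
                "selected_features": self.selected_features,
            },
            indent=2,
        )


def run_study(
    features: pd.DataFrame,
    biomass: pd.DataFrame,
    specs: Sequence[ModelSpec] = (ModelSpec("rf"), ModelSpec("svr")),
    targets: Sequence[str] = TARGETS,
    vip_threshold: float = 1.0,
    n_components: int = 2,
    repeats: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Full selection + validation study over biomass targets.

    For every target a separate PLSR-VIP selection (VIP > threshold; falls
    back to the full registry if nothing clears it) feeds each learner, which
    is then evaluated by LOOCV and by repeated 70/30 splits.
    """
    if not features.index.equals(biomass.index):
        raise ValueError("feature and biomass tables are not aligned by plot_id")
    selected: dict[str, list[str]] = {}
    records = []
    pred_cols = {}
    for target in targets:
        y = biomass[target].to_numpy(dtype=float)
        fit = plsr.fit_plsr(features, y, n_components=n_components)
        ranking = plsr.vip(fit, threshold=vip_threshold)
        chosen = plsr.select_features(ranking)
        if not chosen:
            chosen = list(features.columns)
        selected[target] = chosen
        Xsel = features[chosen]
        for spec in specs:
            cv, preds = loocv(spec, Xsel, y)
            pred_cols[f"{target}_{spec.algorithm}"] = preds
            split = repeated_split(spec, Xsel, y, repeats=repeats, seed=seed)
            for protocol, mtr in (
                ("loocv", cv),
                ("split_train", split.train),
                ("split_test", split.test),
            ):
                records.append(
                    {"target": target, "algorithm": spec.algorithm, "protocol": protocol}
                    | mtr.as_dict()
                )
    rows = pd.DataFrame.from_records(records)
    preds_df = pd.DataFrame(pred_cols, index=features.index)
    return ValidationReport(rows=rows, selected_features=selected, loocv_predictions=preds_df)
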