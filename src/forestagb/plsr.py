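"""Partial least squares regression and VIP-based feature selection.

PLSR projects a standardized predictor matrix X and a centered response y onto
a small number of latent components chosen to maximize the covariance between
component scores and the response.  Predictors are then ranked by their
variable importance in projection (VIP),

    VIP_j = sqrt( k * sum_h SS_h * w_hj^2 / sum_h SS_h ),

with k the number of predictors, ``w_hj`` the unit-norm weight of predictor j
on component h, and ``SS_h = r^2(y, c_h)`` the squared correlation between the
response and the h-th component score — the component's explanatory power.
The mean of VIP² over predictors is 1 by construction, so predictors with
VIP > 1 carry above-average importance; the selection rule keeps exactly
those (strict inequality).

The fit is a plain NIPALS loop on centered/unit-variance data with X
deflation per component; it stores weights, scores and the quantities the VIP
formula needs, and reproduces its own training predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PLSRFit", "VIPRanking", "fit_plsr", "vip", "select_features", "choose_n_components"]


@dataclass(frozen=True)
class PLSRFit:
    """Fitted PLSR model on standardized X and centered y.

    ``weights`` is (n_components, k) with unit-norm rows; ``scores``
    (n_samples, n_components); ``y_correlations[h]`` is r(y, c_h) on the
    training response.
    """

    feature_names: tuple[str, ...]
    n_components: int
    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    y_correlations: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    dropped: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return len(self.feature_names)

    def coefficients(self) -> np.ndarray:
        """Regression coefficients on the standardized scale."""
        W, P, q = self.weights.T, self.loadings.T, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        Xs = (X - self.x_mean) / self.x_scale
        return Xs @ self.coefficients() + self.y_mean


@dataclass(frozen=True)
class VIPRanking:
    """Per-predictor VIP scores with the selection mask at ``threshold``."""

    feature_names: tuple[str, ...]
    vip: np.ndarray
    threshold: float = 1.0

    @property
    def selected(self) -> np.ndarray:
        return self.vip > self.threshold

    @property
    def order(self) -> list[str]:
        """Predictors sorted by descending VIP (ties keep registry order)."""
        idx = np.argsort(-self.vip, kind="stable")
        return [self.feature_names[i] for i in idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": self.feature_names, "vip": self.vip, "selected": self.selected}
        )


def _as_matrix(X, names=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.rename(columns=str)
        if names is not None:
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise KeyError(f"missing predictor columns: {missing}")
            X = X[list(names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def fit_plsr(X, y, n_components: int = 2) -> PLSRFit:
    """NIPALS PLSR on centered, unit-variance X and centered y.

    Zero-variance predictor columns are dropped with a warning; a
    zero-variance response or ``n_components`` above the achievable rank is an
    error.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    names = (
        tuple(map(str, X.columns))
        if isinstance(X, pd.DataFrame)
        else tuple(f"x{j}" for j in range(np.asarray(X).shape[1]))
    )
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, k = Xm.shape
    if yv.size != n:
        raise ValueError(f"X has {n} rows but y has {yv.size}")
    if np.ptp(yv) == 0:
        raise ValueError("response has zero variance")

    sd = Xm.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(nm for nm, k_ in zip(names, keep) if not k_)
    if dropped:
        warnings.warn(f"dropping zero-variance predictors: {list(dropped)}", stacklevel=2)
        Xm, sd, names = Xm[:, keep], sd[keep], tuple(nm for nm in names if nm not in dropped)
        k = Xm.shape[1]
    max_comp = min(k, n - 1)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds the achievable maximum {max_comp}"
        )

    x_mean, x_scale = Xm.mean(axis=0), sd
    Xs = (Xm - x_mean) / x_scale
    y_mean = float(yv.mean())
    yc0 = yv - y_mean
    yc = yc0.copy()

    W = np.zeros((n_components, k))
    P = np.zeros((n_components, k))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for h in range(n_components):
        w = Xs.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(
                f"component {h + 1}: residual covariance vanished; "
                f"use at most {h} components"
            )
        w /= norm
        t = Xs @ w
        tt = t @ t
        p = Xs.T @ t / tt
        q[h] = yc @ t / tt
        Xs = Xs - np.outer(t, p)
        yc = yc - q[h] * t
        W[h], P[h], T[:, h] = w, p, t

    # correlation of each component score with the (undeflated) response
    ycorr = np.array(
        [np.corrcoef(yc0, T[:, h])[0, 1] if T[:, h].std() > 0 else 0.0 for h in range(n_components)]
    )
    return PLSRFit(
        feature_names=names,
        n_components=n_components,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        y_correlations=ycorr,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        dropped=dropped,
    )


def vip(fit: PLSRFit, threshold: float = 1.0) -> VIPRanking:
    """VIP scores of a fitted model; the mean square of the scores is 1."""
    ss = fit.y_correlations**2
    total = ss.sum()
    if total <= 0:
        raise ValueError("response unexplained: every component has zero correlation with y")
    scores = np.sqrt(fit.k * (ss @ fit.weights**2) / total)
    return VIPRanking(feature_names=fit.feature_names, vip=scores, threshold=threshold)


def select_features(ranking: VIPRanking, threshold: float | None = None) -> list[str]:
    """Names with VIP strictly above the threshold, in registry order."""
    thr = ranking.threshold if threshold is None else threshold
    return [nm for nm, v in zip(ranking.feature_names, ranking.vip) if v > thr]


def choose_n_components(X, y, max_components: int = 10) -> int:
    """Smallest component count minimizing leave-one-out PRESS.

    Ties (within a 1e-12 relative margin) go to the smaller count, which keeps
    the model parsimonious when extra components add nothing.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    upper = min(max_components, min(Xm.shape[1], n - 2))
    upper = max(upper, 1)
    X_df = (
        X
        if isinstance(X, pd.DataFrame)
        else pd.DataFrame(Xm, columns=[f"x{j}" for j in range(Xm.shape[1])])
    )
    press = np.full(upper, np.inf)
    for c in range(1, upper + 1):
        sq = 0.0
        ok = True
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f = fit_plsr(X_df.iloc[mask], yv[mask], n_components=c)
                pred = float(f.predict(X_df.iloc[[i]])[0])
            except (ValueError, KeyError):
                ok = False
                break
            sq += (yv[i] - pred) ** 2
        if ok:
            press[c - 1] = sq
    best = float(np.min(press))
    if not np.isfinite(best):
        raise ValueError("no component count could be cross-validated")
    tol = 1e-12 * max(best, 1.0)
    return int(np.flatnonzero(press <= best + tol)[0]) + 1
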