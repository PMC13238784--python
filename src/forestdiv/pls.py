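"""Partial least squares regression with VIP scoring and backward shaving.

Single-response PLS (NIPALS-type deflation) on z-standardized X and y.
Variable importance in projection for predictor j,

    VIP_j = sqrt( p * sum_a SSY_a * (w_ja / ||w_a||)^2 / sum_a SSY_a ),

with SSY_a the response sum of squares explained by component a, satisfies
sum_j VIP_j^2 = p for every fitted model. Backward "shaving" repeatedly
drops the fraction of predictors with the lowest VIP, choosing the number
of components each round by K-fold cross-validated RMSEP, and returns the
subset with the smallest cross-validated RMSEP. Predictors are banded by
VIP: > 1 major, (0.8, 1] medium, <= 0.8 negligible (the half-open boundary
convention is disclosed in the classification output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PLSModel:
    """Fitted single-response PLS model on standardized data."""

    predictors: list[str]
    n_components: int
    weights: np.ndarray          # p x A, columns unit norm (w_a)
    scores: np.ndarray           # n x A (t_a)
    x_loadings: np.ndarray       # p x A (p_a)
    y_loadings: np.ndarray       # A (q_a)
    coef_std: np.ndarray         # p, on the standardized scale
    coef: np.ndarray             # p, original-scale slope coefficients
    intercept: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    ssy: np.ndarray              # A, explained response SS per component

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictors].to_numpy(float)
        return X @ self.coef + self.intercept

    def r2(self, X, y) -> float:
        y = np.asarray(y, float)
        resid = y - self.predict(X)
        return 1.0 - float(resid @ resid) / float((y - y.mean()) @ (y - y.mean()))


def fit_pls(X: pd.DataFrame, y, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS deflation on z-standardized X and y.

    ``n_components`` may not exceed rank(X); with A = rank(X) the
    coefficients coincide with ordinary least squares.
    """
    names = list(X.columns)
    Xm = X.to_numpy(float)
    yv = np.asarray(y, float).ravel()
    n, p = Xm.shape
    if n != yv.size:
        raise ValueError("X and y length mismatch")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rank = np.linalg.matrix_rank(Xm - Xm.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")
    x_mean, x_std = Xm.mean(axis=0), Xm.std(axis=0, ddof=1)
    if np.any(x_std <= 0):
        bad = [names[j] for j in np.flatnonzero(x_std <= 0)]
        raise ValueError(f"constant predictor(s): {bad}")
    y_mean, y_std = float(yv.mean()), float(yv.std(ddof=1))
    if y_std <= 0:
        raise ValueError("constant response")
    E = (Xm - x_mean) / x_std
    f = (yv - y_mean) / y_std

    A = n_components
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    ssy = np.zeros(A)
    for a in range(A):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            raise ValueError("degenerate component: X carries no covariance with y")
        w /= nw
        t = E @ w
        tt = float(t @ t)
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
        ssy[a] = q_a**2 * tt
    coef_std = W @ np.linalg.solve(P.T @ W, q)
    coef = coef_std * y_std / x_std
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        predictors=names, n_components=A, weights=W, scores=T, x_loadings=P,
        y_loadings=q, coef_std=coef_std, coef=coef, intercept=intercept,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std, ssy=ssy,
    )


def vip(model: PLSModel) -> pd.Series:
    """Per-predictor VIP; satisfies sum(VIP^2) = number of predictors."""
    W, ssy = model.weights, model.ssy
    p = W.shape[0]
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    v = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    return pd.Series(v, index=model.predictors, name="VIP")


# ---------------------------------------------------------------------------
# Cross-validation and shaving
# ---------------------------------------------------------------------------

def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [fold for fold in np.array_split(idx, k)]


def cv_rmsep(
    X: pd.DataFrame, y, n_components: int, folds: list[np.ndarray]
) -> float:
    """Root-mean-square error of prediction under pre-drawn CV folds."""
    yv = np.asarray(y, float).ravel()
    n = len(yv)
    press = 0.0
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        a = min(n_components, np.linalg.matrix_rank(
            X.iloc[train].to_numpy() - X.iloc[train].to_numpy().mean(axis=0)))
        m = fit_pls(X.iloc[train], yv[train], a)
        resid = yv[test] - m.predict(X.iloc[test])
        press += float(resid @ resid)
    return math.sqrt(press / n)


def choose_components(
    X: pd.DataFrame, y, folds: list[np.ndarray], max_components: int = 5
) -> tuple[int, float]:
    """Number of components minimizing CV RMSEP (capped by rank)."""
    Xc = X.to_numpy(float)
    cap = min(max_components, np.linalg.matrix_rank(Xc - Xc.mean(axis=0)))
    best_a, best_r = 1, math.inf
    for a in range(1, cap + 1):
        r = cv_rmsep(X, y, a, folds)
        if r < best_r - 1e-12:
            best_a, best_r = a, r
    return best_a, best_r


@dataclass
class ShaveStep:
    predictors: list[str]
    n_components: int
    rmsep: float
    vips: pd.Series


@dataclass
class ShaveResult:
    """Outcome of VIP-guided backward shaving."""

    selected: list[str]
    model: PLSModel
    vips: pd.Series
    rmsep: float
    n_components: int
    history: list[ShaveStep] = field(repr=False, default_factory=list)


def shave(
    X: pd.DataFrame,
    y,
    cv_folds: int = 10,
    step_fraction: float = 0.2,
    max_components: int = 5,
    seed: int = 0,
) -> ShaveResult:
    """Backward variable shaving guided by VIP and CV RMSEP.

    Each round: choose A by K-fold CV, fit, record RMSEP, drop the
    ``step_fraction`` of predictors with the lowest VIP (at least one,
    never all). The subset with minimal CV RMSEP wins; the final model is
    refit on it. Deterministic given the fold seed.
    """
    if X.shape[1] < 4:
        raise ValueError("shaving needs at least 4 predictors")
    if not 0 < step_fraction < 1:
        raise ValueError("step_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    k = min(cv_folds, n)
    folds = _kfold_indices(n, k, rng)

    current = list(X.columns)
    history: list[ShaveStep] = []
    while True:
        Xc = X[current]
        a, rmsep = choose_components(Xc, y, folds, max_components)
        m = fit_pls(Xc, y, a)
        v = vip(m)
        history.append(ShaveStep(list(current), a, rmsep, v))
        if len(current) == 1:
            break
        n_drop = max(1, int(math.floor(step_fraction * len(current))))
        n_drop = min(n_drop, len(current) - 1)
        order = v.sort_values(kind="stable")
        current = [c for c in current if c not in set(order.index[:n_drop])]

    best = min(history, key=lambda s: s.rmsep)
    a_final, rmsep_final = choose_components(X[best.predictors], y, folds, max_components)
    final = fit_pls(X[best.predictors], y, a_final)
    return ShaveResult(
        selected=list(best.predictors),
        model=final,
        vips=vip(final),
        rmsep=rmsep_final,
        n_components=a_final,
        history=history,
    )


# ---------------------------------------------------------------------------
# VIP banding
# ---------------------------------------------------------------------------

BAND_MAJOR = "major"
BAND_MEDIUM = "medium"
BAND_NEGLIGIBLE = "negligible"


def classify_vip(vips: pd.Series) -> pd.DataFrame:
    """Band predictors by VIP: > 1 major, (0.8, 1] medium, <= 0.8 negligible.

    Values exactly at a band edge are flagged as boundary cases. Sorted by
    descending VIP (stable).
    """
    rows = []
    for name, v in vips.items():
        if v > 1.0:
            band = BAND_MAJOR
        elif v > 0.8:
            band = BAND_MEDIUM
        else:
            band = BAND_NEGLIGIBLE
        rows.append(
            {
                "predictor": name,
                "VIP": float(v),
                "band": band,
                "boundary": bool(np.isclose(v, 1.0) or np.isclose(v, 0.8)),
            }
        )
    df = pd.DataFrame(rows, columns=["predictor", "VIP", "band", "boundary"])
    return df.sort_values("VIP", ascending=False, kind="stable").reset_index(drop=True)
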