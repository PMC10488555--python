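"""PLS1 regression (NIPALS) with leave-one-out cross-validation.

The model is the classic chemometric calibration: mean-center X and y
(no autoscaling), extract latent variables by NIPALS with y-deflation,
and express the fit as a single regression vector ``b`` so that

    y_hat = y_mean + (x - x_mean) . b

The number of latent variables is chosen by full (leave-one-out)
cross-validation, taking the smallest LV count whose RMSECV attains the
minimum.

For a single response NIPALS needs no inner iteration, and the whole
coefficient path b(1), ..., b(max_lv) falls out of one pass of
deflations; :func:`pls1_coefficient_path` exposes that path because the
wavelength-selection loops downstream evaluate many LV counts per fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

try:  # the LOO loop is hot inside wavelength selection; JIT when available
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = ["PLSModel", "CVResult", "fit_pls", "predict", "loo_rmsecv", "fit_pls_cv", "pls1_coefficient_path"]

_EPS = 1e-14


def pls1_coefficient_path(X: np.ndarray, y: np.ndarray, max_lv: int):
    """Regression-vector path for 1..max_lv latent variables.

    Returns ``(B, x_mean, y_mean, n_components)`` where column ``k-1`` of
    ``B`` (shape ``(p, max_lv)``) is the coefficient vector of the k-LV
    model.  If the residual collapses before ``max_lv`` components the
    remaining columns repeat the last attainable model and
    ``n_components`` reports how many were actually extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    B = np.empty((p, max_lv))
    b = np.zeros(p)
    loadings: list[np.ndarray] = []
    rotations: list[np.ndarray] = []
    scale = float(np.abs(yc).sum() + np.abs(Xc).max() + 1.0)
    k_eff = 0
    for k in range(max_lv):
        w = Xc.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= _EPS * scale:
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _EPS * scale:
            break
        pl = (Xc.T @ t) / tt
        q = float(yc @ t) / tt
        Xc -= np.outer(t, pl)
        yc = yc - q * t
        r = w.copy()
        for pj, rj in zip(loadings, rotations):
            r -= float(pj @ w) * rj
        b = b + q * r
        B[:, k] = b
        loadings.append(pl)
        rotations.append(r)
        k_eff = k + 1
    for k in range(k_eff, max_lv):
        B[:, k] = b
    return B, x_mean, y_mean, k_eff


@dataclass
class PLSModel:
    """Fitted PLS1 calibration.

    ``coefficients`` is the regression vector of the ``lvs``-component
    model; ``coef_path[:, k-1]`` gives the k-component vector for
    k <= lvs.
    """

    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    coef_path: np.ndarray
    lvs: int
    n_components_effective: int

    @property
    def n_variables(self) -> int:
        return self.coefficients.size


@dataclass
class CVResult:
    rmsecv_by_lv: np.ndarray  # index k-1 -> RMSECV of the k-LV model
    best_lv: int

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv_by_lv[self.best_lv - 1])


def fit_pls(X: np.ndarray, y: np.ndarray, lvs: int) -> PLSModel:
    """Fit a mean-centered NIPALS PLS1 model with ``lvs`` components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match the number of rows of X")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite (no NaNs)")
    if not 1 <= lvs <= min(n - 1, p):
        raise ValueError(f"lvs must be in [1, {min(n - 1, p)}], got {lvs}")
    if y.std() == 0.0:
        raise ValueError("y has zero variance")
    B, x_mean, y_mean, k_eff = pls1_coefficient_path(X, y, lvs)
    return PLSModel(
        x_mean=x_mean,
        y_mean=float(y_mean),
        coefficients=B[:, lvs - 1].copy(),
        coef_path=B,
        lvs=lvs,
        n_components_effective=k_eff,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict responses for the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_variables:
        raise ValueError(
            f"X has {X.shape[1]} variables, model expects {model.n_variables}"
        )
    return model.y_mean + (X - model.x_mean) @ model.coefficients


@njit(cache=True)
def _loo_press_kernel(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """Leave-one-out PRESS per LV count via one NIPALS path per fold."""
    n, p = X.shape
    press = np.zeros(max_lv)
    Xt = np.empty((n - 1, p))
    yt = np.empty(n - 1)
    P = np.empty((max_lv, p))
    R = np.empty((max_lv, p))
    for i in range(n):
        idx = 0
        for r in range(n):
            if r != i:
                Xt[idx] = X[r]
                yt[idx] = y[r]
                idx += 1
        xm = np.zeros(p)
        for r in range(n - 1):
            xm += Xt[r]
        xm /= n - 1
        ym = yt.mean()
        Xc = Xt - xm
        yc = yt - ym
        xi = X[i] - xm
        scale = np.abs(yc).sum() + np.abs(Xc).max() + 1.0
        b = np.zeros(p)
        k_eff = 0
        for k in range(max_lv):
            w = Xc.T @ yc
            nw = np.sqrt((w * w).sum())
            if nw <= _EPS * scale:
                break
            w /= nw
            t = Xc @ w
            tt = (t * t).sum()
            if tt <= _EPS * scale:
                break
            pl = (Xc.T @ t) / tt
            q = (yc @ t) / tt
            Xc -= np.outer(t, pl)
            yc = yc - q * t
            r_vec = w.copy()
            for j in range(k):
                r_vec -= (P[j] @ w) * R[j]
            b = b + q * r_vec
            P[k] = pl
            R[k] = r_vec
            e = ym + xi @ b - y[i]
            press[k] += e * e
            k_eff = k + 1
        if k_eff < max_lv:
            e = ym + xi @ b - y[i]
            for k in range(k_eff, max_lv):
                press[k] += e * e
    return press


@njit(cache=True)
def _mc_final_coefs_kernel(X: np.ndarray, y: np.ndarray, rows: np.ndarray, max_lv: int) -> np.ndarray:
    """Final-LV NIPALS coefficient vectors for M Monte-Carlo row subsets."""
    M, ns = rows.shape
    p = X.shape[1]
    out = np.zeros((M, p))
    Xt = np.empty((ns, p))
    yt = np.empty(ns)
    for m in range(M):
        for r in range(ns):
            Xt[r] = X[rows[m, r]]
            yt[r] = y[rows[m, r]]
        xm = np.zeros(p)
        for r in range(ns):
            xm += Xt[r]
        xm /= ns
        ym = yt.mean()
        Xc = Xt - xm
        yc = yt - ym
        scale = np.abs(yc).sum() + np.abs(Xc).max() + 1.0
        b = np.zeros(p)
        P = np.empty((max_lv, p))
        R = np.empty((max_lv, p))
        for k in range(max_lv):
            w = Xc.T @ yc
            nw = np.sqrt((w * w).sum())
            if nw <= _EPS * scale:
                break
            w /= nw
            t = Xc @ w
            tt = (t * t).sum()
            if tt <= _EPS * scale:
                break
            pl = (Xc.T @ t) / tt
            q = (yc @ t) / tt
            Xc -= np.outer(t, pl)
            yc = yc - q * t
            r_vec = w.copy()
            for j in range(k):
                r_vec -= (P[j] @ w) * R[j]
            b = b + q * r_vec
            P[k] = pl
            R[k] = r_vec
        out[m] = b
    return out


def _mc_final_coefs_numpy(X: np.ndarray, y: np.ndarray, rows: np.ndarray, max_lv: int) -> np.ndarray:
    out = np.zeros((rows.shape[0], X.shape[1]))
    for m in range(rows.shape[0]):
        B, _, _, k_eff = pls1_coefficient_path(X[rows[m]], y[rows[m]], max_lv)
        if k_eff:
            out[m] = B[:, k_eff - 1]
    return out


monte_carlo_final_coefs = _mc_final_coefs_kernel if _HAVE_NUMBA else _mc_final_coefs_numpy


def _loo_press_numpy(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    n = X.shape[0]
    press = np.zeros(max_lv)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        B, x_mean, y_mean, _ = pls1_coefficient_path(X[mask], y[mask], max_lv)
        yhat = y_mean + (X[i] - x_mean) @ B
        press += (yhat - y[i]) ** 2
        mask[i] = True
    return press


_loo_press = _loo_press_kernel if _HAVE_NUMBA else _loo_press_numpy


def loo_rmsecv(X: np.ndarray, y: np.ndarray, max_lvs: int) -> CVResult:
    """Leave-one-out RMSECV for 1..max_lvs latent variables.

    ``best_lv`` is the smallest LV count whose RMSECV is within 1e-12 of
    the minimum.  ``max_lvs`` is clamped (with a warning) to n-2 — each
    leave-one-out fit has n-1 training samples — and to p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out cross-validation needs at least 3 samples")
    limit = min(n - 2, p)
    if max_lvs > limit:
        warnings.warn(
            f"max_lvs={max_lvs} exceeds the usable limit {limit}; clamping",
            stacklevel=2,
        )
        max_lvs = limit
    if max_lvs < 1:
        raise ValueError("max_lvs must be at least 1")
    press = _loo_press(np.ascontiguousarray(X), np.ascontiguousarray(y), max_lvs)
    rmsecv = np.sqrt(press / n)
    best = int(np.argmin(rmsecv))
    for k in range(best + 1):
        if rmsecv[k] <= rmsecv[best] + 1e-12:
            best = k
            break
    return CVResult(rmsecv_by_lv=rmsecv, best_lv=best + 1)


def fit_pls_cv(X: np.ndarray, y: np.ndarray, max_lvs: int) -> tuple[PLSModel, CVResult]:
    """LOO-select the LV count, then fit on the full data."""
    cv = loo_rmsecv(X, y, max_lvs)
    return fit_pls(X, y, cv.best_lv), cv
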