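"""Maximum-likelihood binary logistic regression by Newton/IRLS.

Two entry points:

* :func:`fit_logistic` — fit one model, returning a :class:`LogisticModel`
  with its log-likelihood (and hence BIC).
* :func:`scan_candidates` — given a fitted base design, fit *all* one-feature
  extensions simultaneously.  The forward-stepwise search evaluates a few
  hundred candidate additions per step inside a permutation loop, so the scan
  is vectorized across candidates: one Newton iteration updates every
  candidate model at once using stacked (F, k+1, k+1) Hessians.

Convergence is declared when the largest score (gradient) component falls
below ``tol`` (default 1e-8), with a 100-iteration cap.  Quasi-complete
separation is detected as coefficient divergence (any |beta| above
``SEPARATION_BOUND``); separated fits are flagged, not raised.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import LogisticModel

TOL = 1e-8
MAX_ITER = 100
#: |coefficient| beyond which a fit is treated as (quasi-)separated.
#: Predictors here are log-scale values with O(1) spread, where a slope of 30
#: moves the log-odds by ~30 per SD — numerically indistinguishable from a
#: step function.
SEPARATION_BOUND = 30.0
#: Newton step clip, to keep early iterations from overshooting.
STEP_CLIP = 5.0


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1+exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_array(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, float, bool, bool]:
    """Newton/IRLS on a design matrix *without* an implicit intercept.

    Returns ``(beta, loglik, converged, separated)``.  ``X`` must already
    contain the intercept column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    # start the intercept at the empirical log-odds
    pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    beta[0] = np.log(pbar / (1 - pbar))
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X + ridge * np.eye(k)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        norm = np.max(np.abs(step))
        if norm > STEP_CLIP:
            step *= STEP_CLIP / norm
        beta += step
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            separated = True
            break
    eta = X @ beta
    return beta, _loglik(y, eta), converged, separated


def fit_logistic(
    X: Optional[pd.DataFrame],
    y,
    features: Optional[Sequence[str]] = None,
    ridge: float = 0.0,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> LogisticModel:
    """Fit a logistic regression of binary ``y`` on the given features.

    Parameters
    ----------
    X : DataFrame or None
        Predictor table (complete, numeric).  ``None`` or an empty feature
        list fits the intercept-only model.
    y : array-like of {0, 1}
        Outcome; must contain both classes.
    features : sequence of column names, optional
        Subset of ``X`` to use; defaults to all columns.

    Raises
    ------
    ValueError
        If ``y`` is single-class or predictors contain NaN.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be one-dimensional")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("y contains a single class; cannot fit a logistic model")
    n = len(y)
    if X is None:
        features = []
    else:
        features = list(X.columns) if features is None else list(features)
    if features:
        M = np.asarray(X[features], dtype=float)
        if np.isnan(M).any():
            bad = [f for f in features if np.isnan(np.asarray(X[f], dtype=float)).any()]
            raise ValueError(f"predictors contain missing values: {bad}")
        # center predictors: keeps the working intercept O(1) so the
        # coefficient-magnitude separation check never trips on an offset,
        # and conditions the Newton iterations; slopes are unaffected
        means = M.mean(axis=0)
        design = np.column_stack([np.ones(n), M - means])
    else:
        means = np.zeros(0)
        design = np.ones((n, 1))
    beta, ll, converged, separated = fit_logistic_array(
        design, y, ridge=ridge, tol=tol, max_iter=max_iter
    )
    beta[0] -= beta[1:] @ means
    return LogisticModel(
        intercept=float(beta[0]),
        coef={f: float(b) for f, b in zip(features, beta[1:])},
        loglik=ll,
        n=n,
        separated=separated,
        converged=converged,
        ridge=ridge,
    )


def bic(model: LogisticModel) -> float:
    """Bayesian Information Criterion, ``-2 L + k ln(n)``, k counting the intercept."""
    return model.bic


def scan_candidates(
    S: np.ndarray,
    C: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit every one-column extension of a base design in one vectorized pass.

    Parameters
    ----------
    S : (n, k) base design including the intercept column.
    C : (n, F) candidate columns; model ``j`` uses ``[S, C[:, j]]``.
    y : (n,) binary outcome.
    beta0 : (k,) fitted coefficients of the base model (warm start).

    Returns
    -------
    loglik : (F,) maximized log-likelihood per candidate model.
    beta : (F, k+1) coefficients per candidate model.
    ok : (F,) bool — converged and not separation-flagged.
    """
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = S.shape
    F = C.shape[1]
    beta = np.tile(np.append(beta0, 0.0), (F, 1))  # (F, k+1)
    active = np.ones(F, dtype=bool)
    ok = np.ones(F, dtype=bool)
    eye = np.eye(k + 1) * 1e-12  # jitter keeps collinear candidates solvable
    # pairwise products of base-design columns: HSS[f] = P.T @ w[:, f]
    pair_idx = [(a, b) for a in range(k) for b in range(a, k)]
    P = np.stack([S[:, a] * S[:, b] for a, b in pair_idx], axis=1)  # (n, k(k+1)/2)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ca = C[:, idx]  # (n, Fa)
        Ba = beta[idx]  # (Fa, k+1)
        eta = S @ Ba[:, :k].T + Ca * Ba[:, k]  # (n, Fa)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu  # (n, Fa)
        wc = w * Ca  # (n, Fa)
        gS = S.T @ resid  # (k, Fa)
        gC = np.sum(Ca * resid, axis=0)  # (Fa,)
        g = np.concatenate([gS, gC[None, :]], axis=0).T  # (Fa, k+1)
        conv = np.max(np.abs(g), axis=1) < tol
        # Hessian blocks, all via gemms
        HSS = P.T @ w  # (k(k+1)/2, Fa)
        HSC = S.T @ wc  # (k, Fa)
        HCC = np.sum(Ca * wc, axis=0)  # (Fa,)
        H = np.empty((idx.size, k + 1, k + 1))
        for col, (a, b) in enumerate(pair_idx):
            H[:, a, b] = HSS[col]
            H[:, b, a] = HSS[col]
        H[:, :k, k] = HSC.T
        H[:, k, :k] = HSC.T
        H[:, k, k] = HCC
        try:
            step = np.linalg.solve(H + eye, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            ok[idx] = False
            break
        norm = np.max(np.abs(step), axis=1)
        big = norm > STEP_CLIP
        step[big] *= (STEP_CLIP / norm[big])[:, None]
        Bnew = Ba + step
        Bnew[conv] = Ba[conv]
        beta[idx] = Bnew
        div = np.max(np.abs(Bnew), axis=1) > SEPARATION_BOUND
        ok[idx[div]] = False
        active[idx[conv | div]] = False
    ok &= ~active  # still-active candidates did not converge
    eta = S @ beta[:, :k].T + C * beta[:, k]  # (n, F)
    ll = np.sum(y[:, None] * eta - np.logaddexp(0.0, eta), axis=0)
    return ll, beta, ok
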