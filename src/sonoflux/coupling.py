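"""Cross-omics coupling models: NIPALS partial least squares regression
with cross-validated Q2, VIP scores and permutation validation, and
redundancy analysis (RDA) with variance partitioning.

The PLS implementation is single-response (PLS1) NIPALS: for each
component, w is proportional to X^T y, t = X w, loadings p = X^T t / t^T t
and q = y^T t / t^T t, with deflation of both blocks.  Predictive power is
summarized by R2Y (fit) and Q2 = 1 - PRESS/TSS under seeded contiguous-block
cross-validation; variable influence by VIP scores whose squares average to
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["PLSRegressionNIPALS", "plsr_fit", "vip_scores", "rda", "RDAResult"]


class PLSRegressionNIPALS(BaseEstimator, RegressorMixin):
    """Single-response NIPALS PLS regression with Q2, VIP and permutation p.

    Parameters
    ----------
    n_components : int
        Number of latent variables; must not exceed the rank of X.
    cv_folds : int
        Folds for the Q2 cross-validation (contiguous blocks after a seeded
        shuffle).
    n_perm : int
        Response permutations for the validation p-value (0 disables).
    scale : bool
        Autoscale X columns to unit variance (always centred).
    random_state : int or None
        Seed for fold assignment and permutations.

    Attributes
    ----------
    x_weights_ : (p, a) ndarray, unit-norm weight vectors W.
    x_loadings_ : (p, a) ndarray P.
    y_loadings_ : (a,) ndarray q.
    x_scores_ : (n, a) ndarray T with mutually orthogonal columns.
    coef_ : (p,) regression vector on the standardized scale.
    r2y_ : float, cumulative explained response variance.
    q2_ : float, cross-validated predictive R2.
    rmsee_ : float, residual standard error sqrt(SSres / (n - a - 1)).
    vip_ : (p,) variable-importance-in-projection scores.
    permutation_p_ : float or None.
    """

    def __init__(self, n_components: int = 2, cv_folds: int = 7,
                 n_perm: int = 200, scale: bool = True,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.cv_folds = cv_folds
        self.n_perm = n_perm
        self.scale = scale
        self.random_state = random_state

    # -- core NIPALS on standardized data -------------------------------
    @staticmethod
    def _nipals(x: np.ndarray, y: np.ndarray, a: int):
        n, p = x.shape
        W = np.zeros((p, a))
        P = np.zeros((p, a))
        T = np.zeros((n, a))
        q = np.zeros(a)
        xr, yr = x.copy(), y.copy()
        for i in range(a):
            w = xr.T @ yr
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(
                    f"component {i + 1}: X carries no residual covariance with y "
                    "(n_components may exceed rank)")
            w /= norm
            t = xr @ w
            tt = t @ t
            if tt == 0:
                raise ValueError(f"component {i + 1}: degenerate score vector")
            pl = xr.T @ t / tt
            qi = yr @ t / tt
            xr = xr - np.outer(t, pl)
            yr = yr - qi * t
            W[:, i], P[:, i], T[:, i], q[i] = w, pl, t, qi
        return W, P, T, q

    def _standardize(self, X, y):
        xm = X.mean(axis=0)
        xs = X.std(axis=0, ddof=1) if self.scale else np.ones(X.shape[1])
        xs = np.where(xs == 0, 1.0, xs)
        ym = y.mean()
        return (X - xm) / xs, y - ym, xm, xs, ym

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n != y.size:
            raise ValueError("X and y disagree on sample count")
        if n < self.cv_folds:
            raise ValueError("need at least cv_folds samples")
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds rank(X)={rank}")
        xz, yc, self.x_mean_, self.x_std_, self.y_mean_ = self._standardize(X, y)
        W, P, T, q = self._nipals(xz, yc, self.n_components)
        self.x_weights_, self.x_loadings_, self.x_scores_, self.y_loadings_ = W, P, T, q
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        fitted = xz @ self.coef_
        ss_tot = yc @ yc
        ss_res = np.sum((yc - fitted) ** 2)
        self.r2y_ = 1.0 - ss_res / ss_tot
        dof = max(n - self.n_components - 1, 1)
        self.rmsee_ = float(np.sqrt(ss_res / dof))
        self.vip_ = vip_scores(self)
        rng = np.random.default_rng(self.random_state)
        self.q2_ = self._q2(X, y, rng)
        self.permutation_p_ = self._permutation_p(xz, yc, ss_tot, rng) \
            if self.n_perm else None
        return self

    def _q2(self, X, y, rng) -> float:
        n = len(y)
        idx = rng.permutation(n)
        folds = np.array_split(idx, self.cv_folds)
        press = 0.0
        for fold in folds:
            train = np.setdiff1d(idx, fold)
            xz, yc, xm, xs, ym = self._standardize(X[train], y[train])
            W, P, _, q = self._nipals(xz, yc, self.n_components)
            coef = W @ np.linalg.solve(P.T @ W, q)
            pred = ((X[fold] - xm) / xs) @ coef + ym
            press += np.sum((y[fold] - pred) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - press / tss

    def _permutation_p(self, xz, yc, ss_tot, rng) -> float:
        count = 0
        for _ in range(self.n_perm):
            yp = rng.permutation(yc)
            try:
                W, P, _, q = self._nipals(xz, yp, self.n_components)
            except ValueError:
                continue
            coef = W @ np.linalg.solve(P.T @ W, q)
            r2p = 1.0 - np.sum((yp - xz @ coef) ** 2) / (yp @ yp)
            if r2p >= self.r2y_:
                count += 1
        return (1 + count) / (1 + self.n_perm)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return ((X - self.x_mean_) / self.x_std_) @ self.coef_ + self.y_mean_


def vip_scores(model: PLSRegressionNIPALS) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a) with
    SSY_a = q_a^2 t_a^T t_a the response variance captured by component a.
    The mean of the squared VIPs is exactly 1.
    """
    W = model.x_weights_
    T = model.x_scores_
    q = model.y_loadings_
    ssy = q ** 2 * np.einsum("ij,ij->j", T, T)
    p = W.shape[0]
    return np.sqrt(p * (W ** 2 @ ssy) / ssy.sum())


def plsr_fit(X, y, n_components: int = 2, cv_folds: int = 7,
             n_perm: int = 200, seed: int | None = 0) -> PLSRegressionNIPALS:
    """Functional wrapper: fit and return a :class:`PLSRegressionNIPALS`."""
    return PLSRegressionNIPALS(n_components=n_components, cv_folds=cv_folds,
                               n_perm=n_perm, random_state=seed).fit(X, y)


@dataclass
class RDAResult:
    constrained_fraction: float
    axis_fractions: np.ndarray  # sums to constrained_fraction
    permutation_p: float
    sample_scores: np.ndarray  # samples x axes (PCA of fitted responses)
    predictor_scores: pd.DataFrame  # correlations of predictors with axes
    response_loadings: pd.DataFrame


def rda(Y, X, n_perm: int = 999, seed: int | None = 0) -> RDAResult:
    """Redundancy analysis: ordination of responses constrained by
    predictors.

    Y columns are regressed on centred X by OLS; the constrained variance
    fraction is SS(fitted)/SS(Y) and the axes are the principal components
    of the fitted values.  Significance is assessed by row-permuting X.
    """
    Y = pd.DataFrame(Y)
    X = pd.DataFrame(X)
    n = len(Y)
    if len(X) != n:
        raise ValueError("Y and X disagree on sample count")
    if n <= X.shape[1] + 1:
        raise ValueError("need more samples than predictors + 1")
    yc = Y.to_numpy(dtype=float) - Y.to_numpy(dtype=float).mean(axis=0)
    xc = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        # identify columns whose removal restores full rank
        bad = [c for j, c in enumerate(X.columns)
               if np.linalg.matrix_rank(np.delete(xc, j, axis=1)) == rank]
        raise ValueError(f"collinear predictor columns: {bad}")

    def fraction(xmat):
        beta, *_ = np.linalg.lstsq(xmat, yc, rcond=None)
        fitted = xmat @ beta
        return np.sum(fitted ** 2) / np.sum(yc ** 2), fitted

    frac_obs, fitted = fraction(xc)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > 1e-12 * (s[0] if s.size else 1.0)
    s = s[keep]
    axis_fractions = s ** 2 / np.sum(yc ** 2)
    scores = u[:, keep] * s
    axes = [f"RDA{i + 1}" for i in range(len(s))]
    resp_load = pd.DataFrame(vt[keep].T, index=Y.columns, columns=axes)
    with np.errstate(invalid="ignore"):
        pred_scores = pd.DataFrame(
            np.array([[np.corrcoef(xc[:, j], scores[:, a])[0, 1]
                       for a in range(len(s))] for j in range(xc.shape[1])]),
            index=X.columns, columns=axes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if fraction(xc[rng.permutation(n)])[0] >= frac_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return RDAResult(float(frac_obs), axis_fractions, p, scores,
                     pred_scores, resp_load)
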