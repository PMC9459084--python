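"""Single-response OPLS: orthogonal signal correction + one predictive
latent variable, with VIP, cross-validated Q2 and permutation testing.

The algorithm removes y-uncorrelated X variation component by
component (orthogonal scores have exactly zero sample covariance with
the response), then fits one predictive PLS component on the filtered
matrix. With k orthogonal components the fitted values coincide with
those of a plain (k+1)-component NIPALS PLS on the same data; the
benefit is interpretability: all predictive information is carried by
a single weight vector, from which VIP (normalized so that the mean of
squared VIP is 1) and standardized regression coefficients are read.

The same engine serves OPLS-DA by passing a binary class indicator as
the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FitError

_TOL = 1e-12


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.values.astype(float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


@dataclass
class OplsModel:
    """Fitted OPLS model on standardized variables."""

    variables: list
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    w: np.ndarray  # predictive weights, unit norm
    p_load: np.ndarray  # predictive loadings
    q: float  # predictive y-loading
    t: np.ndarray  # predictive scores (training)
    w_orth: np.ndarray  # (p, k)
    p_orth: np.ndarray  # (p, k)
    t_orth: np.ndarray  # (n, k)
    r2x: float
    r2x_pred: float
    r2x_orth: float
    r2y: float
    q2: float | None = None
    fold_seed: int = 0

    @property
    def n_orthogonal(self) -> int:
        return self.w_orth.shape[1]

    @property
    def coefficients(self) -> pd.Series:
        """Regression coefficients mapping standardized X to standardized y."""
        b = _filter_matrix(np.eye(len(self.w)), self.w_orth, self.p_orth) @ self.w * self.q
        return pd.Series(b, index=self.variables)

    @property
    def vip(self) -> pd.Series:
        """VIP from the predictive component; mean of squared VIP is 1."""
        p = len(self.w)
        return pd.Series(np.sqrt(p) * np.abs(self.w), index=self.variables)

    def predict(self, X) -> np.ndarray:
        Xm, _ = _as_matrix(X)
        Xs = (Xm - self.x_mean) / self.x_sd
        Xf = _filter_matrix(Xs, self.w_orth, self.p_orth)
        return self.y_mean + self.y_sd * self.q * (Xf @ self.w)

    def summary(self) -> dict:
        return {
            "n_orthogonal": self.n_orthogonal,
            "R2X": self.r2x,
            "R2Y": self.r2y,
            "Q2": self.q2,
        }


def _filter_matrix(Xs, w_orth, p_orth):
    """Remove the fitted orthogonal components from (standardized) rows."""
    Xf = np.array(Xs, dtype=float, copy=True)
    for a in range(w_orth.shape[1]):
        t_o = Xf @ w_orth[:, a]
        Xf -= np.outer(t_o, p_orth[:, a])
    return Xf


def _standardize(Xm, y, variables):
    x_mean = Xm.mean(axis=0)
    x_sd = Xm.std(axis=0, ddof=1)
    zero = x_sd <= _TOL * np.maximum(1.0, np.abs(x_mean))
    if zero.any():
        names = [variables[j] for j in np.flatnonzero(zero)]
        raise FitError(f"constant variables cannot be scaled: {names}")
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd <= _TOL * max(1.0, abs(y_mean)):
        raise FitError("response is constant")
    return (Xm - x_mean) / x_sd, (y - y_mean) / y_sd, x_mean, x_sd, y_mean, y_sd


def _fit_core(Xs, ys, n_orthogonal):
    n, p = Xs.shape
    if n_orthogonal >= min(n - 1, p):
        raise FitError(
            f"{n_orthogonal} orthogonal components exceed the rank budget "
            f"of a {n}x{p} matrix"
        )
    Xc = Xs.copy()
    w_list, p_list, t_list = [], [], []
    for _ in range(n_orthogonal):
        w = Xc.T @ ys
        nw = np.linalg.norm(w)
        if nw < _TOL:
            break
        w = w / nw
        t = Xc @ w
        p_vec = Xc.T @ t / (t @ t)
        w_o = p_vec - (w @ p_vec) * w
        n_o = np.linalg.norm(w_o)
        if n_o < _TOL:  # no y-orthogonal variation left
            break
        w_o = w_o / n_o
        t_o = Xc @ w_o
        tt = t_o @ t_o
        if tt < _TOL:
            break
        p_o = Xc.T @ t_o / tt
        Xc -= np.outer(t_o, p_o)
        w_list.append(w_o)
        p_list.append(p_o)
        t_list.append(t_o)

    w = Xc.T @ ys
    nw = np.linalg.norm(w)
    if nw < _TOL:
        raise FitError("response is uncorrelated with every variable")
    w = w / nw
    t = Xc @ w
    p_vec = Xc.T @ t / (t @ t)
    q = (ys @ t) / (t @ t)

    k = len(w_list)
    stack = lambda lst, ncol: (  # noqa: E731
        np.column_stack(lst) if lst else np.empty((ncol, 0))
    )
    w_orth = stack(w_list, p)
    p_orth = stack(p_list, p)
    t_orth = np.column_stack(t_list) if t_list else np.empty((n, 0))

    ss_x = float((Xs ** 2).sum())
    r2x_orth = float(
        sum((t_list[a] @ t_list[a]) * (p_list[a] @ p_list[a]) for a in range(k))
    ) / ss_x
    r2x_pred = float((t @ t) * (p_vec @ p_vec)) / ss_x
    yhat = q * t
    r2y = 1.0 - float(((ys - yhat) ** 2).sum()) / float((ys ** 2).sum())
    return w, p_vec, q, t, w_orth, p_orth, t_orth, r2x_pred, r2x_orth, r2y


def fit_opls(X, y, n_orthogonal="auto", max_orthogonal: int = 5,
             cv_folds: int = 7, fold_seed: int = 0) -> OplsModel:
    """Fit OPLS of a single response on a sample x variable matrix.

    ``n_orthogonal='auto'`` scans 0..max_orthogonal (within the rank
    budget) and keeps the count maximizing cross-validated Q2. X and y
    are centred and unit-variance scaled internally.
    """
    Xm, variables = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if n < 5:
        raise FitError(f"need at least 5 samples, got {n}")
    if len(yv) != n:
        raise ConfigError("X and y have different numbers of samples")

    if n_orthogonal == "auto":
        best_k, best_q2 = 0, -np.inf
        upper = min(max_orthogonal, min(n - 1, p) - 1)
        for k in range(upper + 1):
            try:
                q2 = cross_validate_q2(Xm, yv, folds=cv_folds, n_orthogonal=k,
                                       fold_seed=fold_seed)
            except FitError:
                break
            if q2 > best_q2 + 1e-9:
                best_k, best_q2 = k, q2
        n_orthogonal = best_k
        q2 = best_q2 if np.isfinite(best_q2) else None
    else:
        q2 = cross_validate_q2(Xm, yv, folds=cv_folds, n_orthogonal=n_orthogonal,
                               fold_seed=fold_seed)

    Xs, ys, x_mean, x_sd, y_mean, y_sd = _standardize(Xm, yv, variables)
    (w, p_vec, q, t, w_orth, p_orth, t_orth,
     r2x_pred, r2x_orth, r2y) = _fit_core(Xs, ys, n_orthogonal)
    return OplsModel(
        variables=variables, x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        w=w, p_load=p_vec, q=q, t=t, w_orth=w_orth, p_orth=p_orth, t_orth=t_orth,
        r2x=r2x_pred + r2x_orth, r2x_pred=r2x_pred, r2x_orth=r2x_orth,
        r2y=r2y, q2=q2, fold_seed=fold_seed,
    )


def vip_scores(model: OplsModel) -> pd.Series:
    """Per-variable VIP of the predictive component."""
    return model.vip


def _venetian_folds(n, folds, fold_seed):
    order = np.random.default_rng(fold_seed).permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.arange(n) % folds
    return assignment


def cross_validate_q2(X, y, folds: int = 7, n_orthogonal: int = 0,
                      fold_seed: int = 0) -> float:
    """Q2 = 1 - PRESS / TSS from fold-held-out refits.

    Folds are assigned venetian-blind style over a seeded permutation
    of the sample order, so the value is deterministic given the seed.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    if folds < 2:
        raise ConfigError(f"folds must be >= 2, got {folds}")
    if folds > n:
        raise ConfigError(f"cannot split {n} samples into {folds} folds")
    assignment = _venetian_folds(n, folds, fold_seed)
    press = 0.0
    for f in range(folds):
        held = assignment == f
        Xtr, ytr = Xm[~held], yv[~held]
        Xs, ys, x_mean, x_sd, y_mean, y_sd = _standardize(
            Xtr, ytr, [str(j) for j in range(Xm.shape[1])]
        )
        w, p_vec, q, t, w_orth, p_orth, *_ = _fit_core(Xs, ys, n_orthogonal)
        Xh = (Xm[held] - x_mean) / x_sd
        Xh = _filter_matrix(Xh, w_orth, p_orth)
        yhat = y_mean + y_sd * q * (Xh @ w)
        press += float(((yv[held] - yhat) ** 2).sum())
    tss = float(((yv - yv.mean()) ** 2).sum())
    return 1.0 - press / tss


@dataclass
class PermutationResult:
    """Response-permutation validation of an OPLS fit."""

    table: pd.DataFrame  # columns: correlation, R2Y, Q2; first row = original
    n_orthogonal: int
    passed: bool = field(default=False)
    intercept_q2: float = field(default=np.nan)

    @property
    def original(self) -> pd.Series:
        return self.table.iloc[0]

    @property
    def permuted(self) -> pd.DataFrame:
        return self.table.iloc[1:]


def permutation_test(X, y, n_permutations: int = 200, n_orthogonal="auto",
                     max_orthogonal: int = 5, cv_folds: int = 7,
                     fold_seed: int = 0, seed: int = 0) -> PermutationResult:
    """Refit on uniformly permuted responses and compare R2Y / Q2.

    The verdict is "no overfitting" (``passed``) iff every permuted Q2
    falls below the original Q2 and the intercept at zero response
    correlation of the straight line fitted to the (correlation, Q2)
    points does not exceed 0.05.
    """
    if n_permutations < 20:
        warnings.warn(
            f"{n_permutations} permutations give an unstable verdict; use >= 20",
            stacklevel=2,
        )
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    model = fit_opls(Xm, yv, n_orthogonal=n_orthogonal,
                     max_orthogonal=max_orthogonal, cv_folds=cv_folds,
                     fold_seed=fold_seed)
    k = model.n_orthogonal
    rows = [(1.0, model.r2y, model.q2)]
    rng = np.random.default_rng(seed)
    y_c = yv - yv.mean()
    denom = float(y_c @ y_c)
    for _ in range(n_permutations):
        y_perm = rng.permutation(yv)
        corr = abs(float((y_perm - y_perm.mean()) @ y_c) / denom)
        try:
            perm_model = fit_opls(Xm, y_perm, n_orthogonal=k, cv_folds=cv_folds,
                                  fold_seed=fold_seed)
            rows.append((corr, perm_model.r2y, perm_model.q2))
        except FitError:
            rows.append((corr, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["correlation", "R2Y", "Q2"])
    perm_q2 = table["Q2"].iloc[1:]
    all_below = bool((perm_q2.dropna() < table["Q2"].iloc[0]).all())
    # straight line through all (correlation, Q2) points incl. the original
    valid = table.dropna(subset=["Q2"])
    slope, intercept = np.polyfit(valid["correlation"], valid["Q2"], 1)
    passed = all_below and intercept <= 0.05
    return PermutationResult(table=table, n_orthogonal=k, passed=passed,
                             intercept_q2=float(intercept))


def select_by_vip_coefficient(model_or_vip, coefficients=None,
                              vip_min: float = 0.7,
                              coef_max: float = -0.1) -> list:
    """Variables with VIP > vip_min and coefficient < coef_max.

    A negative coefficient against IC50 encodes the toxicity direction
    (more compound, lower IC50). Accepts a fitted model or explicit
    (vip, coefficient) Series.
    """
    if isinstance(model_or_vip, OplsModel):
        vip = model_or_vip.vip
        coefficients = model_or_vip.coefficients
    else:
        vip = pd.Series(model_or_vip)
        coefficients = pd.Series(coefficients)
    keep = (vip > vip_min) & (coefficients < coef_max)
    return list(vip.index[keep])
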