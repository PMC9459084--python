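"""Back-propagation network mapping compound areas to IC50, with
Garson connection-weight sensitivity and mean impact values (MIV).

The network is the classic three-layer feedforward regressor: inputs
(one per compound) -> one tanh hidden layer (default 10 units) ->
single linear output, trained to minimize MSE on min-max scaled data
with a seeded 80/20 train/validation split. Training is full-batch
gradient descent with an adaptive step and early stopping on the
validation MSE (patience 50 epochs, max 2000); the early stop is what
keeps the over-parameterized fit from chasing noise. Training is
non-convex, so several random restarts run under one master seed and
the weights with the best validation MSE are kept.

Variable importance is read from the trained weights two ways:

* Garson percentage: each input's share of the absolute connection
  weights routed through the hidden layer, normalized to 100%.
* MIV: perturb one (scaled) input column by +/-delta and average the
  prediction difference; the sign gives the direction of association,
  so inputs with negative MIV against IC50 are toxicity-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DataValidationError, FitError


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.values.astype(float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


@dataclass
class _Weights:
    w1: np.ndarray  # inputs x hidden
    b1: np.ndarray  # hidden
    w2: np.ndarray  # hidden
    b2: float

    def copy(self) -> "_Weights":
        return _Weights(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2)

    def predict(self, Xs: np.ndarray) -> np.ndarray:
        hidden = np.tanh(Xs @ self.w1 + self.b1)
        return hidden @ self.w2 + self.b2


#: shrink factor on the uniform fan-in/fan-out init. Early stopping
#: leaves untrained weights near their starting values, so a small
#: symmetric start keeps the connection-weight sensitivity (Garson)
#: reflecting trained structure rather than initialization noise.
_INIT_SCALE = 0.3


def _init_weights(n_in, n_hidden, rng) -> _Weights:
    limit1 = _INIT_SCALE * np.sqrt(6.0 / (n_in + n_hidden))
    limit2 = _INIT_SCALE * np.sqrt(6.0 / (n_hidden + 1))
    return _Weights(
        w1=rng.uniform(-limit1, limit1, size=(n_in, n_hidden)),
        b1=np.zeros(n_hidden),
        w2=rng.uniform(-limit2, limit2, size=n_hidden),
        b2=0.0,
    )


def _gradients(weights, Xs, ys):
    n = len(ys)
    hidden = np.tanh(Xs @ weights.w1 + weights.b1)
    pred = hidden @ weights.w2 + weights.b2
    d_out = 2.0 * (pred - ys) / n
    g_w2 = hidden.T @ d_out
    g_b2 = float(d_out.sum())
    d_hidden = np.outer(d_out, weights.w2) * (1.0 - hidden ** 2)
    g_w1 = Xs.T @ d_hidden
    g_b1 = d_hidden.sum(axis=0)
    mse = float(np.mean((pred - ys) ** 2))
    return mse, (g_w1, g_b1, g_w2, g_b2)


def _train_once(Xs_train, ys_train, Xs_val, ys_val, n_hidden, rng,
                max_epochs=2000, patience=50, lr0=0.5):
    """One gradient-descent run with bold-driver step adaptation and
    early stopping on validation MSE; returns the best-epoch weights."""
    weights = _init_weights(Xs_train.shape[1], n_hidden, rng)
    lr = lr0
    train_mse, grads = _gradients(weights, Xs_train, ys_train)
    best = weights.copy()
    best_val = float(np.mean((weights.predict(Xs_val) - ys_val) ** 2))
    since_best = 0
    for _ in range(max_epochs):
        # take the steepest step that still decreases the training MSE
        accepted = False
        for _try in range(40):
            trial = weights.copy()
            trial.w1 -= lr * grads[0]
            trial.b1 -= lr * grads[1]
            trial.w2 -= lr * grads[2]
            trial.b2 -= lr * grads[3]
            new_mse, new_grads = _gradients(trial, Xs_train, ys_train)
            if np.isfinite(new_mse) and new_mse <= train_mse:
                accepted = True
                break
            lr *= 0.5
            if lr < 1e-14:
                break
        if not accepted:
            break
        weights, train_mse, grads = trial, new_mse, new_grads
        lr = min(lr * 1.1, 10.0)
        val_mse = float(np.mean((weights.predict(Xs_val) - ys_val) ** 2))
        if val_mse < best_val - 1e-12:
            best_val, best = val_mse, weights.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    return best, best_val


@dataclass
class AnnModel:
    """Trained network plus the scaling and split needed to reuse it."""

    variables: list
    weights: _Weights
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: float
    y_range: float
    train_idx: np.ndarray
    val_idx: np.ndarray
    X_scaled: np.ndarray  # full scaled design matrix used for training
    metrics: dict  # mse/R per split, in scaled response units
    seed: int

    @property
    def hidden_weights(self) -> np.ndarray:
        """Input -> hidden weight matrix w (inputs x hidden units)."""
        return self.weights.w1

    @property
    def output_weights(self) -> np.ndarray:
        """Hidden -> output weight vector e (hidden units,)."""
        return self.weights.w2

    def scale_X(self, X) -> np.ndarray:
        Xm, _ = _as_matrix(X)
        return (Xm - self.x_min) / self.x_range

    def predict_scaled(self, X_scaled) -> np.ndarray:
        return self.weights.predict(np.asarray(X_scaled, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.y_min + self.y_range * self.predict_scaled(self.scale_X(X))


def _minmax(values):
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span)
    return lo, span


def _split_metrics(weights, Xs, ys, idx):
    pred = weights.predict(Xs[idx])
    mse = float(np.mean((ys[idx] - pred) ** 2))
    if np.std(pred) == 0 or np.std(ys[idx]) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(ys[idx], pred).statistic)
    return mse, r


def train_bpann(X, y, hidden_units: int = 10, train_fraction: float = 0.8,
                seed: int = 0, n_restarts: int = 5, max_iter: int = 2000) -> AnnModel:
    """Train the 3-layer network with restarts, keeping the best
    validation MSE. Deterministic given ``seed``."""
    Xm, variables = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(Xm).all() and np.isfinite(yv).all()):
        raise DataValidationError("non-finite values in network inputs")
    n = Xm.shape[0]
    if n < 15:
        raise FitError(f"need at least 15 samples to train, got {n}")
    if not (0 < train_fraction < 1):
        raise ConfigError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if hidden_units < 1:
        raise ConfigError("hidden_units must be >= 1")

    x_min, x_range = _minmax(Xm)
    y_min, y_span = _minmax(yv.reshape(-1, 1))
    y_min, y_span = float(y_min[0]), float(y_span[0])
    Xs = (Xm - x_min) / x_range
    ys = (yv - y_min) / y_span

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx, val_idx = order[:n_train], order[n_train:]

    # Early stopping inside each run uses the validation split; restarts
    # are compared on the all-sample MSE of their early-stopped weights.
    # (Comparing on the 20% split alone lets underfit runs win on
    # validation flukes when the split is only ~10 samples.)
    best = None
    for _ in range(n_restarts):
        weights, val_mse = _train_once(
            Xs[train_idx], ys[train_idx], Xs[val_idx], ys[val_idx],
            hidden_units, rng, max_epochs=max_iter,
        )
        if not np.isfinite(val_mse):
            continue
        full_mse = float(np.mean((weights.predict(Xs) - ys) ** 2))
        if best is None or full_mse < best[0]:
            best = (full_mse, weights)
    if best is None:
        raise FitError("network training diverged on every restart")
    weights = best[1]

    train_mse, train_r = _split_metrics(weights, Xs, ys, train_idx)
    val_mse, val_r = _split_metrics(weights, Xs, ys, val_idx)
    return AnnModel(
        variables=variables, weights=weights, x_min=x_min, x_range=x_range,
        y_min=y_min, y_range=y_span, train_idx=train_idx, val_idx=val_idx,
        X_scaled=Xs,
        metrics={
            "train_mse": train_mse, "train_r": train_r,
            "val_mse": val_mse, "val_r": val_r,
            "n_train": int(n_train), "n_val": int(n - n_train),
        },
        seed=seed,
    )


def garson_sensitivity(model: AnnModel) -> pd.Series:
    """Garson contribution percentage per input; sums to 100.

    For input a: contribution_a = sum_b (|w_ab| / sum_d |w_db|) * |e_b|,
    normalized over inputs. Hidden units with all-zero incoming weights
    are skipped with a warning.
    """
    w = np.abs(model.hidden_weights)  # inputs x hidden
    e = np.abs(model.output_weights)  # hidden
    col_sums = w.sum(axis=0)
    dead = col_sums == 0
    if dead.any():
        warnings.warn(
            f"skipping {int(dead.sum())} hidden unit(s) with all-zero input weights",
            stacklevel=2,
        )
        w, e, col_sums = w[:, ~dead], e[~dead], col_sums[~dead]
    contrib = (w / col_sums) @ e
    total = contrib.sum()
    if total == 0:
        raise FitError("all connection weights are zero")
    return pd.Series(100.0 * contrib / total, index=model.variables)


def mean_impact_value(model: AnnModel, X_scaled=None, delta: float = 0.1) -> pd.Series:
    """Signed influence of each input on the (original-unit) response.

    Each scaled input column is multiplied by 1+delta and 1-delta in
    turn; MIV is the mean prediction difference over samples.
    """
    if not (0 < delta < 1):
        raise ConfigError(f"delta must lie in (0, 1), got {delta}")
    Xs = model.X_scaled if X_scaled is None else np.asarray(X_scaled, dtype=float)
    mivs = np.empty(Xs.shape[1])
    for a in range(Xs.shape[1]):
        X_hi = Xs.copy()
        X_lo = Xs.copy()
        X_hi[:, a] *= 1.0 + delta
        X_lo[:, a] *= 1.0 - delta
        diff = model.predict_scaled(X_hi) - model.predict_scaled(X_lo)
        mivs[a] = float(diff.mean()) * model.y_range
    return pd.Series(mivs, index=model.variables)


def select_by_miv(miv: pd.Series) -> list:
    """Inputs with negative MIV against IC50 (toxicity direction),
    ranked by decreasing |MIV|."""
    keep = miv[miv < 0]
    return list(keep.abs().sort_values(ascending=False).index)
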