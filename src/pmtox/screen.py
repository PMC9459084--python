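"""Untargeted differential-feature screening between raw and processed
herb batches: normalization/scaling, PCA, univariate statistics, and
the VIP / p / fold-change cascade with VIP from an OPLS-DA fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .config import ScreenConfig
from .exceptions import ConfigError, DataValidationError
from .io import GROUP_PROCESSED, GROUP_RAW, FeatureMatrix
from .opls import fit_opls


def normalize_and_scale(matrix: FeatureMatrix, normalization: str = "none",
                        scaling: str = "none") -> FeatureMatrix:
    """Sample normalization then feature scaling.

    ``total-intensity`` rescales each sample so its intensity sum
    equals the cohort median sum; scaling centres each feature and
    divides by its standard deviation (``unit-variance``) or the square
    root of it (``pareto``). Note scaled intensities are no longer
    non-negative, so the result is returned as a plain frame inside a
    lightweight wrapper bypassing the positivity check.
    """
    data = matrix.intensities.copy()
    if normalization == "total-intensity":
        sums = data.sum(axis=1)
        if (sums == 0).any():
            bad = list(sums.index[sums == 0])
            raise DataValidationError(f"all-zero samples cannot be normalized: {bad}")
        data = data.mul(sums.median() / sums, axis=0)
    elif normalization != "none":
        raise ConfigError(f"unknown normalization {normalization!r}")

    if scaling in ("unit-variance", "pareto"):
        sd = data.std(axis=0, ddof=1)
        sd = sd.where(sd > 0, 1.0)
        divisor = sd if scaling == "unit-variance" else np.sqrt(sd)
        data = (data - data.mean(axis=0)) / divisor
    elif scaling != "none":
        raise ConfigError(f"unknown scaling {scaling!r}")

    out = FeatureMatrix.__new__(FeatureMatrix)  # scaled values may be negative
    out.intensities = data
    out.groups = matrix.groups.reindex(data.index)
    out.truth = matrix.truth
    return out


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame  # features x components, orthonormal columns
    explained_variance_ratio: np.ndarray


def fit_pca(matrix: FeatureMatrix, n_components: int = 2) -> PcaResult:
    """PCA of the (already scaled) feature matrix."""
    data = matrix.intensities
    max_comp = min(data.shape[0] - 1, data.shape[1])
    if n_components > max_comp:
        raise ConfigError(
            f"n_components={n_components} exceeds min(samples-1, features)={max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data.values)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=data.index, columns=cols),
        loadings=pd.DataFrame(pca.components_.T, index=data.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def compute_univariate_stats(matrix: FeatureMatrix, log_intensities: bool = False
                             ) -> pd.DataFrame:
    """Per-feature Welch t-test p and processed/raw fold change.

    QC samples are excluded; both groups need >= 3 samples. Features
    where both groups are constant and identical get p = 1 by
    convention with ``degenerate=True``.
    """
    working = matrix.without_qc()
    raw = working.intensities.loc[working.groups == GROUP_RAW]
    proc = working.intensities.loc[working.groups == GROUP_PROCESSED]
    if len(raw) < 3 or len(proc) < 3:
        raise DataValidationError(
            f"both groups need >= 3 samples (raw {len(raw)}, processed {len(proc)})"
        )
    raw_v, proc_v = raw.values, proc.values
    test_raw, test_proc = raw_v, proc_v
    if log_intensities:
        if (raw_v <= 0).any() or (proc_v <= 0).any():
            raise DataValidationError("log transform requires positive intensities")
        test_raw, test_proc = np.log(raw_v), np.log(proc_v)
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(test_proc, test_raw, equal_var=False, axis=0)
        p = np.asarray(result.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)

    mean_raw = raw_v.mean(axis=0)
    mean_proc = proc_v.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(mean_raw > 0, mean_proc / mean_raw, np.nan)
    return pd.DataFrame(
        {"p": p, "FC": fc, "degenerate": degenerate},
        index=working.intensities.columns,
    )


def opls_da_vip(matrix: FeatureMatrix, max_orthogonal: int = 5,
                cv_folds: int = 7, fold_seed: int = 0):
    """VIP per feature from an OPLS-DA of raw vs processed samples.

    The engine standardizes features (unit-variance scaling) and uses
    one predictive plus auto-chosen orthogonal components against the
    binary class indicator.
    """
    working = matrix.without_qc()
    y = (working.groups == GROUP_PROCESSED).astype(float)
    folds = min(cv_folds, len(y))
    model = fit_opls(working.intensities, y.values, n_orthogonal="auto",
                     max_orthogonal=max_orthogonal, cv_folds=folds,
                     fold_seed=fold_seed)
    return model.vip, model


def screen_differential(stats_table: pd.DataFrame, vip_min: float = 1.5,
                        p_max: float = 0.05, fc_max: float = 0.5) -> pd.DataFrame:
    """Apply the cascade: selected iff VIP > vip_min AND p < p_max AND
    FC < fc_max (all strict)."""
    for name, value in (("vip_min", vip_min), ("p_max", p_max), ("fc_max", fc_max)):
        if not np.isfinite(value) or value <= 0:
            raise ConfigError(f"threshold {name} must be positive, got {value}")
    required = {"VIP", "p", "FC"}
    missing = required - set(stats_table.columns)
    if missing:
        raise ConfigError(f"stats table lacks columns {sorted(missing)}")
    out = stats_table.copy()
    out["selected"] = (
        (out["VIP"] > vip_min) & (out["p"] < p_max) & (out["FC"] < fc_max)
    )
    return out


def screen_matrix(matrix: FeatureMatrix, config: ScreenConfig | None = None,
                  fold_seed: int = 0) -> pd.DataFrame:
    """Full screening stage on a raw intensity matrix.

    Unit-variance scaled OPLS-DA supplies VIP; the Welch test and fold
    change are computed on unscaled intensities. Returns the stats
    table with a ``selected`` flag.
    """
    config = config or ScreenConfig()
    config.validate()
    vip, _ = opls_da_vip(matrix, fold_seed=fold_seed)
    uni = compute_univariate_stats(matrix, log_intensities=config.log_intensities)
    table = uni.assign(VIP=vip.reindex(uni.index))
    return screen_differential(table, config.vip_min, config.p_max, config.fc_max)
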