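"""OPLS engine: NIPALS-PLS equivalence, VIP normalization, Q2
cross-validation, permutation verdicts and the selection rule."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from pmtox import (
    ConfigError,
    FitError,
    cross_validate_q2,
    fit_opls,
    permutation_test,
    select_by_vip_coefficient,
    vip_scores,
)
from pmtox.datasets import panel_opls_coefficients


def _signal_data(rng, n=30, p=10, noise=0.5):
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, 0] + X[:, 1] + noise * rng.normal(size=n)
    return X, y


class TestFit:
    @pytest.mark.parametrize("n_orthogonal", [0, 1, 2, 3])
    def test_predictions_equal_nipals_pls_with_one_more_component(self, rng, n_orthogonal):
        X, y = _signal_data(rng)
        model = fit_opls(X, y, n_orthogonal=n_orthogonal, cv_folds=5)
        pls = PLSRegression(n_components=n_orthogonal + 1, scale=True).fit(X, y)
        assert np.allclose(model.predict(X), pls.predict(X).ravel(), atol=1e-8)

    def test_perfect_signal_reaches_unit_r2y(self, rng):
        # y equals the first column exactly; remaining columns are noise
        # orthogonalized against y so the single predictive component
        # carries the whole response
        X = rng.normal(size=(40, 6))
        y = X[:, 0].copy()
        yc = y - y.mean()
        for j in range(1, 6):
            X[:, j] -= yc * ((X[:, j] - X[:, j].mean()) @ yc) / (yc @ yc)
        model = fit_opls(X, y, n_orthogonal=0, cv_folds=5)
        assert model.r2y == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        X, y = _signal_data(rng)
        model = fit_opls(X, y, n_orthogonal=3, cv_folds=5)
        for a in range(model.n_orthogonal):
            assert abs(np.corrcoef(model.t_orth[:, a], y)[0, 1]) < 1e-10

    def test_deflation_conserves_x_variance(self, rng):
        X, y = _signal_data(rng)
        model = fit_opls(X, y, n_orthogonal=2, cv_folds=5)
        Xs = (X - model.x_mean) / model.x_sd
        recon = np.outer(model.t, model.p_load)
        for a in range(model.n_orthogonal):
            recon += np.outer(model.t_orth[:, a], model.p_orth[:, a])
        residual = ((Xs - recon) ** 2).sum() / (Xs ** 2).sum()
        assert model.r2x + residual == pytest.approx(1.0, abs=1e-8)

    def test_constant_response_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(FitError):
            fit_opls(X, np.ones(10), n_orthogonal=0, cv_folds=5)

    def test_constant_variable_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        with pytest.raises(FitError):
            fit_opls(X, rng.normal(size=10), n_orthogonal=0, cv_folds=5)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(FitError):
            fit_opls(X, rng.normal(size=6), n_orthogonal=4, cv_folds=2)


class TestVip:
    def test_mean_squared_vip_is_one(self, rng):
        X, y = _signal_data(rng, p=12)
        model = fit_opls(X, y, n_orthogonal=1, cv_folds=5)
        assert (vip_scores(model) ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_single_variable_vip_is_one(self, rng):
        X = rng.normal(size=(20, 1))
        y = 2.0 * X[:, 0] + 0.1 * rng.normal(size=20)
        model = fit_opls(X, y, n_orthogonal=0, cv_folds=5)
        assert vip_scores(model).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_variable_vip_ratio_follows_weights(self, rng):
        # hand evaluation: with one predictive component and unit-norm
        # weights (w1, w2), VIP_j = sqrt(2) |w_j|
        X = rng.normal(size=(50, 2))
        y = 3.0 * X[:, 0] + 1.0 * X[:, 1]
        model = fit_opls(X, y, n_orthogonal=0, cv_folds=5)
        vip = vip_scores(model)
        assert vip.iloc[0] / vip.iloc[1] == pytest.approx(
            abs(model.w[0]) / abs(model.w[1]), rel=1e-10
        )
        assert np.allclose(vip.values, np.sqrt(2) * np.abs(model.w))


class TestCrossValidation:
    def test_deterministic_given_fold_seed(self, rng):
        X, y = _signal_data(rng)
        q2a = cross_validate_q2(X, y, folds=7, n_orthogonal=1, fold_seed=5)
        q2b = cross_validate_q2(X, y, folds=7, n_orthogonal=1, fold_seed=5)
        assert q2a == q2b

    def test_pure_noise_median_q2_nonpositive(self):
        q2s = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(25, 8))
            y = r.normal(size=25)
            q2s.append(cross_validate_q2(X, y, folds=5, n_orthogonal=0, fold_seed=seed))
        assert np.median(q2s) <= 0.0

    def test_strong_signal_gives_high_q2(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(50, 8))
            signal = X[:, 0] * 2 + X[:, 1]
            y = signal + r.normal(size=50) * signal.std() / 3.0  # R2 = 0.9
            hits += cross_validate_q2(X, y, folds=7, n_orthogonal=0, fold_seed=seed) > 0.5
        assert hits >= 95

    def test_too_many_folds_rejected(self, rng):
        X, y = _signal_data(rng, n=6)
        with pytest.raises(ConfigError):
            cross_validate_q2(X, y, folds=10)


class TestPermutation:
    def test_row_counts_and_original_first(self, rng):
        X, y = _signal_data(rng)
        result = permutation_test(X, y, n_permutations=30, seed=1)
        assert len(result.permuted) == 30
        assert result.original["correlation"] == 1.0

    def test_planted_signal_passes(self, rng):
        X, y = _signal_data(rng, n=50, noise=0.8)
        assert permutation_test(X, y, n_permutations=100, seed=0).passed

    def test_pure_noise_fails(self, rng):
        X = rng.normal(size=(50, 10))
        y = rng.normal(size=50)
        assert not permutation_test(X, y, n_permutations=100, seed=0).passed

    def test_few_permutations_warn(self, rng):
        X, y = _signal_data(rng)
        with pytest.warns(UserWarning):
            permutation_test(X, y, n_permutations=10, seed=0)


class TestSelectionRule:
    def test_reported_coefficients_reproduce_printed_sets(self):
        coefs = panel_opls_coefficients()
        vip = pd.Series(1.0, index=coefs.index)  # all VIP > 0.7 as reported
        l02 = select_by_vip_coefficient(vip, coefs["L02"], vip_min=0.7, coef_max=-0.1)
        hepg2 = select_by_vip_coefficient(vip, coefs["HepG2"], vip_min=0.7, coef_max=-0.1)
        assert set(l02) == {"X2", "X5", "X6", "X7", "X9", "X10", "X11", "X14", "X16"}
        assert set(hepg2) == {"X4", "X5", "X6", "X7", "X9", "X10", "X14", "X15", "X16"}

    def test_all_positive_coefficients_select_nothing(self):
        vip = pd.Series([2.0, 1.5], index=["a", "b"])
        coef = pd.Series([0.3, 0.2], index=["a", "b"])
        assert select_by_vip_coefficient(vip, coef) == []

    def test_selection_invariant_to_reordering(self, rng):
        X, y = _signal_data(rng, p=8)
        frame = pd.DataFrame(X, columns=[f"X{j+1}" for j in range(8)])
        model = fit_opls(frame, y, n_orthogonal=1, cv_folds=5)
        base = set(select_by_vip_coefficient(model))
        order = rng.permutation(8)
        shuffled = frame.iloc[:, order]
        model2 = fit_opls(shuffled, y, n_orthogonal=1, cv_folds=5)
        assert set(select_by_vip_coefficient(model2)) == base
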