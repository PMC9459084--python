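"""Normalization/scaling, PCA, univariate statistics and the
VIP / p / FC screening cascade."""

import numpy as np
import pandas as pd
import pytest

from pmtox import (
    ConfigError,
    DataValidationError,
    FeatureMatrix,
    compute_univariate_stats,
    fit_pca,
    generate_metabolomics_matrix,
    normalize_and_scale,
    screen_differential,
    screen_matrix,
)
from pmtox.datasets import panel_screen_stats


def _matrix(values, groups):
    frame = pd.DataFrame(values, index=[f"s{i}" for i in range(len(values))])
    frame.columns = [f"f{j}" for j in range(frame.shape[1])]
    return FeatureMatrix(frame, pd.Series(groups, index=frame.index))


class TestNormalizeAndScale:
    def test_identity_when_disabled(self, rng):
        matrix = generate_metabolomics_matrix(n_features=8, n_differential=2,
                                              groups=(4, 4, 2), seed=1)
        out = normalize_and_scale(matrix, "none", "none")
        assert np.array_equal(out.intensities.values, matrix.intensities.values)

    def test_unit_variance_scaling(self):
        matrix = generate_metabolomics_matrix(n_features=6, n_differential=0,
                                              groups=(5, 5, 0), seed=2)
        out = normalize_and_scale(matrix, "none", "unit-variance")
        assert np.allclose(out.intensities.std(axis=0, ddof=1), 1.0)
        assert np.allclose(out.intensities.mean(axis=0), 0.0, atol=1e-12)

    def test_pareto_scaling_halves_a_sd_of_four(self):
        values = np.tile([[1.0], [5.0], [9.0]], (1, 1))  # sd = 4
        matrix = _matrix(values, ["raw", "raw", "processed"])
        out = normalize_and_scale(matrix, "none", "pareto")
        assert out.intensities.std(axis=0, ddof=1).iloc[0] == pytest.approx(2.0)

    def test_total_intensity_equalizes_sample_sums(self):
        matrix = generate_metabolomics_matrix(n_features=10, n_differential=3,
                                              groups=(4, 4, 0), seed=3)
        out = normalize_and_scale(matrix, "total-intensity", "none")
        sums = out.intensities.sum(axis=1)
        assert np.allclose(sums, sums.iloc[0])

    def test_all_zero_sample_rejected(self):
        matrix = _matrix([[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]],
                         ["raw", "raw", "processed"])
        with pytest.raises(DataValidationError):
            normalize_and_scale(matrix, "total-intensity", "none")


class TestPca:
    def test_loadings_orthonormal(self):
        matrix = generate_metabolomics_matrix(n_features=20, n_differential=5,
                                              groups=(8, 8, 3), seed=4)
        scaled = normalize_and_scale(matrix, "none", "unit-variance")
        result = fit_pca(scaled, n_components=3)
        gram = result.loadings.values.T @ result.loadings.values
        assert np.allclose(gram, np.eye(3), atol=1e-10)
        assert np.all(np.diff(result.explained_variance_ratio) <= 1e-12)

    def test_rank_one_data_explained_by_first_component(self, rng):
        scores = rng.normal(size=12)
        direction = rng.normal(size=5)
        values = np.abs(np.outer(scores, direction)) + 1.0
        matrix = _matrix(values, ["raw"] * 6 + ["processed"] * 6)
        centered = normalize_and_scale(matrix, "none", "none")
        centered.intensities -= centered.intensities.mean(axis=0)
        result = fit_pca(centered, n_components=1)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_component_budget_enforced(self):
        matrix = generate_metabolomics_matrix(n_features=5, n_differential=0,
                                              groups=(3, 3, 0), seed=5)
        with pytest.raises(ConfigError):
            fit_pca(matrix, n_components=6)

    def test_qc_replicates_cluster_tighter_than_groups(self):
        matrix = generate_metabolomics_matrix(n_features=80, n_differential=20,
                                              groups=(10, 10, 6), qc_cv=0.01, seed=6)
        scaled = normalize_and_scale(matrix, "total-intensity", "unit-variance")
        result = fit_pca(scaled, n_components=2)
        scores = result.scores
        qc = scores[matrix.groups == "QC"].values
        raw = scores[matrix.groups == "raw"].values
        proc = scores[matrix.groups == "processed"].values
        within_qc = np.mean(
            [np.linalg.norm(a - b) for i, a in enumerate(qc) for b in qc[i + 1:]]
        )
        between = np.mean([np.linalg.norm(a - b) for a in raw for b in proc])
        assert within_qc < between


class TestUnivariateStats:
    def test_identical_groups_have_unit_fc_and_degenerate_p(self):
        values = np.tile([[2.0, 3.0]], (6, 1))
        matrix = _matrix(values, ["raw"] * 3 + ["processed"] * 3)
        stats = compute_univariate_stats(matrix)
        assert np.allclose(stats["FC"], 1.0)
        assert np.allclose(stats["p"], 1.0)
        assert stats["degenerate"].all()

    def test_fc_is_direct_mean_ratio(self):
        raw = np.full((3, 1), 10.0)
        proc = np.full((3, 1), 2.86)
        matrix = _matrix(np.vstack([raw, proc]), ["raw"] * 3 + ["processed"] * 3)
        stats = compute_univariate_stats(matrix)
        assert stats["FC"].iloc[0] == pytest.approx(0.286)

    def test_qc_samples_excluded(self):
        values = np.vstack([np.full((3, 1), 10.0), np.full((3, 1), 5.0),
                            np.full((2, 1), 1000.0)])
        matrix = _matrix(values, ["raw"] * 3 + ["processed"] * 3 + ["QC"] * 2)
        stats = compute_univariate_stats(matrix)
        assert stats["FC"].iloc[0] == pytest.approx(0.5)

    def test_planted_fc_estimated_consistently(self):
        # FC 0.25 at 20% CV with 23 vs 23 samples: the estimated FC
        # distribution concentrates near the truth
        medians = []
        for seed in range(200):
            matrix = generate_metabolomics_matrix(
                n_features=5, n_differential=5, groups=(23, 23, 0),
                fc_range=(0.25, 0.25), seed=seed,
            )
            stats = compute_univariate_stats(matrix)
            medians.append(stats["FC"].median())
        assert 0.2 <= float(np.median(medians)) <= 0.3

    def test_small_groups_rejected(self):
        matrix = _matrix(np.ones((4, 2)), ["raw", "raw", "processed", "processed"])
        with pytest.raises(DataValidationError):
            compute_univariate_stats(matrix)


class TestScreeningCascade:
    def test_reported_catechin_row_is_selected(self):
        stats = panel_screen_stats().rename(columns={})
        out = screen_differential(stats, vip_min=1.5, p_max=0.05, fc_max=0.5)
        assert bool(out.loc["X1", "selected"])  # VIP 11.03, p 1.5e-6, FC 0.286

    def test_boundaries_are_strict(self):
        stats = pd.DataFrame({
            "VIP": [1.5, 3.0], "p": [0.001, 0.001], "FC": [0.3, 1.4],
        }, index=["at_vip_boundary", "fc_too_high"])
        out = screen_differential(stats)
        assert not out["selected"].any()

    def test_nonpositive_threshold_rejected(self):
        stats = pd.DataFrame({"VIP": [2.0], "p": [0.01], "FC": [0.3]})
        with pytest.raises(ConfigError):
            screen_differential(stats, vip_min=0.0)

    def test_screening_is_monotone_in_thresholds(self):
        matrix = generate_metabolomics_matrix(n_features=60, n_differential=10,
                                              groups=(10, 10, 0), seed=9)
        tight = screen_matrix(matrix, fold_seed=9)
        relaxed = screen_differential(tight, vip_min=1.0, p_max=0.2, fc_max=0.7)
        assert set(tight.index[tight["selected"]]) <= set(
            relaxed.index[relaxed["selected"]]
        )

    def test_null_matrix_yields_no_selections(self):
        # without planted differential features the FC < 0.5 gate alone
        # should stop everything at these group sizes
        false_positives = 0
        for seed in range(20):
            matrix = generate_metabolomics_matrix(n_features=50, n_differential=0,
                                                  groups=(23, 23, 0), seed=seed)
            out = screen_matrix(matrix, fold_seed=seed)
            false_positives += int(out["selected"].sum())
        assert false_positives == 0
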