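"""Seeded study-scale experiments over the synthetic cohorts.

Each function reruns a pipeline stage across many seeded replicates
and summarizes how well the stage recovers the planted ground truth.
They back the analysis drivers and the acceptance evaluation, and are
deterministic given their base seed (replicate seeds are derived from
it, kept below 2**31).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_CONCENTRATION_GRID
from .dose_response import fit_four_pl, four_pl, inhibition_ratio
from .opls import permutation_test
from .pipeline import run_pipeline
from .screen import screen_matrix
from .synthetic import default_cohort_spec, generate_metabolomics_matrix, generate_quant_cohort


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def marker_recovery_experiment(n_runs: int = 50, seed: int = 0) -> dict:
    """Full-pipeline consensus vs the planted markers over seeded cohorts.

    Returns the exact-recovery rate plus marker sensitivity and the
    false-inclusion count, with per-run detail.
    """
    rows = []
    for run_seed in _derive_seeds(seed, n_runs):
        run_seed = int(run_seed)
        cohort = generate_quant_cohort(default_cohort_spec(run_seed))
        result = run_pipeline(cohort.quant, cohort.true_ic50, seed=run_seed)
        got, truth = set(result.consensus.final), set(cohort.truth)
        rows.append({
            "seed": run_seed,
            "exact": got == truth,
            "n_markers_found": len(got & truth),
            "n_false": len(got - truth),
            "consensus": ",".join(sorted(got)),
        })
    detail = pd.DataFrame(rows)
    return {
        "recovery_rate": float(detail["exact"].mean()),
        "marker_sensitivity": float(detail["n_markers_found"].mean() / 3.0),
        "mean_false_inclusions": float(detail["n_false"].mean()),
        "n_runs": n_runs,
        "detail": detail,
    }


def screening_experiment(n_runs: int = 50, seed: int = 0, **matrix_kwargs) -> dict:
    """Sensitivity and false-discovery proportion of the VIP/p/FC
    cascade on matrices with planted differential features."""
    rows = []
    for run_seed in _derive_seeds(seed, n_runs):
        run_seed = int(run_seed)
        matrix = generate_metabolomics_matrix(seed=run_seed, **matrix_kwargs)
        table = screen_matrix(matrix, fold_seed=run_seed)
        selected = table["selected"]
        truth = matrix.truth.reindex(table.index)
        tp = int((selected & truth).sum())
        fp = int((selected & ~truth).sum())
        rows.append({
            "seed": run_seed,
            "sensitivity": tp / max(int(truth.sum()), 1),
            "fdp": fp / max(int(selected.sum()), 1),
            "n_selected": int(selected.sum()),
        })
    detail = pd.DataFrame(rows)
    return {
        "sensitivity": float(detail["sensitivity"].mean()),
        "fdp": float(detail["fdp"].mean()),
        "n_runs": n_runs,
        "detail": detail,
    }


def ic50_refit_experiment(n_plates: int = 100, od_noise_sd: float = 0.02,
                          seed: int = 0, hill: float = 1.0,
                          grid=DEFAULT_CONCENTRATION_GRID,
                          od_nc: float = 1.4, od_stsp: float = 0.2) -> dict:
    """Median relative IC50 error of the 4PL refit on noisy plates.

    True IC50s are drawn log-uniformly over the grid's informative
    span (second to second-last concentration), where the seven-point
    design brackets the transition.
    """
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    true_ic50 = 10.0 ** rng.uniform(np.log10(grid[1]), np.log10(grid[-2]), n_plates)
    errors = []
    for ic in true_ic50:
        inh = four_pl(grid, 0.0, 100.0, ic, hill)
        od = od_nc + inh / 100.0 * (od_stsp - od_nc)
        od = od + rng.normal(0.0, od_noise_sd, size=grid.size)
        observed = inhibition_ratio(od, od_nc, od_stsp)
        fit = fit_four_pl(grid, observed)
        errors.append(abs(fit.ic50 - ic) / ic)
    errors = np.asarray(errors)
    return {
        "median_rel_error": float(np.median(errors)),
        "q90_rel_error": float(np.quantile(errors, 0.9)),
        "n_plates": n_plates,
        "od_noise_sd": od_noise_sd,
    }


def permutation_calibration_experiment(n_runs: int = 50, seed: int = 0,
                                       n_samples: int = 50, n_vars: int = 10,
                                       signal_r2: float = 0.6,
                                       n_permutations: int = 200) -> dict:
    """Verdict rates of the permutation test on planted-signal vs
    pure-noise responses."""
    seeds = _derive_seeds(seed, n_runs)
    signal_pass = noise_fail = 0
    beta = np.zeros(n_vars)
    beta[:3] = [1.0, 0.8, 0.6]
    for run_seed in seeds:
        rng = np.random.default_rng(int(run_seed))
        X = rng.normal(size=(n_samples, n_vars))
        signal = X @ beta
        noise_sd = signal.std() * np.sqrt(1.0 / signal_r2 - 1.0)
        y = signal + rng.normal(size=n_samples) * noise_sd
        verdict = permutation_test(X, y, n_permutations=n_permutations,
                                   seed=int(run_seed))
        signal_pass += verdict.passed
        y_noise = rng.normal(size=n_samples)
        verdict = permutation_test(X, y_noise, n_permutations=n_permutations,
                                   seed=int(run_seed))
        noise_fail += not verdict.passed
    return {
        "signal_pass_rate": signal_pass / n_runs,
        "noise_fail_rate": noise_fail / n_runs,
        "n_runs": n_runs,
    }


def group_separation_experiment(n_runs: int = 50, seed: int = 0,
                                alpha: float = 1e-4) -> dict:
    """How often the raw-vs-processed IC50 difference reaches the
    reported significance level on default synthetic cohorts."""
    from .dose_response import compare_groups

    hits = 0
    rows = []
    for run_seed in _derive_seeds(seed, n_runs):
        cohort = generate_quant_cohort(default_cohort_spec(int(run_seed)))
        comparison = compare_groups(cohort.true_ic50, cohort.quant.groups)
        significant = bool((comparison["welch_p"] < alpha).all())
        hits += significant
        rows.append(comparison.assign(seed=int(run_seed)))
    return {
        "significant_rate": hits / n_runs,
        "n_runs": n_runs,
        "detail": pd.concat(rows),
    }
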