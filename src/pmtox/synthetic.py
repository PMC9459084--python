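"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a raw-vs-processed herbal cohort profiled by a
semiquantitative MRM panel and assayed for hepatocytotoxicity:

* peak areas are log-normal per compound (positive, right-skewed),
  with a compound-specific processing reduction factor applied to the
  processed batches;
* compound draws are independent across the panel by default; an
  optional batch-level co-regulation factor can correlate the planted
  markers to emulate a shared biosynthetic pathway;
* hepatocyte potency acts additively on the 1/IC50 scale:
  1/IC50 = (baseline + sum_j beta_j * area_j) * exp(eps), with beta
  nonzero only on the planted markers and eps Gaussian on the log
  scale (multiplicative assay noise keeps potency positive without
  truncation artifacts); IC50 is the reciprocal;
* dose-response plates carry a negative (vehicle) and a full-kill
  control and seven-point sample wells whose noise-free inhibition
  follows a four-parameter logistic centred at the batch's true IC50;
* untargeted feature matrices plant differential features whose
  processed-group mean is the raw mean times a fold change, plus tight
  QC replicates of the grand mean.

Default sizes and effects follow the study conditions: 30 raw + 20
processed batches, a 16-compound panel with markers X6/X7/X14,
processing fold changes in [0.137, 0.441], cohort mean IC50s of
250/735 ug/ml (L02, raw/processed) and 281/1185 ug/ml (HepG2), and a
noise level leaving the compound panel ~80% of the potency variance
(matching the reported spectrum-effect model fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_CONCENTRATION_GRID
from .dose_response import four_pl
from .exceptions import ConfigError
from .io import GROUP_PROCESSED, GROUP_QC, GROUP_RAW, FeatureMatrix, QuantTable, ToxicityTable

#: geometric coefficient of variation of batch-to-batch peak areas
DEFAULT_GEOMETRIC_CV = 0.4
#: share of planted-marker log-variance carried by a common batch
#: factor; 0 = independent compound draws (the default generative
#: model), raise to emulate co-regulated marker pathways
DEFAULT_COREGULATION_SHARE = 0.0
#: CV of the multiplicative potency noise (calibrated so the cohort
#: OPLS fit of IC50 on the panel reaches R2Y ~ 0.8, the reported level)
DEFAULT_NOISE_CV = 0.15
#: processing reduction range of the planted markers (processed/raw)
DEFAULT_REDUCTION_RANGE = (0.137, 0.441)
#: cohort mean IC50 targets (ug/ml) used to calibrate baseline and beta
DEFAULT_MEAN_IC50 = {
    "L02": {"raw": 250.0, "processed": 735.0},
    "HepG2": {"raw": 281.0, "processed": 1185.0},
}
DEFAULT_PLANTED = (6, 7, 14)  # 1-based panel positions of the toxic markers

_POTENCY_FLOOR = 1e-6  # 1/IC50 truncation keeping IC50 finite


@dataclass
class CellLineEffect:
    """Latent potency model of one hepatocyte line."""

    baseline_inverse_ic50: float  # 1/(ug/ml)
    toxicity_coefficients: np.ndarray  # per-compound beta, >= 0

    def validate(self, n_compounds, planted_mask):
        beta = np.asarray(self.toxicity_coefficients, dtype=float)
        if beta.shape != (n_compounds,):
            raise ConfigError("toxicity_coefficients must have one entry per compound")
        if (beta < 0).any():
            raise ConfigError("toxicity_coefficients must be non-negative")
        if (beta[~planted_mask] != 0).any():
            raise ConfigError("beta must be zero outside the planted set")
        self.toxicity_coefficients = beta


@dataclass
class CohortSpec:
    """Full description of a synthetic quantification + toxicity cohort."""

    n_raw: int = 30
    n_processed: int = 20
    n_compounds: int = 16
    planted_toxic: tuple = DEFAULT_PLANTED  # 1-based compound indices
    reduction_factors: np.ndarray | None = None  # per-compound, in (0, 1]
    compound_medians: np.ndarray | None = None  # peak-area scale per compound
    cell_lines: dict = field(default_factory=dict)  # name -> CellLineEffect
    geometric_cv: float = DEFAULT_GEOMETRIC_CV
    coregulation_share: float = DEFAULT_COREGULATION_SHARE
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_raw < 1 or self.n_processed < 1 or self.n_compounds < 1:
            raise ConfigError("cohort sizes must be positive")
        planted = tuple(int(i) for i in self.planted_toxic)
        if any(i < 1 or i > self.n_compounds for i in planted):
            raise ConfigError(
                f"planted_toxic {planted} outside 1..{self.n_compounds}"
            )
        self.planted_toxic = planted
        if self.reduction_factors is not None:
            rf = np.asarray(self.reduction_factors, dtype=float)
            if rf.shape != (self.n_compounds,):
                raise ConfigError("reduction_factors must have one entry per compound")
            if (rf <= 0).any() or (rf > 1).any():
                raise ConfigError("reduction_factors must lie in (0, 1]")
            self.reduction_factors = rf
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if not (0 <= self.coregulation_share < 1):
            raise ConfigError("coregulation_share must lie in [0, 1)")
        if self.geometric_cv <= 0:
            raise ConfigError("geometric_cv must be positive")
        mask = self.planted_mask
        for effect in self.cell_lines.values():
            effect.validate(self.n_compounds, mask)
        return self

    @property
    def planted_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_compounds, dtype=bool)
        mask[[i - 1 for i in self.planted_toxic]] = True
        return mask

    @property
    def compound_names(self) -> list:
        return [f"X{j + 1}" for j in range(self.n_compounds)]

    @property
    def planted_names(self) -> tuple:
        return tuple(f"X{i}" for i in self.planted_toxic)


def default_cohort_spec(seed: int = 0, noise_cv: float = DEFAULT_NOISE_CV,
                        mean_ic50: dict | None = None) -> CohortSpec:
    """Build the default study-condition spec, calibrating baseline and
    beta per cell line so the cohort group-mean potencies match the
    target mean IC50s, with equal potency share per planted marker."""
    mean_ic50 = mean_ic50 or DEFAULT_MEAN_IC50
    rng = np.random.default_rng(seed)
    spec = CohortSpec(seed=seed, noise_cv=noise_cv)

    medians = 10.0 ** rng.uniform(4, 6, size=spec.n_compounds)
    reduction = np.ones(spec.n_compounds)
    mask = spec.planted_mask
    reduction[mask] = rng.uniform(*DEFAULT_REDUCTION_RANGE, size=mask.sum())
    spec.compound_medians = medians
    spec.reduction_factors = reduction

    sigma2 = np.log1p(spec.geometric_cv ** 2)
    expected_area = medians * np.exp(sigma2 / 2.0)
    planted = np.flatnonzero(mask)
    r = reduction[planted]
    kappa = float(r.mean())
    # log-scale correlation of the planted markers -> area covariance
    # factors c_jk = cov(A_j, A_k) / (E[A_j] E[A_k])
    phi = spec.coregulation_share
    corr_log = np.full((len(planted), len(planted)), phi)
    np.fill_diagonal(corr_log, 1.0)
    cfac = np.exp(corr_log * sigma2) - 1.0

    noise_factor = 1.0 + noise_cv ** 2  # E[exp(-eps)] of the potency noise
    for cell_line, targets in mean_ic50.items():
        # Solve for baseline alpha and total marker potency S so the
        # *arithmetic mean IC50* per group matches the target, using
        # E[1/X] ~ (1/E[X]) (1 + cv^2) for the deterministic potency.
        mu_raw = 1.0 / targets["raw"]
        mu_proc = 1.0 / targets["processed"]
        for _ in range(20):
            total = (mu_raw - mu_proc) / (1.0 - kappa)
            share = total / len(planted)  # equal potency share per marker
            var_raw = share ** 2 * cfac.sum()
            var_proc = share ** 2 * float((np.outer(r, r) * cfac).sum())
            mu_raw = noise_factor * (1.0 + var_raw / mu_raw ** 2) / targets["raw"]
            mu_proc = noise_factor * (1.0 + var_proc / mu_proc ** 2) / targets["processed"]
        total = (mu_raw - mu_proc) / (1.0 - kappa)
        baseline = mu_raw - total
        beta = np.zeros(spec.n_compounds)
        beta[mask] = (total / len(planted)) / expected_area[mask]
        spec.cell_lines[cell_line] = CellLineEffect(baseline, beta)
    return spec.validate()


@dataclass
class SyntheticCohort:
    """Generated quantification table, true toxicity and ground truth."""

    quant: QuantTable
    true_ic50: ToxicityTable
    truth: tuple  # planted compound names
    spec: CohortSpec
    seed: int


def generate_quant_cohort(spec: CohortSpec | None = None, seed: int | None = None
                          ) -> SyntheticCohort:
    """Draw a cohort from a spec (default spec when omitted)."""
    if spec is None:
        spec = default_cohort_spec(seed if seed is not None else 0)
    spec.validate()
    if seed is None:
        seed = spec.seed
    if spec.compound_medians is None or spec.reduction_factors is None or not spec.cell_lines:
        raise ConfigError(
            "spec needs compound_medians, reduction_factors and cell_lines; "
            "use default_cohort_spec() to fill them"
        )
    rng = np.random.default_rng(seed)
    n = spec.n_raw + spec.n_processed
    p = spec.n_compounds
    mask = spec.planted_mask

    sigma = np.sqrt(np.log1p(spec.geometric_cv ** 2))
    share = np.where(mask, spec.coregulation_share, 0.0)
    g = rng.standard_normal(n)  # common batch factor of the marker pathway
    z = rng.standard_normal((n, p))
    log_dev = sigma * (np.sqrt(share) * g[:, None] + np.sqrt(1.0 - share) * z)
    areas = spec.compound_medians * np.exp(log_dev)
    is_processed = np.arange(n) >= spec.n_raw
    areas[is_processed] *= spec.reduction_factors

    batches = [f"S{i + 1}" for i in range(spec.n_raw)] + [
        f"Z{i + 1}" for i in range(spec.n_processed)
    ]
    groups = pd.Series(
        [GROUP_RAW] * spec.n_raw + [GROUP_PROCESSED] * spec.n_processed,
        index=batches,
    )
    quant = QuantTable(
        pd.DataFrame(areas, index=batches, columns=spec.compound_names), groups
    )

    rows = []
    for cell_line, effect in spec.cell_lines.items():
        deterministic = effect.baseline_inverse_ic50 + areas @ effect.toxicity_coefficients
        if spec.noise_cv > 0:
            # multiplicative assay noise with the requested CV, mean 1
            s = np.sqrt(np.log1p(spec.noise_cv ** 2))
            potency = deterministic * np.exp(
                rng.normal(0.0, s, size=n) - s ** 2 / 2.0
            )
        else:
            potency = deterministic.copy()
        potency = np.maximum(potency, _POTENCY_FLOOR)
        for batch, pot in zip(batches, potency):
            rows.append({"batch": batch, "cell_line": cell_line,
                         "ic50": 1.0 / pot, "censored": False})
    toxicity = ToxicityTable(pd.DataFrame(rows))
    return SyntheticCohort(quant=quant, true_ic50=toxicity,
                           truth=spec.planted_names, spec=spec, seed=seed)


def generate_dose_response_plates(cohort: SyntheticCohort,
                                  grid=DEFAULT_CONCENTRATION_GRID,
                                  hill_slope: float = 1.0,
                                  od_noise_sd: float = 0.02,
                                  n_replicates: int = 3,
                                  od_nc: float = 1.4, od_stsp: float = 0.2,
                                  seed: int | None = None) -> pd.DataFrame:
    """Emit a long-format plate table for every batch and cell line.

    Noise-free sample wells satisfy inhibition(c) = 4PL(c; 0, 100,
    true IC50, hill); Gaussian OD noise is added to every well.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ConfigError("grid must be strictly increasing and positive")
    if hill_slope <= 0:
        raise ConfigError("hill_slope must be positive")
    if od_noise_sd < 0:
        raise ConfigError("od_noise_sd must be >= 0")
    rng = np.random.default_rng(cohort.seed + 1 if seed is None else seed)

    rows = []
    span = od_stsp - od_nc
    tox = cohort.true_ic50.data
    for _, entry in tox.iterrows():
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, od_noise_sd, size=grid.size + 2) \
                if od_noise_sd > 0 else np.zeros(grid.size + 2)
            rows.append({"batch": entry["batch"], "cell_line": entry["cell_line"],
                         "replicate": rep, "role": "NC", "concentration": np.nan,
                         "OD": max(od_nc + noise[0], 1e-6)})
            rows.append({"batch": entry["batch"], "cell_line": entry["cell_line"],
                         "replicate": rep, "role": "STSP", "concentration": np.nan,
                         "OD": max(od_stsp + noise[1], 1e-6)})
            inh = four_pl(grid, 0.0, 100.0, entry["ic50"], hill_slope)
            od_sample = np.maximum(od_nc + inh / 100.0 * span + noise[2:], 1e-6)
            for conc, od in zip(grid, od_sample):
                rows.append({"batch": entry["batch"],
                             "cell_line": entry["cell_line"], "replicate": rep,
                             "role": "sample", "concentration": conc, "OD": od})
    return pd.DataFrame(rows)


def generate_metabolomics_matrix(n_features: int = 300, n_differential: int = 40,
                                 groups=(23, 23, 8),
                                 fc_range=DEFAULT_REDUCTION_RANGE,
                                 feature_cv: float = 0.2, qc_cv: float = 0.05,
                                 seed: int = 0) -> FeatureMatrix:
    """Untargeted intensity matrix with planted differential features.

    ``groups`` = (n raw, n processed, n QC). Differential features get
    processed mean = raw mean x FC with FC drawn from ``fc_range``; QC
    samples replicate the grand mean with a small CV. The returned
    matrix carries per-feature truth flags.
    """
    if n_differential > n_features:
        raise ConfigError("n_differential cannot exceed n_features")
    lo, hi = fc_range
    if not (0 < lo < 1 and 0 < hi < 1 and lo <= hi):
        raise ConfigError(f"fc_range must lie inside (0, 1), got {fc_range}")
    n_raw, n_proc, n_qc = groups
    rng = np.random.default_rng(seed)

    base = 10.0 ** rng.uniform(3, 6, size=n_features)
    rt = rng.uniform(1.0, 45.0, size=n_features)
    mz = rng.uniform(100.0, 1000.0, size=n_features)
    features = [f"{r:.2f}_{m:.4f}" for r, m in zip(rt, mz)]
    if len(set(features)) < n_features:  # vanishingly unlikely collision
        features = [f"{f}_{i}" for i, f in enumerate(features)]

    diff_idx = rng.choice(n_features, size=n_differential, replace=False)
    fc = np.ones(n_features)
    fc[diff_idx] = rng.uniform(lo, hi, size=n_differential)

    sigma = np.sqrt(np.log1p(feature_cv ** 2))
    sigma_qc = np.sqrt(np.log1p(qc_cv ** 2))

    def draw(mean_vec, n_samples, s):
        ln = np.log(mean_vec) - s ** 2 / 2.0
        return np.exp(ln + s * rng.standard_normal((n_samples, n_features)))

    raw = draw(base, n_raw, sigma)
    proc = draw(base * fc, n_proc, sigma)
    grand = (n_raw * base + n_proc * base * fc) / (n_raw + n_proc)
    qc = draw(grand, n_qc, sigma_qc)

    samples = ([f"S{i + 1}" for i in range(n_raw)]
               + [f"Z{i + 1}" for i in range(n_proc)]
               + [f"QC{i + 1}" for i in range(n_qc)])
    labels = [GROUP_RAW] * n_raw + [GROUP_PROCESSED] * n_proc + [GROUP_QC] * n_qc
    frame = pd.DataFrame(np.vstack([raw, proc, qc]), index=samples, columns=features)
    truth = pd.Series(False, index=features)
    truth.iloc[diff_idx] = True
    return FeatureMatrix(frame, pd.Series(labels, index=samples), truth=truth)
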