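# Methods and design notes

## The analysis in one paragraph

Fifty herb batches (30 raw, 20 processed) are profiled on a
16-compound semiquantitative MRM panel and assayed for cytotoxicity on
two hepatocyte lines (L02, HepG2). Three models relate per-compound
peak areas to toxicity: gray relational analysis against the potency
series 1/IC50, single-response OPLS of IC50 on the standardized areas,
and a 16–10–1 back-propagation network read out via Garson weights and
mean impact values. Each model nominates toxicity-associated
compounds; the final markers are the compounds every model nominates
in both cell lines. Upstream of this sit the untargeted differential
screen that defined the panel (VIP/p/FC cascade) and the plate-level
IC50 estimation.

## Engines

### Gray relational analysis

Series are made dimensionless (default: division by the series mean,
which preserves profile shape for strictly positive data; min–max and
initial-value transforms are available). With Δᵢ(k) = |x₀(k) − xᵢ(k)|
and global (two-level) extrema Δmin, Δmax over all comparison series,
Deng's coefficient is ξᵢ(k) = (Δmin + ρΔmax)/(Δᵢ(k) + ρΔmax) and the
relational degree is its mean over batches. ρ defaults to 0.5, the
universal convention; degrees are monotone increasing in ρ. The
selection threshold (degree > 0.6) is a convention recorded in the
configuration — on the published panel it retains all 16 compounds, so
GRA constrains the consensus only on datasets with genuinely
unrelated series.

### OPLS

The engine standardizes X and y, then alternates: compute the
predictive weight w ∝ Xᵀy, extract the loading component orthogonal to
w, deflate X by it, repeat for k orthogonal components, and finally
fit one predictive PLS component on the filtered matrix. Orthogonal
scores have exactly zero sample covariance with y by construction, and
the fitted values equal those of a (k+1)-component NIPALS PLS — the
independent oracle used in the tests (tolerance 1e-8). With one
predictive component, VIP_j = √p·|w_j| (mean squared VIP exactly 1)
and the standardized coefficients are the linear map composed of the
orthogonal filters and w·q. k is chosen automatically (0–5) by
maximizing Q² under 7-fold venetian-blind cross-validation with a
seeded fold assignment; Q² = 1 − PRESS/TSS with fully refit folds.
The permutation test refits on n (default 200) uniform permutations
of y and reports "no overfitting" iff every permuted Q² lies below
the original and the intercept of the Q²-vs-|correlation| regression
is ≤ 0.05. Compound selection keeps VIP > 0.7 and coefficient < −0.1
(both cell lines; the negative sign encodes abundance↑ → IC50↓ →
toxicity↑). The coefficient threshold −0.1 reproduces both published
per-cell-line selection lists exactly, which fixes its sign
convention.

### BP-ANN

One tanh hidden layer (10 units), linear output, inputs and response
min–max scaled to [0, 1]. Training is full-batch gradient descent with
a bold-driver step (accepted steps grow the rate ×1.1, rejected steps
halve it and are retried within the epoch) and early stopping on the
MSE of a seeded 20% validation split (patience 50 epochs, max 2000),
reverting to the best-validation weights. Five random restarts run
under one master seed; restarts are compared on the all-sample MSE of
their early-stopped weights, because comparing on the ~10-sample
validation split alone lets underfit runs win on validation flukes
(early stopping within each run still uses the validation split
only). Weights initialize uniformly at 0.3× the fan-in/fan-out limit:
early stopping leaves untrained weights near their start, so a small
symmetric start keeps Garson sensitivity reflecting trained structure
rather than initialization noise. Garson's contribution of input a is
Σ_b (|w_ab|/Σ_d |w_db|)·|e_b|, normalized to 100% over inputs; MIV
multiplies one scaled input column by 1±δ (δ = 0.1, the usual
perturbation) and averages the prediction difference, reported in
response units. Selection keeps MIV < 0 against IC50. The specific
optimizer is not the contract — fit quality and seeded reproducibility
are; Levenberg–Marquardt would serve equally.

### Consensus

Within each engine, selections are intersected over cell lines; the
per-engine common sets are then intersected across engines —
deliberately in that order, and commutative/associative so engine
order is irrelevant. Marker ranking averages per-evidence ranks (GRA
degree, VIP·|coefficient|, |MIV|), ties broken by panel position.

## Dose–response stage

Inhibition = 100·(OD_S − OD_NC)/(OD_STSP − OD_NC), affine-invariant in
the ODs. The four-parameter logistic is fitted on log concentration by
bounded least squares with multi-start (hill ∈ {0.5, 1, 2}; IC50
started at the half-maximum crossing, or a decade beyond the grid when
the plate never crosses it). Plateau bounds are bottom ∈ [−50, 50] and
top ∈ [50, 150] percent: inhibition is control-normalized, and with
only seven points an unbounded top plateau trades off against a
runaway IC50 whenever the transition sits near the top of the grid.
The reported IC50 is the relative one (half-maximal between fitted
plateaus); estimates above the highest tested concentration
(1000 µg/ml by default) are reported but flagged censored, and
censoring propagates through replicate averaging (arithmetic mean).
Group comparison reports both Welch's t and Mann–Whitney U per cell
line: IC50 distributions are right-skewed, so the rank test typically
carries the sharper significance and both are shown.

Refit accuracy at 2% OD noise is ~4–6% median relative error for
plates whose IC50 lies within the grid's informative span
(second to second-last concentration); plates with IC50 near or above
the 1000 µg/ml top — which the processed-batch cohort genuinely
contains — are extrapolations with ~20% error and a censor flag. That
is a limitation of the assay design, not of the fitter, and it is why
the refit benchmark draws its true IC50s from the informative span.

## Synthetic cohorts: what they emulate, and what they do not

Per compound, raw-batch peak areas are log-normal (geometric CV 40%)
around a compound-specific median (drawn log-uniformly over 10⁴–10⁶
area units); processed batches multiply each compound by its reduction
factor. The planted markers (defaults: panel positions 6, 7, 14) draw
reductions uniformly from the reported fold-change range
[0.137, 0.441]; non-planted compounds default to 1.0 so that the
causal processing signal is carried by the markers. Batch potency is
1/IC50 = baseline + Σ β_j·area_j, with β > 0 only on planted markers
(equal potency share), times multiplicative lognormal noise — assay
error on a positive quantity — with CV 0.15. Two calibrations pin the
free scales: (i) baseline and β solve, per cell line, for the group
arithmetic-mean IC50s 250/735 µg/ml (L02) and 281/1185 µg/ml (HepG2),
including a second-order Jensen correction for the reciprocal; and
(ii) the noise CV is set so the cohort-level OPLS fit of IC50 on the
panel lands near the reported R²Y ≈ 0.8. Dose–response plates place
noise-free inhibition on a 4PL centred at each batch's true IC50
(negative and full-kill control wells at OD 1.4 and 0.2) and add
Gaussian OD noise; the untargeted-matrix generator plants differential
features with FC drawn from the same reported range plus tight QC
replicates of the grand mean (CV 5% by default).

Deliberately not emulated: retention-time drift and peak-shape
artifacts, plate edge effects, between-compound correlation (an
optional co-regulation factor exists but defaults to 0 — real panels
from one herb are positively correlated batch-to-batch, which makes
marker attribution *harder* than the default conditions), and
all-panel processing reduction (in the real cohort every panel
compound is reduced by processing, which confounds passenger compounds
with causal ones). Passing recovery tests therefore demonstrates the
machinery is correct under the stated generative model, not that the
selection rules are unconfounded on real cohorts.

## Recovery performance and an honest limit

With the defaults above, the differential screen recovers planted
features with sensitivity ≈ 1.0 and FDP ≈ 0, and the consensus
recovers all three planted markers in ≈ 99% of seeded cohorts. The
*exact-set* recovery rate — consensus equal to the planted set with no
extra compound — measures ≈ 0.82–0.88 over 50-seed batches, short of a
0.9 design goal. The shortfall is structural, not an implementation
defect: a non-causal compound enters the consensus when its chance
sample correlation with IC50 (standard deviation 1/√49 ≈ 0.14 at 50
batches) exceeds the effective OPLS bar (|coefficient| ≈ 0.23 once the
VIP > 0.7 gate is expressed in correlation units) with a negative
sign — probability ≈ 4% per compound per cell line, and largely shared
between cell lines because both potencies derive from the same batch
abundances — and then shows a negative MIV, which sign-only selection
cannot refuse. With 13 non-causal compounds this admits ≈ 0.15 false
compounds per run. The published study shows the same behaviour: its
per-engine selections retain 6–16 compounds each, and specificity
comes only from the final intersection. Sharpening exact-set recovery
would require either magnitude thresholds on MIV (not part of the
method) or more batches.

## Numerical and interface choices

- CSV exchange: comma-separated UTF-8, header row, decimal point;
  readers parse floats in round-trip mode so write-then-read is
  bit-identical. Batch groups are inferred from ID prefixes (S → raw,
  Z → processed) unless an explicit map is given.
- RSD uses the sample (n−1) standard deviation; linearity is the
  Pearson r of area vs injected volume.
- The Welch t-test for the differential screen runs on normalized
  intensities by default (a log option exists); features with
  zero variance in both groups and equal means get p = 1, flagged.
- Screening thresholds are strict inequalities; relaxing any
  threshold can only grow the selected set.
- All randomness flows from explicit integer seeds (derived seeds stay
  below 2³¹); every pipeline output is a pure function of
  (inputs, configuration, seed).
- Experiment sizes default to 50 seeded replicates (20 in the
  narrative drivers), chosen to estimate the recovery rates to a few
  percent while keeping a full run around a minute on one CPU.
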