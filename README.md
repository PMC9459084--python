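# pmtox — spectrum–effect modelling of hepatotoxic components in *Polygonum multiflorum*

*Polygonum multiflorum* (PM) is a widely used herbal medicine whose raw
form carries a well-documented risk of liver injury, largely removed by
traditional processing. Which of its many constituents drive that
toxicity is the open question this package addresses computationally:
it implements the full spectrum–effect analysis chain that links a
semiquantitative 16-compound MRM panel measured over 50 herb batches
(30 raw, 20 processed) to the batches' hepatocytotoxicity (IC50 on L02
and HepG2 cells), and distils toxicity markers by consensus of three
models.

The pipeline, for users doing chemometric toxicity-marker discovery:

1. **Differential screen** — untargeted intensity matrices are
   normalized, inspected by PCA, and filtered with the cascade
   VIP > 1.5 (from OPLS-DA), Welch *p* < 0.05, fold change
   (processed/raw) < 0.5.
2. **Dose–response** — plate optical densities become inhibition
   ratios, 100·(OD_S − OD_NC)/(OD_STSP − OD_NC), fitted with a
   variable-slope four-parameter logistic
   `inh(c) = bottom + (top − bottom)/(1 + (IC50/c)^hill)`;
   replicate IC50s are averaged per batch and the reciprocal 1/IC50 is
   the potency scale.
3. **Three engines per cell line** —
   *GRA*: Deng's gray relational coefficient
   ξᵢ(k) = (Δmin + ρΔmax)/(Δᵢ(k) + ρΔmax) of each compound series
   against the 1/IC50 reference (ρ = 0.5), compounds kept at
   degree > 0.6;
   *OPLS*: orthogonal-signal-corrected PLS of IC50 on the standardized
   areas, compounds kept at VIP > 0.7 and standardized coefficient
   < −0.1, validated by 7-fold Q² and 200 response permutations;
   *BP-ANN*: a 16–10–1 tanh network trained by gradient descent with
   early stopping (80/20 split), read out through Garson
   connection-weight percentages and mean impact values (MIV);
   compounds kept at MIV < 0 against IC50.
4. **Consensus** — intersect each engine's selections over the two
   cell lines, then intersect across engines.

A first-class synthetic-cohort generator reproduces the study's
statistical structure (log-normal peak areas, compound-specific
processing reduction in the reported 0.137–0.441 fold-change range, a
latent linear potency model on 1/IC50 calibrated to the reported group
mean IC50s of 250/281 µg/ml raw and 735/1185 µg/ml processed) and
provides planted ground truth for recovery tests of every stage.

## Worked example

```python
from pmtox import default_cohort_spec, generate_quant_cohort, run_pipeline

cohort = generate_quant_cohort(default_cohort_spec(seed=11))
result = run_pipeline(cohort.quant, cohort.true_ic50, seed=11)
print("consensus:", result.consensus.final)
print("OPLS L02:", result.opls_models["L02"].summary())
```

prints

```
consensus: ['X6', 'X7', 'X14']
OPLS L02: {'n_orthogonal': 0, 'R2X': 0.1362..., 'R2Y': 0.7543..., 'Q2': 0.5163...}
```

i.e. the consensus recovers exactly the three planted markers — the
emodin-8-*O*-β-D-glucopyranoside (X6), emodin dianthrone (X7) and
PM 14-17 (X14) positions of the panel — and the OPLS model explains
~75% of the IC50 variance with a cross-validated Q² of 0.52 on this
cohort. The same rules applied to the published panel tables keep
9 (OPLS, L02), 9 (OPLS, HepG2), 9 (BP-ANN, L02) and 6 (BP-ANN, HepG2)
compounds and intersect to the same three markers.

The numbered drivers under `analysis/` run the stages as a narrative
(simulate → screen → dose–response → spectrum–effect → consensus) and
write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_screen_features.py
python analysis/03_dose_response.py
python analysis/04_spectrum_effect.py
python analysis/05_consensus_and_recovery.py
```

## Layout

- `src/pmtox/` — library: `io`, `config`, `validation`, `synthetic`,
  `screen`, `dose_response`, `gra`, `opls`, `bpann`, `consensus`,
  `pipeline`, `experiments`, `datasets` (published panel reference
  tables).
- `analysis/` — numbered narrative drivers.
- `tests/` — unit, property and study-level acceptance tests.
- `docs/methods.md` — model and design notes.
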