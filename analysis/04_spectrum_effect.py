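#!/usr/bin/env python
"""Three-engine spectrum-effect analysis of the reference cohort.

Runs gray relational analysis, OPLS (with permutation validation) and
the BP network with Garson/MIV sensitivity on the simulated cohort's
peak areas against its true IC50s, and writes the full report bundle
under results/spectrum_effect/. Also applies the selection rules to
the published 16-compound panel tables for comparison.
"""

from pathlib import Path

import pandas as pd

from pmtox import (
    permutation_test,
    read_quant_table,
    read_toxicity_table,
    run_pipeline,
    select_by_miv,
    select_by_vip_coefficient,
    write_report,
)
from pmtox.datasets import panel_ann_sensitivity, panel_opls_coefficients

SEED = 11
BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "spectrum_effect"


def main() -> None:
    quant_path = BASE / "cohort" / "quant.csv"
    if not quant_path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    quant = read_quant_table(quant_path)
    toxicity = read_toxicity_table(BASE / "cohort" / "ic50.csv")
    result = run_pipeline(quant, toxicity, seed=SEED)
    write_report(result, OUT)

    for cl, model in result.opls_models.items():
        perm = permutation_test(quant.areas,
                                toxicity.ic50_series(cl).reindex(quant.batches).values,
                                n_permutations=200, seed=SEED)
        verdict = "no overfitting" if perm.passed else "OVERFIT"
        print(f"OPLS {cl}: R2X {model.r2x:.2f}, R2Y {model.r2y:.2f}, "
              f"Q2 {model.q2:.2f}; 200-permutation verdict: {verdict}")
    for (engine, cl), sel in sorted(result.selections.items()):
        print(f"{engine}/{cl}: {', '.join(sel) if sel else '(none)'}")
    print(f"consensus markers: {', '.join(result.consensus.final)}")

    # published panel tables under the same rules
    coefs = panel_opls_coefficients()
    ann = panel_ann_sensitivity()
    vip = pd.Series(1.0, index=coefs.index)
    for cl in ("L02", "HepG2"):
        opls_set = select_by_vip_coefficient(vip, coefs[cl], 0.7, -0.1)
        ann_set = select_by_miv(ann[f"miv_{cl}"])
        print(f"published panel {cl}: OPLS keeps {len(opls_set)}, "
              f"BP-ANN keeps {len(ann_set)} compounds")
    print(f"wrote report bundle -> {OUT}")


if __name__ == "__main__":
    main()
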