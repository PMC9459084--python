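#!/usr/bin/env python
"""Generate the reference synthetic cohort.

Draws the default-condition cohort — 30 raw and 20 processed batches
quantified on the 16-compound panel with markers X6/X7/X14 planted —
together with its true per-batch IC50s on both hepatocyte lines and
three-replicate dose-response plates at 2% OD noise, and writes
everything under results/cohort/.
"""

from pathlib import Path

import json

from pmtox import (
    generate_dose_response_plates,
    generate_quant_cohort,
    write_quant_table,
    write_toxicity_table,
)
from pmtox.synthetic import default_cohort_spec

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_quant_cohort(default_cohort_spec(SEED))
    write_quant_table(cohort.quant, OUT / "quant.csv")
    write_toxicity_table(cohort.true_ic50, OUT / "ic50.csv")
    plates = generate_dose_response_plates(cohort, od_noise_sd=0.02, seed=SEED + 1)
    plates.to_csv(OUT / "plates.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps({
        "planted_markers": list(cohort.truth),
        "seed": SEED,
        "n_raw": 30, "n_processed": 20, "n_compounds": 16,
    }, indent=2))

    for cl in ("L02", "HepG2"):
        ic50 = cohort.true_ic50.ic50_series(cl)
        groups = cohort.quant.groups.reindex(ic50.index)
        print(f"{cl}: raw mean IC50 {ic50[groups == 'raw'].mean():.0f} ug/ml, "
              f"processed {ic50[groups == 'processed'].mean():.0f} ug/ml")
    print(f"planted markers: {', '.join(cohort.truth)}")
    print(f"wrote quant.csv, ic50.csv, plates.csv, truth.json -> {OUT}")


if __name__ == "__main__":
    main()
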