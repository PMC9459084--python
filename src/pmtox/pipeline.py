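"""End-to-end spectrum-effect pipeline: peak areas + IC50s in, three
model engines (GRA / OPLS / BP-ANN), consensus markers out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json

import numpy as np
import pandas as pd

from . import bpann, gra, opls
from .config import AnalysisConfig
from .consensus import ConsensusResult, across_model_intersection, rank_markers
from .dose_response import compare_groups
from .io import QuantTable, ToxicityTable, check_batches_match


@dataclass
class PipelineResult:
    selections: dict  # (engine, cell_line) -> compound list
    consensus: ConsensusResult
    marker_table: pd.DataFrame | None
    gra_results: dict  # cell_line -> GraResult
    opls_models: dict  # cell_line -> OplsModel
    ann_reports: dict  # cell_line -> {model, garson, miv}
    group_comparison: pd.DataFrame
    standardized_areas: pd.DataFrame  # heat-map matrix (per-compound z-scores)
    config: AnalysisConfig
    seed: int

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "consensus_markers": list(self.consensus.final),
            "per_engine_common": {k: list(v) for k, v in
                                  self.consensus.per_engine_common.items()},
            "selections": {f"{eng}/{cl}": list(v)
                           for (eng, cl), v in self.selections.items()},
            "opls": {cl: m.summary() for cl, m in self.opls_models.items()},
            "ann": {cl: rep["model"].metrics for cl, rep in self.ann_reports.items()},
            "group_comparison": self.group_comparison.reset_index().to_dict("records"),
        }


def run_pipeline(quant: QuantTable, toxicity: ToxicityTable,
                 config: AnalysisConfig | None = None, seed: int = 0
                 ) -> PipelineResult:
    """Run GRA, OPLS and BP-ANN per cell line and intersect the
    selections. Deterministic given (inputs, config, seed)."""
    config = (config or AnalysisConfig()).validate()
    check_batches_match(quant, toxicity)
    batches = quant.batches

    selections: dict = {}
    gra_results, opls_models, ann_reports = {}, {}, {}
    rng = np.random.default_rng(seed)
    for cell_line in toxicity.cell_lines:
        ic50 = toxicity.ic50_series(cell_line).reindex(batches)
        X = quant.areas

        # gray relational analysis against the potency reference 1/IC50
        g = gra.relational_degree(1.0 / ic50, X, rho=config.gra.rho,
                                  normalization=config.gra.normalization)
        gra_results[cell_line] = g
        selections[("GRA", cell_line)] = gra.select_by_degree(
            g, config.gra.degree_min
        )

        # OPLS of IC50 on the standardized areas
        model = opls.fit_opls(X, ic50.values,
                              n_orthogonal=config.opls.n_orthogonal,
                              max_orthogonal=config.opls.max_orthogonal,
                              cv_folds=config.opls.cv_folds, fold_seed=seed)
        opls_models[cell_line] = model
        selections[("OPLS", cell_line)] = opls.select_by_vip_coefficient(
            model, vip_min=config.opls.vip_min, coef_max=config.opls.coef_max
        )

        # back-propagation network with sensitivity analysis
        ann_seed = int(rng.integers(0, 2 ** 31 - 1))
        net = bpann.train_bpann(X, ic50.values,
                                hidden_units=config.ann.hidden_units,
                                train_fraction=config.ann.train_fraction,
                                seed=ann_seed, n_restarts=config.ann.n_restarts,
                                max_iter=config.ann.max_iter)
        garson = bpann.garson_sensitivity(net)
        miv = bpann.mean_impact_value(net, delta=config.ann.miv_delta)
        ann_reports[cell_line] = {"model": net, "garson": garson, "miv": miv}
        selections[("BP-ANN", cell_line)] = bpann.select_by_miv(miv)

    consensus = across_model_intersection(selections)
    marker_table = None
    if consensus.final:
        evidence = {}
        for cell_line in toxicity.cell_lines:
            evidence[f"gra_degree_{cell_line}"] = gra_results[cell_line].degrees
            m = opls_models[cell_line]
            evidence[f"opls_strength_{cell_line}"] = m.vip * m.coefficients.abs()
            evidence[f"abs_miv_{cell_line}"] = ann_reports[cell_line]["miv"].abs()
        marker_table = rank_markers(consensus, pd.DataFrame(evidence))

    comparison = compare_groups(toxicity, quant.groups)
    return PipelineResult(
        selections=selections, consensus=consensus, marker_table=marker_table,
        gra_results=gra_results, opls_models=opls_models, ann_reports=ann_reports,
        group_comparison=comparison, standardized_areas=quant.standardized(),
        config=config, seed=seed,
    )


def write_report(result: PipelineResult, out_dir) -> None:
    """Write the CSV tables and JSON summary of a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for (engine, cell_line), compounds in result.selections.items():
        for rank, compound in enumerate(compounds, start=1):
            rows.append({"engine": engine, "cell_line": cell_line,
                         "compound": compound, "rank": rank})
    pd.DataFrame(rows).to_csv(out / "selections.csv", index=False)

    prov = result.consensus.provenance.copy()
    prov.columns = [f"{eng}_{cl}" for eng, cl in prov.columns]
    prov.loc[:, "in_consensus"] = prov.index.isin(result.consensus.final)
    prov.to_csv(out / "consensus.csv", index_label="compound")
    if result.marker_table is not None:
        result.marker_table.to_csv(out / "markers.csv", index_label="compound")

    degrees = pd.DataFrame({cl: g.degrees for cl, g in result.gra_results.items()})
    degrees.to_csv(out / "gra_degrees.csv", index_label="compound")
    opls_table = pd.DataFrame({
        f"{col}_{cl}": series
        for cl, m in result.opls_models.items()
        for col, series in (("vip", m.vip), ("coefficient", m.coefficients))
    })
    opls_table.to_csv(out / "opls.csv", index_label="compound")
    ann_table = pd.DataFrame({
        f"{col}_{cl}": rep[key]
        for cl, rep in result.ann_reports.items()
        for col, key in (("garson_percent", "garson"), ("miv", "miv"))
    })
    ann_table.to_csv(out / "ann_sensitivity.csv", index_label="compound")

    result.group_comparison.to_csv(out / "group_comparison.csv")
    result.standardized_areas.to_csv(out / "standardized_areas.csv",
                                     index_label="batch")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary(), fh, indent=2, default=float)
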