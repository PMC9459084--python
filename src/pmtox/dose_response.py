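"""Plate optical densities -> inhibition ratios -> four-parameter
logistic IC50 estimates, plus raw-vs-processed group comparison.

The inhibition ratio normalizes a treated well between the negative
(vehicle) control and the full-kill staurosporine control:

    inhibition (%) = 100 * (OD_S - OD_NC) / (OD_STSP - OD_NC)

The dose-response model is the variable-slope four-parameter logistic

    inhibition(c) = bottom + (top - bottom) / (1 + (ic50 / c)^hill)

fitted by least squares on log concentration; the reported IC50 is the
"relative" one, i.e. the concentration of half-maximal response
between the fitted bottom and top plateaus. Estimates above the top
tested concentration are reported but flagged censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataValidationError, FitError
from .io import GROUP_PROCESSED, GROUP_RAW, ToxicityTable


def inhibition_ratio(od_s, od_nc, od_stsp):
    """Percent inhibition of treated wells between the plate controls.

    Affine-invariant in the ODs; may fall outside [0, 100] with noisy
    plates. Raises if the controls coincide.
    """
    od_s = np.asarray(od_s, dtype=float)
    denom = float(od_stsp) - float(od_nc)
    if denom == 0:
        raise DataValidationError(
            "degenerate controls: OD_STSP equals OD_NC, inhibition undefined"
        )
    out = 100.0 * (od_s - float(od_nc)) / denom
    return float(out) if out.ndim == 0 else out


def four_pl(conc, bottom, top, ic50, hill):
    """Variable-slope four-parameter logistic on the inhibition scale."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)


def _4pl_log(log_c, bottom, top, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_ic50 - log_c)))


@dataclass
class DoseResponseCurve:
    concentrations: np.ndarray  # ug/ml, strictly increasing
    inhibitions: np.ndarray  # percent
    bottom: float
    top: float
    ic50: float
    hill: float
    sse: float
    censored: bool

    def predict(self, conc):
        return four_pl(conc, self.bottom, self.top, self.ic50, self.hill)


def fit_four_pl(concentrations, inhibitions, censor_limit: float | None = None
                ) -> DoseResponseCurve:
    """Least-squares 4PL fit with multi-start initialization.

    The IC50 start is placed at the concentration bracketing the
    half-maximal observed response (or beyond the grid when the plate
    never reaches it); hill starts at {0.5, 1, 2}. The censor flag is
    set whenever the fitted IC50 exceeds ``censor_limit`` (default:
    the highest tested concentration).
    """
    conc = np.asarray(concentrations, dtype=float)
    inh = np.asarray(inhibitions, dtype=float)
    if conc.size != inh.size:
        raise FitError("concentrations and inhibitions differ in length")
    if conc.size < 5:
        raise FitError(f"need at least 5 concentration points, got {conc.size}")
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise DataValidationError("concentrations must be positive and increasing")
    if censor_limit is None:
        censor_limit = float(conc.max())

    log_c = np.log(conc)
    span = inh.max() - inh.min()
    if span > 30:
        b0, t0 = float(inh.min()), float(inh.max())
    else:  # nearly flat plate: anchor plateaus at the assay scale
        b0, t0 = 0.0, 100.0
    mid = 0.5 * (b0 + t0)
    above = inh >= mid
    if above.any() and (~above).any():
        # bracket the first crossing of the observed half-maximum
        idx = int(np.argmax(above != above[0]))
        lic0 = 0.5 * (log_c[idx - 1] + log_c[idx])
    elif above.all():  # everything inhibited: midpoint below the grid
        lic0 = log_c[0] - np.log(10.0)
    else:  # nothing inhibited: midpoint beyond the grid
        lic0 = log_c[-1] + np.log(10.0)

    # inhibition is control-normalized, so the plateaus live near 0 and
    # 100; generous but finite bounds keep sparse top-of-grid plates
    # from trading an inflated top plateau against a runaway IC50
    lo = (-50.0, 50.0, log_c[0] - np.log(1e4), 1e-3)
    hi = (50.0, 150.0, log_c[-1] + np.log(1e4), 20.0)
    best = None
    for hill0 in (0.5, 1.0, 2.0):
        p0 = (
            np.clip(b0, lo[0], hi[0]), np.clip(t0, lo[1], hi[1]),
            np.clip(lic0, lo[2], hi[2]), hill0,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _4pl_log, log_c, inh, p0=p0, bounds=(lo, hi), maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(((inh - _4pl_log(log_c, *popt)) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError(
            "4PL fit did not converge from any start "
            f"(inhibition range {inh.min():.1f}..{inh.max():.1f}%)"
        )
    sse, (bottom, top, log_ic50, hill) = best
    ic50 = float(np.exp(log_ic50))

    fitted = _4pl_log(log_c, bottom, top, log_ic50, hill)
    resid_sd = np.sqrt(sse / max(conc.size - 4, 1))
    if np.any(np.diff(fitted) * np.sign(top - bottom) < -3 * max(resid_sd, 1e-9)):
        warnings.warn("fitted curve is non-monotone beyond noise tolerance",
                      stacklevel=2)
    return DoseResponseCurve(
        concentrations=conc, inhibitions=inh, bottom=float(bottom),
        top=float(top), ic50=ic50, hill=float(hill), sse=sse,
        censored=ic50 > censor_limit,
    )


def summarize_ic50(curves) -> dict:
    """Arithmetic mean over replicate fits; censoring propagates.

    Accepts :class:`DoseResponseCurve` objects or (ic50, censored)
    pairs or bare IC50 values.
    """
    values, flags = [], []
    for item in curves:
        if isinstance(item, DoseResponseCurve):
            values.append(item.ic50)
            flags.append(item.censored)
        elif isinstance(item, (tuple, list)):
            values.append(float(item[0]))
            flags.append(bool(item[1]))
        else:
            values.append(float(item))
            flags.append(False)
    if not values:
        raise DataValidationError("need at least one replicate")
    return {"ic50": float(np.mean(values)), "censored": bool(any(flags)),
            "n_replicates": len(values)}


def fit_plate_table(plates: pd.DataFrame, censor_limit: float | None = None
                    ) -> ToxicityTable:
    """Fit every (batch, cell line) in a long-format plate table.

    Controls (role NC / STSP) are averaged per replicate; replicate
    IC50s are averaged into the batch-level value.
    """
    rows = []
    for (batch, cell_line), group in plates.groupby(["batch", "cell_line"], sort=False):
        curves = []
        for _, rep in group.groupby("replicate", sort=False):
            nc = rep.loc[rep["role"] == "NC", "OD"].mean()
            stsp = rep.loc[rep["role"] == "STSP", "OD"].mean()
            sample = rep[rep["role"] == "sample"].sort_values("concentration")
            inh = inhibition_ratio(sample["OD"].values, nc, stsp)
            curves.append(
                fit_four_pl(sample["concentration"].values, inh, censor_limit)
            )
        summary = summarize_ic50(curves)
        rows.append({"batch": batch, "cell_line": cell_line,
                     "ic50": summary["ic50"], "censored": summary["censored"]})
    return ToxicityTable(pd.DataFrame(rows))


def compare_groups(toxicity: ToxicityTable, groups: pd.Series) -> pd.DataFrame:
    """Raw-vs-processed IC50 comparison per cell line.

    Reports the two-sided Welch t-test (default inference) and the
    Mann-Whitney U test alongside the group means.
    """
    rows = []
    for cell_line in toxicity.cell_lines:
        ic50 = toxicity.ic50_series(cell_line)
        labels = groups.reindex(ic50.index)
        raw = ic50[labels == GROUP_RAW].values
        proc = ic50[labels == GROUP_PROCESSED].values
        if len(raw) < 2 or len(proc) < 2:
            raise DataValidationError(
                f"{cell_line}: both groups need >= 2 batches "
                f"(raw {len(raw)}, processed {len(proc)})"
            )
        welch = stats.ttest_ind(raw, proc, equal_var=False)
        mw = stats.mannwhitneyu(raw, proc, alternative="two-sided")
        rows.append({
            "cell_line": cell_line,
            "mean_raw": float(raw.mean()),
            "mean_processed": float(proc.mean()),
            "welch_t": float(welch.statistic), "welch_p": float(welch.pvalue),
            "mannwhitney_u": float(mw.statistic), "mannwhitney_p": float(mw.pvalue),
        })
    return pd.DataFrame(rows).set_index("cell_line")
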