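"""Method-validation QC metrics for the semiquantitative MRM panel.

Repeatability, precision and stability are all summarized as the
relative standard deviation (RSD, percent) of replicate peak areas;
linearity is the Pearson correlation of peak area against injected
volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataValidationError


def rsd_percent(values) -> float:
    """100 * sample (n-1) standard deviation / mean of replicate areas."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DataValidationError("RSD needs at least 2 replicates")
    mean = values.mean()
    if mean == 0:
        raise DataValidationError("RSD undefined: replicate mean is zero")
    return float(100.0 * values.std(ddof=1) / mean)


def linearity_r(volumes, areas) -> float:
    """Pearson correlation of peak area vs injected volume."""
    volumes = np.asarray(volumes, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if volumes.size < 3:
        raise DataValidationError("linearity needs at least 3 points")
    return float(stats.pearsonr(volumes, areas).statistic)


@dataclass
class ValidationReport:
    """Per-compound RSDs (percent) and linearity correlations."""

    rsd: pd.DataFrame  # compounds x replicate-series names
    linearity: pd.Series  # compound -> Pearson r

    def passes(self, rsd_max: float = 15.0, r_min: float = 0.98) -> bool:
        ok_rsd = bool((self.rsd.values <= rsd_max).all())
        ok_r = bool((self.linearity >= r_min).all()) if len(self.linearity) else True
        return ok_rsd and ok_r

    def frame(self) -> pd.DataFrame:
        out = self.rsd.copy()
        out["linearity_r"] = self.linearity
        return out


def compute_validation_metrics(replicate_areas: dict, linearity_pairs: dict | None = None
                               ) -> ValidationReport:
    """Summarize replicate series and linearity points per compound.

    ``replicate_areas`` maps compound -> {series name -> replicate
    values} (or compound -> values for a single unnamed series);
    ``linearity_pairs`` maps compound -> (volumes, areas).
    Requires >= 3 replicates per series and >= 3 linearity points.
    """
    rsd_rows = {}
    for compound, series in replicate_areas.items():
        if not isinstance(series, dict):
            series = {"rsd_percent": series}
        row = {}
        for name, values in series.items():
            values = np.asarray(values, dtype=float)
            if values.size < 3:
                raise DataValidationError(
                    f"{compound}/{name}: need >= 3 replicates, got {values.size}"
                )
            row[name] = rsd_percent(values)
        rsd_rows[compound] = row
    rsd = pd.DataFrame.from_dict(rsd_rows, orient="index")

    lin = {}
    if linearity_pairs:
        for compound, (volumes, areas) in linearity_pairs.items():
            lin[compound] = linearity_r(volumes, areas)
    linearity = pd.Series(lin, dtype=float).reindex(rsd.index)
    return ValidationReport(rsd=rsd, linearity=linearity)
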