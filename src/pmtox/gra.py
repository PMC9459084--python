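"""Gray relational analysis (Deng's relational coefficient).

Each compound's peak-area series across batches is compared with the
potency reference series 1/IC50. After a dimensionless transform, the
absolute deviation of comparison series i from the reference at batch k
is Delta_i(k); Deng's coefficient with resolution coefficient rho is

    xi_i(k) = (Dmin + rho * Dmax) / (Delta_i(k) + rho * Dmax)

with Dmin / Dmax the two-level extrema of Delta over all series and
batches. The relational degree of series i is the mean of xi_i over
batches; compounds are ranked by degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, TransformError


def dimensionless_transform(series, method: str = "mean"):
    """Remove scale from a series: divide by mean / first element, or min-max.

    Returns an object of the same type (Series in, Series out).
    """
    values = np.asarray(series, dtype=float)
    if method == "mean":
        m = values.mean()
        if m == 0:
            raise TransformError("mean transform undefined: series mean is zero")
        out = values / m
    elif method == "initial":
        if values[0] == 0:
            raise TransformError("initial transform undefined: first element is zero")
        out = values / values[0]
    elif method == "minmax":
        span = values.max() - values.min()
        if span == 0:
            raise TransformError("minmax transform undefined: series is constant")
        out = (values - values.min()) / span
    else:
        raise ConfigError(f"unknown dimensionless method {method!r}")
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index)
    return out


@dataclass
class GraResult:
    degrees: pd.Series  # compound -> relational degree, in (0, 1]
    coefficients: pd.DataFrame  # batches x compounds
    rho: float
    normalization: str

    def ranked(self) -> pd.Series:
        return self.degrees.sort_values(ascending=False)


def relational_degree(reference, comparisons: pd.DataFrame, rho: float = 0.5,
                      normalization: str | None = "mean") -> GraResult:
    """Deng relational degrees of each comparison column vs the reference.

    ``normalization`` is applied to the reference and to every column
    first; pass ``None`` if the series are already dimensionless.
    Dmin / Dmax are taken globally over all comparison series.
    """
    if not (0 < rho <= 1):
        raise ConfigError(f"rho must lie in (0, 1], got {rho}")
    reference = pd.Series(reference)
    if len(reference) < 3:
        raise ConfigError("series must have length >= 3")
    comparisons = pd.DataFrame(comparisons)
    if len(comparisons) != len(reference):
        raise ConfigError(
            f"length mismatch: reference has {len(reference)} points, "
            f"comparisons have {len(comparisons)}"
        )
    comparisons = comparisons.set_axis(reference.index, axis=0)

    if normalization is not None:
        reference = dimensionless_transform(reference, normalization)
        comparisons = comparisons.apply(
            lambda col: dimensionless_transform(col, normalization)
        )

    delta = (comparisons.sub(reference, axis=0)).abs()
    dmin = float(delta.values.min())
    dmax = float(delta.values.max())
    if dmax == 0:  # all comparisons identical to the reference
        coeff = pd.DataFrame(1.0, index=delta.index, columns=delta.columns)
    else:
        coeff = (dmin + rho * dmax) / (delta + rho * dmax)
    degrees = coeff.mean(axis=0)
    return GraResult(
        degrees=degrees,
        coefficients=coeff,
        rho=rho,
        normalization=normalization or "none",
    )


def select_by_degree(result: GraResult, degree_min: float = 0.6) -> list:
    """Compounds with relational degree strictly above the threshold,
    ranked by decreasing degree."""
    keep = result.degrees[result.degrees > degree_min]
    return list(keep.sort_values(ascending=False).index)
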