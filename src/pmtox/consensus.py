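"""Combine per-engine, per-cell-line selections into the final marker
set: intersect over cell lines within each engine, then intersect the
per-engine common sets across engines, keeping full provenance."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError

ENGINES = ("GRA", "OPLS", "BP-ANN")


def _compound_sort_key(name: str):
    """Order X2 before X10; fall back to lexicographic."""
    text = str(name)
    digits = "".join(ch for ch in text if ch.isdigit())
    return (0, int(digits)) if digits else (1, text)


def _sorted(compounds) -> list:
    return sorted(compounds, key=_compound_sort_key)


def within_model_common(selections: dict, engine: str) -> list:
    """Intersection of one engine's selections over cell lines.

    ``selections`` maps (engine, cell_line) -> iterable of compounds.
    """
    cell_sets = [set(v) for (eng, _), v in selections.items() if eng == engine]
    if len(cell_sets) < 2:
        raise ConfigError(
            f"engine {engine!r} needs selections for both cell lines, "
            f"got {len(cell_sets)}"
        )
    return _sorted(set.intersection(*cell_sets))


@dataclass
class ConsensusResult:
    per_engine_common: dict  # engine -> sorted list
    final: list  # sorted intersection across engines
    provenance: pd.DataFrame  # compound x (engine, cell_line) support flags


def across_model_intersection(selections: dict) -> ConsensusResult:
    """Intersect per-engine common sets across >= 2 engines.

    ``selections`` maps (engine, cell_line) -> compound iterable. An
    empty engine set triggers a warning but the intersection proceeds.
    """
    engines = sorted({eng for eng, _ in selections})
    if len(engines) < 2:
        raise ConfigError(f"need selections from >= 2 engines, got {engines}")
    per_engine = {eng: within_model_common(selections, eng) for eng in engines}
    for eng, common in per_engine.items():
        if not common:
            warnings.warn(f"engine {eng} retained no compound", stacklevel=2)
    final = set.intersection(*(set(v) for v in per_engine.values()))

    all_compounds = _sorted({c for v in selections.values() for c in v})
    columns = pd.MultiIndex.from_tuples(sorted(selections.keys()),
                                        names=["engine", "cell_line"])
    provenance = pd.DataFrame(False, index=all_compounds, columns=columns)
    for key, compounds in selections.items():
        for compound in compounds:
            provenance.loc[compound, key] = True
    return ConsensusResult(per_engine_common=per_engine, final=_sorted(final),
                           provenance=provenance)


def rank_markers(consensus: ConsensusResult, evidence: pd.DataFrame) -> pd.DataFrame:
    """Order consensus markers by mean rank over evidence columns.

    Each evidence column holds a strength score (larger = stronger,
    e.g. GRA degree, |coefficient| x VIP, |MIV|). Ties break by panel
    position (the compound's number).
    """
    if not consensus.final:
        raise ConfigError("consensus is empty; nothing to rank")
    evid = evidence.reindex(consensus.final)
    ranks = evid.rank(ascending=False, axis=0)
    mean_rank = ranks.mean(axis=1)
    order = sorted(
        consensus.final,
        key=lambda c: (mean_rank[c] if np.isfinite(mean_rank[c]) else np.inf,
                       _compound_sort_key(c)),
    )
    out = evid.loc[order].copy()
    out.insert(0, "mean_rank", mean_rank.loc[order])
    out.insert(0, "rank", np.arange(1, len(order) + 1))
    return out
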