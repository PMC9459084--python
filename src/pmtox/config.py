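"""Run configuration for the spectrum-effect pipeline.

Thresholds default to the values used throughout the study design:
the differential screen keeps features with VIP > 1.5, p < 0.05 and
fold change < 0.5; the spectrum-effect OPLS keeps compounds with
VIP > 0.7 and a standardized coefficient below -0.1; gray relational
analysis uses Deng's resolution coefficient rho = 0.5; the network has
one hidden layer of 10 units trained on an 80/20 split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigError

#: seven-point extract concentration grid of the cytotoxicity assay, ug/ml
DEFAULT_CONCENTRATION_GRID = (0.064, 0.32, 1.6, 8.0, 40.0, 200.0, 1000.0)

GRA_NORMALIZATIONS = ("mean", "initial", "minmax")


@dataclass
class ScreenConfig:
    """Thresholds of the VIP / p / FC differential-screening cascade."""

    vip_min: float = 1.5
    p_max: float = 0.05
    fc_max: float = 0.5
    log_intensities: bool = False

    def validate(self) -> None:
        for name in ("vip_min", "p_max", "fc_max"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"screen.{name} must be finite and positive, got {v}")
        if self.p_max > 1:
            raise ConfigError(f"screen.p_max is a probability, got {self.p_max}")


@dataclass
class GraConfig:
    """Gray relational analysis options."""

    rho: float = 0.5
    normalization: str = "mean"
    degree_min: float = 0.6

    def validate(self) -> None:
        if not (0 < self.rho <= 1):
            raise ConfigError(f"gra.rho must lie in (0, 1], got {self.rho}")
        if self.normalization not in GRA_NORMALIZATIONS:
            raise ConfigError(
                f"gra.normalization must be one of {GRA_NORMALIZATIONS}, got {self.normalization!r}"
            )
        if not np.isfinite(self.degree_min):
            raise ConfigError("gra.degree_min must be finite")


@dataclass
class OplsConfig:
    """OPLS / OPLS-DA engine options."""

    n_orthogonal: int | str = "auto"
    max_orthogonal: int = 5
    cv_folds: int = 7
    n_permutations: int = 200
    vip_min: float = 0.7
    coef_max: float = -0.1

    def validate(self) -> None:
        if self.n_orthogonal != "auto":
            if not isinstance(self.n_orthogonal, (int, np.integer)) or self.n_orthogonal < 0:
                raise ConfigError(
                    f"opls.n_orthogonal must be 'auto' or a non-negative integer, got {self.n_orthogonal!r}"
                )
        if self.cv_folds < 2:
            raise ConfigError(f"opls.cv_folds must be >= 2, got {self.cv_folds}")
        if self.n_permutations < 1:
            raise ConfigError("opls.n_permutations must be positive")
        if not np.isfinite(self.vip_min) or not np.isfinite(self.coef_max):
            raise ConfigError("opls selection thresholds must be finite")


@dataclass
class AnnConfig:
    """Back-propagation network options (inputs -> hidden -> single output)."""

    hidden_units: int = 10
    train_fraction: float = 0.8
    miv_delta: float = 0.1
    n_restarts: int = 5
    max_iter: int = 2000

    def validate(self) -> None:
        if self.hidden_units < 1:
            raise ConfigError("ann.hidden_units must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ConfigError(
                f"ann.train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        if not (0 < self.miv_delta < 1):
            raise ConfigError(f"ann.miv_delta must lie in (0, 1), got {self.miv_delta}")
        if self.n_restarts < 1:
            raise ConfigError("ann.n_restarts must be >= 1")


@dataclass
class DoseResponseConfig:
    """Plate layout and censoring options for IC50 estimation."""

    concentration_grid: tuple = DEFAULT_CONCENTRATION_GRID
    censor_limit: float | None = None  # None -> top of the grid

    def validate(self) -> None:
        grid = np.asarray(self.concentration_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ConfigError("dose_response.concentration_grid needs >= 2 points")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ConfigError(
                "dose_response.concentration_grid must be strictly increasing and positive"
            )
        if self.censor_limit is not None and self.censor_limit <= 0:
            raise ConfigError("dose_response.censor_limit must be positive")

    @property
    def effective_censor_limit(self) -> float:
        if self.censor_limit is not None:
            return float(self.censor_limit)
        return float(self.concentration_grid[-1])


@dataclass
class AnalysisConfig:
    """Full pipeline configuration; ``validate`` checks every block."""

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    gra: GraConfig = field(default_factory=GraConfig)
    opls: OplsConfig = field(default_factory=OplsConfig)
    ann: AnnConfig = field(default_factory=AnnConfig)
    dose_response: DoseResponseConfig = field(default_factory=DoseResponseConfig)

    def validate(self) -> "AnalysisConfig":
        self.screen.validate()
        self.gra.validate()
        self.opls.validate()
        self.ann.validate()
        self.dose_response.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        kwargs = {}
        blocks = {
            "screen": ScreenConfig,
            "gra": GraConfig,
            "opls": OplsConfig,
            "ann": AnnConfig,
            "dose_response": DoseResponseConfig,
        }
        for key, block_cls in blocks.items():
            if key in data:
                payload = dict(data[key])
                if key == "dose_response" and "concentration_grid" in payload:
                    payload["concentration_grid"] = tuple(payload["concentration_grid"])
                kwargs[key] = block_cls(**payload)
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        data = self.to_dict()
        data["dose_response"]["concentration_grid"] = list(
            data["dose_response"]["concentration_grid"]
        )
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
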