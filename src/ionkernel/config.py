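"""Pipeline configuration: element panel, normalization constants, thresholds.

Defaults reproduce the standard single-kernel maize ionomics workflow:
20 ICP-MS elements, indium internal standard at 20 ppb, a 10 mL primary
digest with a 0.9 mL -> 5.0 mL secondary dilution, matrix-matched controls
every tenth sample, and a conservative 15-MAD analytical outlier cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Default ICP-MS element panel for maize kernels.
DEFAULT_ELEMENTS: tuple[str, ...] = (
    "B", "Na", "Mg", "Al", "P", "S", "K", "Ca", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "As", "Se", "Rb", "Sr", "Mo", "Cd",
)


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass(frozen=True)
class NormalizationConfig:
    """Constants converting solution concentrations (ppb) to seed ppm.

    Attributes
    ----------
    is_nominal_ppb : internal-standard (In) concentration spiked into the
        digestion acid, ppb.
    digest_volume_ml : primary digest volume after first dilution, mL.
    secondary_aliquot_ml : volume of first dilution carried into the
        secondary dilution, mL.
    secondary_total_ml : total volume of the secondary dilution, mL.
    """

    is_nominal_ppb: float = 20.0
    digest_volume_ml: float = 10.0
    secondary_aliquot_ml: float = 0.9
    secondary_total_ml: float = 5.0

    def __post_init__(self) -> None:
        for name in ("is_nominal_ppb", "digest_volume_ml",
                     "secondary_aliquot_ml", "secondary_total_ml"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def secondary_dilution_factor(self) -> float:
        """Secondary dilution factor (total/aliquot), ~5.556 by default."""
        return self.secondary_total_ml / self.secondary_aliquot_ml

    def seed_ppm_per_solution_ppb(self, weight_g: float) -> float:
        """Multiplicative factor mapping measured solution ppb to seed ppm.

        ppm (mg element / kg seed) =
            ppb (ug/L) * secondary_dilution * digest_volume_L
            / seed_mass_kg / 1000 (ug -> mg)
        """
        if weight_g <= 0:
            raise ConfigError("seed weight must be positive")
        digest_l = self.digest_volume_ml / 1000.0
        weight_kg = weight_g / 1000.0
        return self.secondary_dilution_factor * digest_l / weight_kg / 1000.0


@dataclass(frozen=True)
class OutlierConfig:
    """Median-absolute-deviation outlier rule.

    ``threshold`` counts raw MADs (no 1.4826 consistency scaling) unless
    ``scale_mad`` is set; grouping is per plot for replicated field designs
    and per line otherwise.
    """

    threshold: float = 15.0
    group_by: tuple[str, ...] = ("line", "year", "block")
    scale_mad: bool = False
    min_group_size: int = 3

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigError("MAD threshold must be positive")
        if self.min_group_size < 3:
            raise ConfigError("min_group_size must be >= 3")


@dataclass
class PipelineConfig:
    """Top-level settings shared across pipeline stages."""

    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    alpha: float = 0.01
    run_size: int = 576
    control_interval: int = 10
    n_jackknife: int = 100
    jackknife_seed: int = 7
    excluded_lines: tuple[str, ...] = ("IL14H", "HP301", "P39")

    def __post_init__(self) -> None:
        if len(set(self.elements)) != len(self.elements):
            raise ConfigError("element names must be unique")
        for name in ("alpha", "run_size", "control_interval", "n_jackknife"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def alpha_adjusted(self) -> float:
        """Bonferroni-adjusted significance cutoff (alpha / n elements)."""
        return self.alpha / len(self.elements)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["elements"] = list(self.elements)
        data["excluded_lines"] = list(self.excluded_lines)
        data["outlier"]["group_by"] = list(self.outlier.group_by)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        norm = NormalizationConfig(**data.pop("normalization", {}))
        out = data.pop("outlier", {})
        if "group_by" in out:
            out["group_by"] = tuple(out["group_by"])
        outlier = OutlierConfig(**out)
        if "elements" in data:
            data["elements"] = tuple(data["elements"])
        if "excluded_lines" in data:
            data["excluded_lines"] = tuple(data["excluded_lines"])
        return cls(normalization=norm, outlier=outlier, **data)
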