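"""Physical constants and pipeline configuration.

Every constant used by the two-pool doubly-labelled-water (DLW)
computation lives in one frozen object so that a run can be reproduced
from its provenance record alone.  The defaults are the standard
two-pool field values; the food quotient and hydration constant are the
two a user realistically overrides (diet composition and population
differences respectively).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "DLWConstants",
    "CutPoints",
    "WearParams",
    "PipelineConfig",
    "DEFAULT_CONSTANTS",
    "DEFAULT_CUTPOINTS",
    "DEFAULT_WEAR",
]


@dataclass(frozen=True)
class DLWConstants:
    """Constants of the two-pool DLW equations.

    Units: dilution spaces in mol, elimination rates per day, energies
    in kcal, volumes in litres, masses in kg.  Time is in days
    throughout the package.

    Attributes
    ----------
    nd_pool_excess : float
        The deuterium dilution space overestimates total body water by
        ~4.3%; ND is divided by this factor.
    no_pool_excess : float
        The oxygen-18 space overestimates body water by ~0.7%.
    kg_per_mol_water : float
        0.01802 kg (litres) of water per mol.
    hydration_constant : float
        Water fraction of fat-free mass (FFM = TBW / 0.732).
    rco2_pool_divisor : float
        Divisor of the corrected pool in the CO2 production equation.
    gaseous_frac_coeff, gaseous_frac_scale : float
        Coefficients of the fractionated gaseous water-loss correction:
        rGF = 1.05 * Ncorr * delta, subtracted as 0.0246 * rGF.
    litres_per_mol_co2 : float
        Molar volume applied to CO2 production (22.26 L/mol at STP).
    weir_intercept, weir_slope : float
        Weir-type energy equivalent of CO2: kcal/L = 1.106 + 3.94/FQ.
    food_quotient : float
        Diet-level CO2/O2 ratio; 0.86 assumes ~30% of energy from fat.
    wt_fractionation : float
        Fractionation correction in the water-turnover formula
        (division by 0.99).
    """

    nd_pool_excess: float = 1.043
    no_pool_excess: float = 1.007
    kg_per_mol_water: float = 0.01802
    hydration_constant: float = 0.732
    rco2_pool_divisor: float = 2.078
    gaseous_frac_coeff: float = 0.0246
    gaseous_frac_scale: float = 1.05
    litres_per_mol_co2: float = 22.26
    weir_intercept: float = 1.106
    weir_slope: float = 3.94
    food_quotient: float = 0.86
    wt_fractionation: float = 0.99

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"constant {f.name} must be positive, got {v}")
        if not 0.7 < self.food_quotient < 1.0:
            raise ValueError(
                f"food quotient must lie in (0.7, 1.0), got {self.food_quotient}"
            )

    def energy_equiv_kcal_per_litre(self, fq: float | None = None) -> float:
        """Weir-type energy equivalent of one litre of CO2 at food quotient *fq*."""
        fq = self.food_quotient if fq is None else fq
        if not 0.7 < fq < 1.0:
            raise ValueError(f"food quotient must lie in (0.7, 1.0), got {fq}")
        return self.weir_intercept + self.weir_slope / fq


@dataclass(frozen=True)
class CutPoints:
    """Per-minute vector-magnitude cut points (counts/min).

    MVPA is VM >= ``mvpa_lo``; light is ``light_lo`` <= VM < ``mvpa_lo``;
    everything below ``light_lo`` is sedentary+nonwear.  The three
    classes tile every possible VM value.
    """

    mvpa_lo: float = 2690.0
    light_lo: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.light_lo < self.mvpa_lo:
            raise ValueError(
                f"require 0 < light_lo < mvpa_lo, got {self.light_lo}, {self.mvpa_lo}"
            )


@dataclass(frozen=True)
class WearParams:
    """Non-wear detection parameters (minutes).

    A run of at least ``window_min`` consecutive zero-VM minutes,
    tolerating interruptions of at most ``spike_tolerance_min``
    consecutive non-zero minutes, is marked non-wear.
    """

    window_min: int = 90
    spike_tolerance_min: int = 2

    def __post_init__(self) -> None:
        if self.window_min < 1 or self.spike_tolerance_min < 0:
            raise ValueError("window_min >= 1 and spike_tolerance_min >= 0 required")


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all tunables, YAML round-trippable for provenance."""

    constants: DLWConstants = field(default_factory=DLWConstants)
    cutpoints: CutPoints = field(default_factory=CutPoints)
    wear: WearParams = field(default_factory=WearParams)
    negative_fm_policy: str = "warn"  # "warn" (pass through) or "clamp"
    output_sigfigs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.negative_fm_policy not in ("warn", "clamp"):
            raise ValueError("negative_fm_policy must be 'warn' or 'clamp'")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("constants", DLWConstants),
            ("cutpoints", CutPoints),
            ("wear", WearParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


DEFAULT_CONSTANTS = DLWConstants()
DEFAULT_CUTPOINTS = CutPoints()
DEFAULT_WEAR = WearParams()
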