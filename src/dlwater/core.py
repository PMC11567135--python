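"""Two-pool doubly-labelled-water (DLW) computations.

The chain implemented here converts the four kinetic quantities of a
DLW measurement — deuterium and oxygen-18 dilution spaces (ND, NO; mol)
and elimination rates (kD, kO; per day) — into body composition, CO2
production, total energy expenditure (TEE) and water turnover (WT):

    Ncorr = (ND/1.043 + NO/1.007) / 2            corrected pool, mol
    TBW   = Ncorr * 0.01802                      total body water, kg
    FFM   = TBW / 0.732                          fat-free mass, kg
    FM    = body mass - FFM                      fat mass, kg
    delta = 1.007*kO - 1.043*kD                  net isotope divergence
    rGF   = 1.05 * Ncorr * delta                 fractionated gaseous loss
    rCO2  = (Ncorr/2.078)*delta - 0.0246*rGF     mol/day -> *22.26 L/day
    TEE   = rCO2_L * (1.106 + 3.94/FQ)           kcal/day
    WT    = 0.01802 * 1.043 * kD * ND / 0.99     litres/day

All functions accept scalars or numpy arrays and carry out no rounding;
display rounding happens only at I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONSTANTS, DLWConstants

__all__ = [
    "IsotopeSummary",
    "BodyComposition",
    "EnergyWater",
    "PhysiologicallyInvalidError",
    "CohortSchemaError",
    "dilution_space_ratio",
    "corrected_n",
    "body_composition",
    "rco2",
    "tee",
    "water_turnover",
    "process_participant",
    "process_cohort",
]

#: typical range of the dilution-space ratio ND/NO in adults
_RATIO_RANGE = (1.00, 1.08)

DERIVED_COLUMNS = [
    "Ncorr_mol",
    "TBW_kg",
    "FFM_kg",
    "FM_kg",
    "fat_pct",
    "rCO2_mol_day",
    "rCO2_L_day",
    "TEE_kcal_day",
    "WT_L_day",
    "FQ",
]


class PhysiologicallyInvalidError(ValueError):
    """Raised when 1.007*kO <= 1.043*kD, which would imply rCO2 <= 0."""


class CohortSchemaError(ValueError):
    """Raised on malformed cohort inputs; carries itemised problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class IsotopeSummary:
    """The four kinetic quantities driving all downstream physiology."""

    ND: float
    NO: float
    kD: float
    kO: float

    def __post_init__(self) -> None:
        for name in ("ND", "NO", "kD", "kO"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        ratio = self.ND / self.NO
        if not _RATIO_RANGE[0] <= ratio <= _RATIO_RANGE[1]:
            warnings.warn(
                f"dilution-space ratio ND/NO = {ratio:.4f} outside the "
                f"typical range {_RATIO_RANGE}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BodyComposition:
    Ncorr: float  # corrected dilution space, mol
    TBW: float  # total body water, kg (== litres)
    FFM: float  # fat-free mass, kg
    FM: float  # fat mass, kg
    fat_pct: float


@dataclass(frozen=True)
class EnergyWater:
    rCO2_mol: float  # CO2 production, mol/day
    rCO2_L: float  # CO2 production, L/day
    TEE: float  # total energy expenditure, kcal/day
    WT: float  # water turnover, L/day
    FQ: float  # food quotient used


def dilution_space_ratio(nd, no):
    """ND/NO, dimensionless; typically 1.00-1.08 in adults."""
    no = np.asarray(no, dtype=float)
    if np.any(no <= 0):
        raise ValueError("NO must be strictly positive")
    return np.asarray(nd, dtype=float) / no


def corrected_n(nd, no, constants: DLWConstants = DEFAULT_CONSTANTS):
    """Corrected dilution space Ncorr = (ND/1.043 + NO/1.007)/2, mol.

    Each space is first deflated by its known overestimate of the body
    water pool, then the two independent estimates are averaged.
    """
    nd = np.asarray(nd, dtype=float)
    no = np.asarray(no, dtype=float)
    if np.any(nd <= 0) or np.any(no <= 0):
        raise ValueError("ND and NO must be strictly positive")
    return (nd / constants.nd_pool_excess + no / constants.no_pool_excess) / 2.0


def body_composition(
    body_mass,
    nd,
    no,
    constants: DLWConstants = DEFAULT_CONSTANTS,
    clamp_negative_fm: bool = False,
):
    """Body composition from the two dilution spaces.

    TBW = Ncorr*0.01802; FFM = TBW/0.732; FM = body mass - FFM.
    Negative fat mass (possible when rounded inputs meet a very lean
    subject) passes through with a warning unless *clamp_negative_fm*.
    """
    ncorr = corrected_n(nd, no, constants)
    tbw = ncorr * constants.kg_per_mol_water
    ffm = tbw / constants.hydration_constant
    fm = np.asarray(body_mass, dtype=float) - ffm
    if np.any(fm < 0):
        warnings.warn("negative fat mass computed (FFM exceeds body mass)", stacklevel=2)
        if clamp_negative_fm:
            fm = np.maximum(fm, 0.0)
    fat_pct = 100.0 * fm / np.asarray(body_mass, dtype=float)
    if np.ndim(ncorr) == 0:
        return BodyComposition(
            float(ncorr), float(tbw), float(ffm), float(fm), float(fat_pct)
        )
    return BodyComposition(ncorr, tbw, ffm, fm, fat_pct)


def _delta(kd, ko, constants: DLWConstants):
    """Net isotope divergence 1.007*kO - 1.043*kD (per day)."""
    return constants.no_pool_excess * np.asarray(ko, float) - (
        constants.nd_pool_excess * np.asarray(kd, float)
    )


def rco2(ncorr, kd, ko, constants: DLWConstants = DEFAULT_CONSTANTS):
    """Two-pool CO2 production rate.

    Returns ``(rCO2_mol, rCO2_L)`` in mol/day and L/day.  The second
    term subtracts the isotopic effect of fractionated gaseous water
    loss, rGF = 1.05*Ncorr*delta, weighted by 0.0246.
    """
    d = _delta(kd, ko, constants)
    if np.any(d <= 0):
        raise PhysiologicallyInvalidError(
            f"1.007*kO must exceed 1.043*kD for positive CO2 production "
            f"(kD={kd!r}, kO={ko!r})"
        )
    ncorr = np.asarray(ncorr, dtype=float)
    rgf = constants.gaseous_frac_scale * ncorr * d
    mol = (ncorr / constants.rco2_pool_divisor) * d - constants.gaseous_frac_coeff * rgf
    litres = constants.litres_per_mol_co2 * mol
    return mol, litres


def tee(rco2_litres, fq: float | None = None, constants: DLWConstants = DEFAULT_CONSTANTS):
    """TEE (kcal/day) from CO2 production in litres/day.

    Energy equivalent per litre CO2 is the Weir-type 1.106 + 3.94/FQ
    (5.687 kcal/L at the default food quotient 0.86).
    """
    return np.asarray(rco2_litres, dtype=float) * constants.energy_equiv_kcal_per_litre(fq)


def water_turnover(kd, nd, constants: DLWConstants = DEFAULT_CONSTANTS):
    """Water turnover (litres/day) from deuterium kinetics.

    WT = 0.01802 * 1.043 * kD * ND / 0.99; the division by 0.99 undoes
    isotopic fractionation of the deuterium flux.
    """
    kd = np.asarray(kd, dtype=float)
    nd = np.asarray(nd, dtype=float)
    if np.any(kd <= 0) or np.any(nd <= 0):
        raise ValueError("kD and ND must be strictly positive")
    return (
        constants.kg_per_mol_water
        * constants.nd_pool_excess
        * kd
        * nd
        / constants.wt_fractionation
    )


def process_participant(
    body_mass: float,
    iso: IsotopeSummary,
    constants: DLWConstants = DEFAULT_CONSTANTS,
    fq: float | None = None,
    clamp_negative_fm: bool = False,
) -> tuple[BodyComposition, EnergyWater]:
    """Full chain for one participant."""
    bc = body_composition(body_mass, iso.ND, iso.NO, constants, clamp_negative_fm)
    mol, litres = rco2(bc.Ncorr, iso.kD, iso.kO, constants)
    fq_used = constants.food_quotient if fq is None else fq
    ew = EnergyWater(
        rCO2_mol=float(mol),
        rCO2_L=float(litres),
        TEE=float(tee(litres, fq_used, constants)),
        WT=float(water_turnover(iso.kD, iso.ND, constants)),
        FQ=fq_used,
    )
    return bc, ew


PARTICIPANT_COLUMNS = ["participant_id", "community", "age_y", "sex", "body_mass_kg"]
ISOTOPE_COLUMNS = ["participant_id", "ND_mol", "NO_mol", "kD_perday", "kO_perday"]


def process_cohort(
    participants: pd.DataFrame,
    isotopes: pd.DataFrame,
    constants: DLWConstants = DEFAULT_CONSTANTS,
    fq: float | None = None,
    clamp_negative_fm: bool = False,
) -> pd.DataFrame:
    """Join participant and isotope tables and derive all DLW outputs.

    Returns one row per participant with the input columns plus
    ``DERIVED_COLUMNS``.  Rows with invalid isotope values are dropped
    with a warning identifying the participant; structural problems
    (missing columns, duplicate or unmatched ids) raise
    :class:`CohortSchemaError` listing every violation.
    """
    problems = []
    for df, cols, name in (
        (participants, PARTICIPANT_COLUMNS, "participants"),
        (isotopes, ISOTOPE_COLUMNS, "isotopes"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            problems.append(f"{name} table missing columns {missing}")
    if problems:
        raise CohortSchemaError(problems)

    for df, name in ((participants, "participants"), (isotopes, "isotopes")):
        dupes = df["participant_id"][df["participant_id"].duplicated()].tolist()
        if dupes:
            problems.append(f"duplicated participant_id in {name}: {sorted(set(dupes))}")
    unmatched = set(participants["participant_id"]) ^ set(isotopes["participant_id"])
    if unmatched and len(participants) and len(isotopes):
        problems.append(f"participant_id not present in both tables: {sorted(unmatched)}")
    if problems:
        raise CohortSchemaError(problems)

    merged = participants.merge(isotopes, on="participant_id", how="inner")
    if merged.empty:
        warnings.warn("empty cohort input; returning empty derived table", stacklevel=2)
        return merged.reindex(columns=list(merged.columns) + DERIVED_COLUMNS)

    fq_used = constants.food_quotient if fq is None else fq
    rows = []
    for _, row in merged.iterrows():
        try:
            iso = IsotopeSummary(
                ND=row["ND_mol"], NO=row["NO_mol"], kD=row["kD_perday"], kO=row["kO_perday"]
            )
            bc, ew = process_participant(
                row["body_mass_kg"], iso, constants, fq_used, clamp_negative_fm
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(
                f"participant {row['participant_id']!r} rejected: {exc}", stacklevel=2
            )
            continue
        out = row.to_dict()
        out.update(
            Ncorr_mol=bc.Ncorr,
            TBW_kg=bc.TBW,
            FFM_kg=bc.FFM,
            FM_kg=bc.FM,
            fat_pct=bc.fat_pct,
            rCO2_mol_day=ew.rCO2_mol,
            rCO2_L_day=ew.rCO2_L,
            TEE_kcal_day=ew.TEE,
            WT_L_day=ew.WT,
            FQ=ew.FQ,
        )
        rows.append(out)
    derived = pd.DataFrame(rows)
    return derived.reset_index(drop=True)
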