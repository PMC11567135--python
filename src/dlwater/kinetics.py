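"""Slope-intercept estimation of isotope elimination kinetics.

After an oral dose of doubly labelled water, the excess enrichment of
each tracer in body water decays mono-exponentially,

    excess(t) = A * exp(-k t),

so ordinary least squares of ln(excess) on time (days) yields the
elimination rate k = -slope and the zero-time intercept A = exp(b0).
The dilution space N follows from the dose: the intercept is the moles
of tracer administered diluted into N moles of body water, hence
N = n_tracer / A with A expressed as mole-fraction excess.

The canonical internal enrichment unit is mole-fraction excess above
the participant's own pre-dose baseline; ppm-excess inputs are
converted via a declared unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ISOTOPES",
    "MOLAR_MASS_G",
    "DoseRecord",
    "EliminationFit",
    "EliminationModel",
    "InsufficientDataError",
    "InvalidSampleError",
    "fit_elimination",
    "dilution_space_from_dose",
]

ISOTOPES = ("2H", "18O")

#: molar mass (g/mol) of the labelled water species carrying each tracer
MOLAR_MASS_G = {"2H": 20.0231, "18O": 20.0148}  # 2H2O, H2-18O

_UNIT_TO_MOLE_FRACTION = {"mole_fraction": 1.0, "ppm": 1e-6}


class InsufficientDataError(ValueError):
    """Fewer than two usable post-dose samples."""


class InvalidSampleError(ValueError):
    """A sample violates the washout preconditions; names the offender."""


@dataclass(frozen=True)
class DoseRecord:
    """Mass and composition of the administered dose water.

    Defaults follow the common field protocol: ~80 g of water at 6%
    2H2O and 10% H2-18O by mass.
    """

    dose_mass_g: float = 80.0
    frac_2h2o: float = 0.06
    frac_h218o: float = 0.10

    def __post_init__(self) -> None:
        if not self.dose_mass_g > 0:
            raise ValueError("dose_mass_g must be positive")
        for name in ("frac_2h2o", "frac_h218o"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def tracer_moles(self, isotope: str) -> float:
        """Moles of the labelled water species given for *isotope*."""
        frac = {"2H": self.frac_2h2o, "18O": self.frac_h218o}[isotope]
        return self.dose_mass_g * frac / MOLAR_MASS_G[isotope]


@dataclass(frozen=True)
class EliminationFit:
    """Result of a log-linear washout fit for one participant x isotope."""

    isotope: str
    k: float  # elimination rate, per day
    intercept_excess: float  # extrapolated excess enrichment at t=0
    fit_r2: float
    n_points: int
    N: float | None = None  # dilution space, mol (set from the dose)

    def summary(self) -> str:
        lines = [
            f"Elimination fit ({self.isotope})",
            f"  k              {self.k:.6g} /day",
            f"  intercept      {self.intercept_excess:.6g} (excess)",
            f"  R^2            {self.fit_r2:.6f}",
            f"  n points       {self.n_points}",
        ]
        if self.N is not None:
            lines.append(f"  dilution space {self.N:.6g} mol")
        return "\n".join(lines)


class EliminationModel:
    """Log-linear washout model for one participant and one isotope.

    Parameters
    ----------
    samples : pandas.DataFrame
        Columns ``time_days``, ``enrichment``, ``is_baseline`` for a
        single participant x isotope.  Exactly one baseline sample is
        expected; multiple baselines are averaged with a warning.
    isotope : str
        ``"2H"`` or ``"18O"``.
    """

    def __init__(self, samples: pd.DataFrame, isotope: str):
        if isotope not in ISOTOPES:
            raise ValueError(f"isotope must be one of {ISOTOPES}, got {isotope!r}")
        self.isotope = isotope

        base = samples[samples["is_baseline"].astype(bool)]
        post = samples[~samples["is_baseline"].astype(bool)]
        if base.empty:
            raise InvalidSampleError(f"no baseline sample for isotope {isotope}")
        if len(base) > 1:
            warnings.warn(
                f"{len(base)} baseline samples for isotope {isotope}; averaging",
                stacklevel=2,
            )
        self.baseline = float(base["enrichment"].mean())

        t = post["time_days"].to_numpy(dtype=float)
        e = post["enrichment"].to_numpy(dtype=float)
        if np.any(t <= 0):
            bad = t[t <= 0]
            raise InvalidSampleError(
                f"post-dose sample times must be strictly positive, got {bad.tolist()}"
            )
        excess = e - self.baseline
        if np.any(excess <= 0):
            bad = t[excess <= 0].tolist()
            raise InvalidSampleError(
                f"non-positive excess enrichment at time(s) {bad} days "
                f"(enrichment must exceed baseline after the dose)"
            )
        if len(t) < 2:
            raise InsufficientDataError(
                f"need >= 2 post-dose samples to fit a slope, got {len(t)}"
            )
        self.time_days = t
        self.excess = excess

    def fit(self) -> EliminationFit:
        """Unweighted OLS of ln(excess) on time; k = -slope."""
        y = np.log(self.excess)
        slope, intercept = np.polyfit(self.time_days, y, 1)
        yhat = slope * self.time_days + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        k = -float(slope)
        if k <= 0:
            warnings.warn(
                f"non-positive elimination rate fitted for {self.isotope} "
                f"(k = {k:.4g}/day); the washout is not decaying",
                stacklevel=2,
            )
        return EliminationFit(
            isotope=self.isotope,
            k=k,
            intercept_excess=float(np.exp(intercept)),
            fit_r2=r2,
            n_points=len(self.time_days),
        )


def fit_elimination(samples: pd.DataFrame, isotope: str) -> EliminationFit:
    """Slope-intercept fit; see :class:`EliminationModel`."""
    return EliminationModel(samples, isotope).fit()


def dilution_space_from_dose(
    fit: EliminationFit,
    dose: DoseRecord,
    enrichment_unit: str = "mole_fraction",
) -> EliminationFit:
    """Fill the dilution space N (mol) from the dose and the intercept.

    N = moles of tracer administered / intercept excess (mole fraction).
    """
    if enrichment_unit not in _UNIT_TO_MOLE_FRACTION:
        raise ValueError(
            f"unknown enrichment unit {enrichment_unit!r}; "
            f"declare one of {sorted(_UNIT_TO_MOLE_FRACTION)}"
        )
    if not fit.intercept_excess > 0:
        raise ValueError("intercept excess must be positive to infer a dilution space")
    intercept_mf = fit.intercept_excess * _UNIT_TO_MOLE_FRACTION[enrichment_unit]
    n = dose.tracer_moles(fit.isotope) / intercept_mf
    return replace(fit, N=n)
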