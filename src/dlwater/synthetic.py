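"""Synthetic cohorts, isotope washout curves and accelerometer streams.

Every generator is a pure function of (seed, config) and carries its
ground truth alongside, so each pipeline stage can be tested without
any external data.  The cohort generator works backwards through the
DLW equations: it draws body composition, energy expenditure and water
turnover first, then solves for the isotope quantities (ND, NO, kD,
kO) that make the forward pipeline reproduce the truth exactly.

Default distribution parameters emulate a small East-African pastoralist
cohort: sex-specific body mass around 52.5 kg (men) and 49.2 kg
(women), body fat around 14% and 25%, an allometric lnTEE model with
an FFM exponent of 1.33, and water turnover rising with TEE around a
7.4 L/day mean.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .accel import _runs
from .config import DEFAULT_CONSTANTS, DLWConstants
from .kinetics import DoseRecord

__all__ = [
    "CohortGenConfig",
    "CohortTruth",
    "AccelProfile",
    "generate_cohort",
    "generate_enrichment_series",
    "generate_cohort_enrichment",
    "generate_accel_stream",
    "participant_rng",
]

#: natural-abundance mole fractions of the tracers in body water
BACKGROUND_MOLE_FRACTION = {"2H": 0.00015576, "18O": 0.0020052}


def participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Per-participant substream: one global seed fans out via a stable hash."""
    return np.random.default_rng([seed, zlib.crc32(participant_id.encode())])


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class CohortGenConfig:
    """Distributional truth of the synthetic cohort.

    ``lnTEE_*`` define the generative allometric model
    lnTEE = b0 + bFFM*lnFFM + bFM*lnFM + bsex*[male] + noise, and
    ``wt_*`` the turnover model WT = a0 + a1*TEE + noise (L/day).
    """

    p_female: float = 19 / 34
    communities: tuple[str, ...] = ("Illeret", "El Bokoch", "Roto")
    community_probs: tuple[float, ...] = (12 / 34, 12 / 34, 10 / 34)
    age_mean: float = 32.0
    age_sd: float = 9.0
    age_bounds: tuple[float, float] = (18.0, 60.0)
    mass_mean: dict = field(default_factory=lambda: {"M": 52.5, "F": 49.2})
    mass_sd: float = 5.0
    mass_bounds: tuple[float, float] = (39.0, 65.0)
    fat_mean: dict = field(default_factory=lambda: {"M": 14.0, "F": 25.0})
    fat_sd: dict = field(default_factory=lambda: {"M": 6.0, "F": 8.0})
    fat_bounds: tuple[float, float] = (4.5, 37.6)
    lnTEE_intercept: float = 3.35
    lnTEE_lnFFM: float = 1.33
    lnTEE_lnFM: float = -0.16
    lnTEE_sexM: float = -0.22
    lnTEE_noise_sd: float = 0.14
    wt_intercept: float = 3.07
    wt_per_kcal: float = 0.002
    wt_noise_sd: float = 1.8
    wt_floor: float = 2.0
    ratio_mean: float = 1.041
    ratio_sd: float = 0.008
    ratio_bounds: tuple[float, float] = (1.00, 1.07)

    def __post_init__(self) -> None:
        if not 0 < self.p_female < 1:
            raise ValueError("p_female must lie in (0, 1)")
        if len(self.communities) != len(self.community_probs):
            raise ValueError("communities and community_probs must align")
        for mean, (lo, hi) in ((self.fat_mean["M"], self.fat_bounds),
                               (self.fat_mean["F"], self.fat_bounds)):
            if not lo < mean < hi:
                raise ValueError("fat% truncation bounds exclude the mean")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth plus the exact input tables the pipeline consumes."""

    truth: pd.DataFrame
    participants: pd.DataFrame
    isotopes: pd.DataFrame
    seed: int
    config: CohortGenConfig


def generate_cohort(
    n: int,
    seed: int,
    config: CohortGenConfig = CohortGenConfig(),
    constants: DLWConstants = DEFAULT_CONSTANTS,
) -> CohortTruth:
    """Draw a cohort and back-solve the isotope quantities.

    The returned isotope table is exactly invertible: running the
    forward DLW chain on it reproduces the drawn FFM, TEE and WT to
    machine precision.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    c = config

    sex = np.where(rng.random(n) < c.p_female, "F", "M")
    community = rng.choice(c.communities, size=n, p=c.community_probs)
    age = _truncnorm(rng, c.age_mean, c.age_sd, *c.age_bounds, size=n)
    mass = np.empty(n)
    fat = np.empty(n)
    for s in ("M", "F"):
        m = sex == s
        mass[m] = _truncnorm(rng, c.mass_mean[s], c.mass_sd, *c.mass_bounds, size=m.sum())
        fat[m] = _truncnorm(rng, c.fat_mean[s], c.fat_sd[s], *c.fat_bounds, size=m.sum())

    ffm = mass * (1 - fat / 100)
    fm = mass - ffm
    ln_tee = (
        c.lnTEE_intercept
        + c.lnTEE_lnFFM * np.log(ffm)
        + c.lnTEE_lnFM * np.log(fm)
        + c.lnTEE_sexM * (sex == "M")
        + rng.normal(0, c.lnTEE_noise_sd, n)
    )
    tee = np.exp(ln_tee)
    wt = np.maximum(
        c.wt_intercept + c.wt_per_kcal * tee + rng.normal(0, c.wt_noise_sd, n),
        c.wt_floor,
    )

    # invert the DLW chain
    tbw = ffm * constants.hydration_constant
    ncorr = tbw / constants.kg_per_mol_water
    ratio = _truncnorm(rng, c.ratio_mean, c.ratio_sd, *c.ratio_bounds, size=n)
    no = 2 * ncorr / (ratio / constants.nd_pool_excess + 1 / constants.no_pool_excess)
    nd = ratio * no
    kd = (
        wt
        * constants.wt_fractionation
        / (constants.kg_per_mol_water * constants.nd_pool_excess * nd)
    )
    rco2_l = tee / constants.energy_equiv_kcal_per_litre()
    rco2_mol = rco2_l / constants.litres_per_mol_co2
    pool = ncorr * (
        1 / constants.rco2_pool_divisor
        - constants.gaseous_frac_coeff * constants.gaseous_frac_scale
    )
    delta = rco2_mol / pool
    ko = (delta + constants.nd_pool_excess * kd) / constants.no_pool_excess

    pid = [f"S{i + 1:04d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "community": community,
            "age_y": np.round(age, 1),
            "sex": sex,
            "body_mass_kg": mass,
            "fat_pct": fat,
            "FFM_kg": ffm,
            "FM_kg": fm,
            "TEE_kcal_day": tee,
            "WT_L_day": wt,
            "Ncorr_mol": ncorr,
            "ND_mol": nd,
            "NO_mol": no,
            "kD_perday": kd,
            "kO_perday": ko,
        }
    )
    participants = truth[["participant_id", "community", "age_y", "sex", "body_mass_kg"]]
    isotopes = truth[["participant_id", "ND_mol", "NO_mol", "kD_perday", "kO_perday"]]
    return CohortTruth(truth, participants.copy(), isotopes.copy(), seed, c)


DEFAULT_SCHEDULE_DAYS = (0.25, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)


def generate_enrichment_series(
    participant_id: str,
    k: float,
    N: float,
    isotope: str,
    schedule_days=DEFAULT_SCHEDULE_DAYS,
    noise_sd: float = 0.0,
    seed: int = 0,
    dose: DoseRecord = DoseRecord(),
    baseline_time_days: float = -0.0625,
) -> pd.DataFrame:
    """Mono-exponential washout samples for one participant x isotope.

    excess(t) = A e^(-k t) with A = tracer moles / N (mole-fraction
    excess over natural background); measurement noise is
    multiplicative log-normal with log-scale *noise_sd* on post-dose
    samples.  The baseline sample sits ~1.5 h pre-dose at natural
    abundance.
    """
    schedule = np.asarray(schedule_days, dtype=float)
    if len(schedule) < 2:
        raise ValueError("schedule needs at least two post-dose times")
    if np.any(schedule <= 0):
        raise ValueError("post-dose times must be strictly positive")
    rng = participant_rng(seed, f"{participant_id}:{isotope}")
    background = BACKGROUND_MOLE_FRACTION[isotope]
    amp = dose.tracer_moles(isotope) / N
    excess = amp * np.exp(-k * schedule)
    if noise_sd > 0:
        excess = excess * np.exp(rng.normal(0, noise_sd, len(schedule)))
    rows = [
        {
            "participant_id": participant_id,
            "isotope": isotope,
            "time_days": baseline_time_days,
            "enrichment": background,
            "enrichment_unit": "mole_fraction",
            "is_baseline": 1,
        }
    ]
    rows += [
        {
            "participant_id": participant_id,
            "isotope": isotope,
            "time_days": t,
            "enrichment": background + e,
            "enrichment_unit": "mole_fraction",
            "is_baseline": 0,
        }
        for t, e in zip(schedule, excess)
    ]
    return pd.DataFrame(rows)


def generate_cohort_enrichment(
    truth: CohortTruth,
    schedule_days=DEFAULT_SCHEDULE_DAYS,
    noise_sd: float = 0.0,
    dose: DoseRecord = DoseRecord(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Washout curves for every participant and both isotopes.

    Returns (enrichment table, dose table) in the CSV schemas the
    kinetics stage reads.
    """
    frames = []
    for _, row in truth.truth.iterrows():
        for isotope, kcol, ncol in (("2H", "kD_perday", "ND_mol"),
                                    ("18O", "kO_perday", "NO_mol")):
            frames.append(
                generate_enrichment_series(
                    row["participant_id"], row[kcol], row[ncol], isotope,
                    schedule_days, noise_sd, truth.seed, dose,
                )
            )
    doses = pd.DataFrame(
        {
            "participant_id": truth.truth["participant_id"],
            "dose_g": dose.dose_mass_g,
            "frac_2H2O": dose.frac_2h2o,
            "frac_H218O": dose.frac_h218o,
        }
    )
    return pd.concat(frames, ignore_index=True), doses


@dataclass(frozen=True)
class AccelProfile:
    """Daily activity composition for the accelerometer generator.

    Minutes per class per day; everything not light/MVPA/non-wear is
    sedentary.  VM ranges are kept a safe margin inside the cut points
    so integer rounding cannot move a minute across a class boundary.
    """

    mvpa_min: int = 40
    light_min: int = 240
    nonwear_min: int = 0
    steps_per_mvpa_min: int = 110
    steps_per_light_min: int = 45
    mvpa_vm: tuple[float, float] = (3000.0, 6000.0)
    light_vm: tuple[float, float] = (300.0, 2400.0)
    sed_vm_hi: float = 150.0
    start: str = "2022-06-20"

    def __post_init__(self) -> None:
        if self.mvpa_min + self.light_min + self.nonwear_min > 1440:
            raise ValueError("profile exceeds 1440 minutes per day")
        if self.nonwear_min and not self.nonwear_min >= 1:
            raise ValueError("nonwear_min must be non-negative")


_AXIS_UNIT = np.array([0.8, 0.53, 0.27]) / np.linalg.norm([0.8, 0.53, 0.27])


def _minute_layout(profile: AccelProfile) -> tuple[np.ndarray, np.ndarray]:
    """Class label per minute of one day, bout-structured, plus nonwear flag."""
    classes = np.zeros(1440, dtype=int)  # 0 sed, 1 light, 2 mvpa
    nonwear = np.zeros(1440, dtype=bool)
    cursor = 60  # non-wear block starts 01:00
    if profile.nonwear_min:
        nonwear[cursor : cursor + profile.nonwear_min] = True
        cursor += profile.nonwear_min
    # activity during "daytime": interleave light and MVPA bouts from 07:00
    cursor = max(cursor, 7 * 60)
    light_left, mvpa_left = profile.light_min, profile.mvpa_min
    while (light_left or mvpa_left) and cursor < 1440:
        if mvpa_left:
            b = min(10, mvpa_left, 1440 - cursor)
            classes[cursor : cursor + b] = 2
            mvpa_left -= b
            cursor += b + 5  # sedentary gap between bouts
        if light_left and cursor < 1440:
            b = min(20, light_left, 1440 - cursor)
            classes[cursor : cursor + b] = 1
            light_left -= b
            cursor += b + 5
    if light_left or mvpa_left:
        raise ValueError("profile minutes do not fit in the day with bout gaps")
    return classes, nonwear


def generate_accel_stream(
    days: int,
    profile: AccelProfile = AccelProfile(),
    seed: int = 0,
    participant_id: str = "S0001",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bout-structured 10 s triaxial count stream with per-day truth.

    Per-day class minutes and steps match the profile exactly; VM
    levels within each class are drawn uniformly inside the class
    range.  Sedentary minutes are mostly zero-VM but a small movement
    minute is forced at least every 10 minutes so that only the
    labelled non-wear block forms a long zero run.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = participant_rng(seed, f"{participant_id}:accel")
    records = []
    truth_rows = []
    t0 = pd.Timestamp(profile.start)
    for d in range(days):
        classes, nonwear = _minute_layout(profile)
        vm = np.zeros(1440)
        sed = (classes == 0) & ~nonwear
        # low-level movement blocks in sedentary time, longer than the
        # wear-marking spike tolerance so only labelled non-wear forms
        # a long zero run
        mover: list[int] = []
        for lo, hi, val in _runs(sed):
            if val:
                for off in range(lo, hi, 10):
                    mover.extend(range(off, min(off + 3, hi)))
        vm[mover] = rng.uniform(20, profile.sed_vm_hi, len(mover))
        vm[classes == 1] = rng.uniform(*profile.light_vm, (classes == 1).sum())
        vm[classes == 2] = rng.uniform(*profile.mvpa_vm, (classes == 2).sum())
        vm[nonwear] = 0.0
        steps = np.zeros(1440, dtype=int)
        steps[classes == 1] = profile.steps_per_light_min
        steps[classes == 2] = profile.steps_per_mvpa_min
        axes_min = np.round(vm[:, None] * _AXIS_UNIT).astype(int)
        day_start = t0 + pd.Timedelta(days=d)
        # split each minute into six 10 s epochs conserving counts and steps
        base = axes_min // 6
        rem = axes_min - base * 6
        sbase, srem = steps // 6, steps - (steps // 6) * 6
        for e in range(6):
            ax = base + (rem > e)
            st = sbase + (srem > e)
            idx = day_start + pd.to_timedelta(np.arange(1440) * 60 + e * 10, unit="s")
            records.append(
                pd.DataFrame(
                    {"timestamp": idx, "axis1": ax[:, 0], "axis2": ax[:, 1],
                     "axis3": ax[:, 2], "steps": st}
                )
            )
        truth_rows.append(
            {
                "date": day_start.date(),
                "mvpa_min": int((classes == 2).sum()),
                "light_min": int((classes == 1).sum()),
                "sed_nonwear_min": int(((classes == 0) | nonwear).sum()),
                "nonwear_min": int(nonwear.sum()),
                "steps": int(steps.sum()),
            }
        )
    stream = (
        pd.concat(records, ignore_index=True)
        .sort_values("timestamp")
        .set_index("timestamp")
    )
    return stream, pd.DataFrame(truth_rows)
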