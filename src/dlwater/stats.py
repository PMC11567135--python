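"""Cohort-level statistics for DLW outputs.

Ordinary least squares of ln-transformed energy expenditure (and of
water turnover) on body-composition covariates, residual-based
adjustment with one-way ANOVA, rank tests, group summaries, and
screening of individuals against an external reference regression via
95% prediction intervals.

The modelling surface follows the Model/Results convention: build a
:class:`CohortModel` from a spec and a derived cohort table, call
``fit()``, and read estimates off the returned :class:`FitResult`.
OLS itself is delegated to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import yaml

__all__ = [
    "ModelSpec",
    "CohortModel",
    "FitResult",
    "AnovaResult",
    "ReferenceModel",
    "prepare_regression_frame",
    "fit_model",
    "residual_adjust_anova",
    "kruskal_wallis",
    "group_summaries",
]

DEFAULT_REFERENCE_LEVELS = {
    "sex": "F",
    "community": "Illeret",
    "population": "Daasanach",
}

_CATEGORICAL = ("sex", "community", "population")

#: derived-table column behind each modelling variable
_SOURCE_COLUMNS = {
    "TEE": "TEE_kcal_day",
    "WT": "WT_L_day",
    "FFM": "FFM_kg",
    "FM": "FM_kg",
    "age": "age_y",
    "sex": "sex",
    "community": "community",
    "population": "population",
    "steps": "steps",
    "MVPA": "MVPA_min",
}


def prepare_regression_frame(derived: pd.DataFrame) -> pd.DataFrame:
    """Build the modelling frame from a derived cohort table.

    Adds natural-log transforms lnTEE, lnFFM, lnFM; any non-positive
    value under a log raises, naming the participant.  FM comes from
    the pipeline (body mass - FFM), never from an external source.
    """
    out = pd.DataFrame(index=derived.index)
    if "participant_id" in derived.columns:
        out.index = pd.Index(derived["participant_id"], name="participant_id")
    for var, col in _SOURCE_COLUMNS.items():
        if col in derived.columns:
            out[var] = derived[col].to_numpy()
    for var in ("TEE", "FFM", "FM"):
        if var in out.columns:
            bad = out.index[out[var] <= 0].tolist()
            if bad:
                raise ValueError(
                    f"cannot log-transform {var}: non-positive value for {bad}"
                )
            out[f"ln{var}"] = np.log(out[var].astype(float))
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A regression specification: response ~ predictors.

    Categorical predictors (sex, community, population) are
    dummy-coded against the declared reference level.
    """

    response: str
    predictors: tuple[str, ...]
    reference_levels: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS)
    )

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictors must be non-empty")
        object.__setattr__(self, "predictors", tuple(self.predictors))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        refs = dict(DEFAULT_REFERENCE_LEVELS)
        refs.update(d.get("reference_levels", {}))
        return cls(d["response"], tuple(d["predictors"]), refs)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def label(self) -> str:
        return f"{self.response} ~ {' + '.join(self.predictors)}"


def _design_matrix(spec: ModelSpec, frame: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for pred in spec.predictors:
        if pred not in frame.columns:
            raise KeyError(f"predictor {pred!r} not present in the cohort frame")
        if pred in _CATEGORICAL:
            levels = pd.unique(frame[pred].astype(str))
            ref = str(spec.reference_levels.get(pred, levels[0]))
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} for {pred!r} not among observed "
                    f"levels {sorted(levels)}"
                )
            for lev in [l for l in levels if l != ref]:
                cols[f"{pred}[{lev}]"] = (frame[pred].astype(str) == lev).astype(float)
        else:
            cols[pred] = frame[pred].astype(float)
    X = pd.DataFrame(cols, index=frame.index)
    X.insert(0, "intercept", 1.0)
    return X


@dataclass
class FitResult:
    """OLS estimates with uncertainties and per-participant residuals."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    nobs: int
    resid: pd.Series
    sm_results: object  # statsmodels RegressionResults

    def tidy(self) -> pd.DataFrame:
        """Coefficient table: term, estimate, se, p."""
        return pd.DataFrame(
            {"term": self.params.index, "estimate": self.params.to_numpy(),
             "se": self.bse.to_numpy(), "p": self.pvalues.to_numpy()}
        )

    def summary(self) -> str:
        rows = [
            f"{t:<24s} {e:>10.4f} ({s:.4f})  p={p:.4g}"
            for t, e, s, p in zip(self.params.index, self.params, self.bse, self.pvalues)
        ]
        return "\n".join(
            [self.spec.label(), "-" * 48, *rows, "-" * 48,
             f"n = {self.nobs}   R^2 = {self.rsquared:.4f}   "
             f"adj. R^2 = {self.rsquared_adj:.4f}"]
        )

    def residual_anova(self, groups: pd.Series) -> "AnovaResult":
        return residual_adjust_anova(self, groups)


class CohortModel:
    """OLS model of a cohort regression frame under a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, frame: pd.DataFrame):
        self.spec = spec
        needed = [spec.response, *spec.predictors]
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise KeyError(f"cohort frame lacks columns {missing}")
        complete = frame[needed].dropna()
        self.frame = complete
        self.X = _design_matrix(spec, complete)
        self.y = complete[spec.response].astype(float)
        p = self.X.shape[1]
        if len(complete) < p + 1:
            raise ValueError(
                f"need at least {p + 1} complete rows to fit {p} terms, "
                f"got {len(complete)}"
            )
        rank = np.linalg.matrix_rank(self.X.to_numpy())
        if rank < p:
            collinear = [
                c
                for c in self.X.columns
                if np.linalg.matrix_rank(self.X.drop(columns=c).to_numpy()) == rank
            ]
            raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")

    @classmethod
    def from_derived(cls, spec: ModelSpec, derived: pd.DataFrame) -> "CohortModel":
        return cls(spec, prepare_regression_frame(derived))

    def fit(self) -> FitResult:
        res = sm.OLS(self.y.to_numpy(), self.X.to_numpy()).fit()
        idx = self.X.columns
        return FitResult(
            spec=self.spec,
            params=pd.Series(res.params, index=idx),
            bse=pd.Series(res.bse, index=idx),
            pvalues=pd.Series(res.pvalues, index=idx),
            rsquared=float(res.rsquared),
            rsquared_adj=float(res.rsquared_adj),
            nobs=int(res.nobs),
            resid=pd.Series(res.resid, index=self.frame.index),
            sm_results=res,
        )


def fit_model(spec: ModelSpec, derived: pd.DataFrame) -> FitResult:
    """Fit *spec* on a derived cohort table (convenience wrapper)."""
    return CohortModel.from_derived(spec, derived).fit()


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def residual_adjust_anova(fit: FitResult, groups: pd.Series) -> AnovaResult:
    """One-way ANOVA of model residuals across *groups*.

    The residuals represent the response adjusted for everything in the
    fitted model; the ANOVA then asks whether the grouping explains any
    of what remains.
    """
    groups = groups.reindex(fit.resid.index)
    if groups.isna().any():
        missing = groups.index[groups.isna()].tolist()
        raise ValueError(f"no group label for residual rows {missing}")
    arrays = [fit.resid[groups == g].to_numpy() for g in pd.unique(groups)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups for an ANOVA")
    small = [g for g, a in zip(pd.unique(groups), arrays) if len(a) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")
    F, p = scipy.stats.f_oneway(*arrays)
    return AnovaResult(
        F=float(F),
        df_between=len(arrays) - 1,
        df_within=int(len(fit.resid) - len(arrays)),
        p=float(p),
    )


def kruskal_wallis(values, labels) -> tuple[float, int, float]:
    """Rank-based Kruskal-Wallis H with tie correction.

    Returns ``(H, df, p)`` with df = number of groups - 1.  If every
    observation is identical the statistic is 0 by convention (warned).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    df = len(uniq) - 1
    if np.all(values == values[0]):
        warnings.warn("all observations identical; H = 0", stacklevel=2)
        return 0.0, df, 1.0
    H, p = scipy.stats.kruskal(*samples)
    return float(H), df, float(p)


@dataclass(frozen=True)
class ReferenceModel:
    """An external reference regression used for individual screening.

    Carries named coefficients (key ``"intercept"`` plus covariate
    terms such as ``lnFFM``, ``lnFM``, ``age``, ``sex[M]``), the
    residual standard deviation, the reference sample size, and
    optionally the full coefficient covariance matrix.  With the
    covariance the 95% prediction interval uses the exact half-width
    sqrt(s^2 + x' V x); without it, the mean-covariate approximation
    s * sqrt(1 + 1/n).
    """

    response: str
    coefficients: dict
    resid_sd: float
    n: int
    covariance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if "intercept" not in self.coefficients:
            raise ValueError("coefficients must include an 'intercept' entry")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")

    @classmethod
    def from_fit(cls, fit: FitResult, with_covariance: bool = True) -> "ReferenceModel":
        """Snapshot a fitted cohort model as a reference for screening."""
        res = fit.sm_results
        cov = None
        if with_covariance:
            cov = pd.DataFrame(
                np.asarray(res.cov_params()), index=fit.params.index,
                columns=fit.params.index,
            )
        return cls(
            response=fit.spec.response,
            coefficients=dict(fit.params),
            resid_sd=float(np.sqrt(res.mse_resid)),
            n=fit.nobs,
            covariance=cov,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ReferenceModel":
        d = yaml.safe_load(text)
        cov = d.get("covariance")
        if cov is not None:
            terms = list(d["coefficients"])
            cov = pd.DataFrame(np.asarray(cov, dtype=float), index=terms, columns=terms)
        return cls(d["response"], dict(d["coefficients"]), float(d["resid_sd"]),
                   int(d["n"]), cov)

    @property
    def terms(self) -> list[str]:
        return [t for t in self.coefficients if t != "intercept"]

    def _row_design(self, row: pd.Series) -> np.ndarray | None:
        x = [1.0]
        for term in self.terms:
            if "[" in term:  # dummy term like sex[M]
                var, lev = term[:-1].split("[")
                if var not in row or pd.isna(row[var]):
                    return None
                x.append(float(str(row[var]) == lev))
            else:
                if term not in row or pd.isna(row[term]):
                    return None
                x.append(float(row[term]))
        return np.asarray(x)

    def predict_with_interval(
        self, frame: pd.DataFrame, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Point estimate, 95% PI and inside/below/above flag per row.

        Rows missing a covariate are skipped with a warning.  If the
        observed response column is present the flag compares it to the
        interval; a zero-residual reference collapses the interval onto
        the point estimate.
        """
        beta = np.asarray([self.coefficients["intercept"]]
                          + [self.coefficients[t] for t in self.terms])
        dof = max(self.n - len(beta), 1)
        tcrit = scipy.stats.t.ppf(1 - alpha / 2, dof)
        records, skipped = [], []
        for idx, row in frame.iterrows():
            x = self._row_design(row)
            if x is None:
                skipped.append(idx)
                continue
            point = float(x @ beta)
            if self.covariance is not None:
                var = self.resid_sd**2 + float(x @ self.covariance.to_numpy() @ x)
            else:
                var = self.resid_sd**2 * (1 + 1 / self.n)
            half = tcrit * np.sqrt(var)
            rec = {"row": idx, "point": point, "pi_lo": point - half, "pi_hi": point + half}
            if self.response in frame.columns and not pd.isna(row[self.response]):
                obs = float(row[self.response])
                rec["observed"] = obs
                rec["flag"] = (
                    "below" if obs < rec["pi_lo"]
                    else "above" if obs > rec["pi_hi"]
                    else "inside"
                )
            records.append(rec)
        if skipped:
            warnings.warn(f"rows skipped for missing covariates: {skipped}", stacklevel=2)
        return pd.DataFrame(records).set_index("row") if records else pd.DataFrame()


def group_summaries(
    derived: pd.DataFrame, by: list[str], values: list[str] | None = None
) -> pd.DataFrame:
    """Arithmetic means and SDs of *values* within groups defined by *by*.

    Single-member groups report an NA standard deviation.
    """
    if values is None:
        values = [
            c for c in ("TEE_kcal_day", "WT_L_day", "FFM_kg", "fat_pct",
                        "body_mass_kg", "steps", "MVPA_min")
            if c in derived.columns
        ]
    g = derived.groupby(by, observed=True)[values]
    out = g.agg(["mean", "std", "count"])
    out.columns = [f"{v}_{stat}" for v, stat in out.columns]
    return out.reset_index()
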