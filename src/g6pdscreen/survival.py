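"""Diabetic-retinopathy survival contrasts by predicted-deficiency stratum.

Time runs in years from diabetes diagnosis to incident retinopathy, with
right censoring at death or end of follow-up.  Screening strata come from
the decision rule: for each criterion (possible, likely) a separate Cox
proportional-hazards model contrasts participants meeting the criterion
against its complement, adjusting for age, sex, smoking, diabetes
duration, LDL cholesterol and hypertension.  Cumulative incidence at a
horizon (default 20 years) is 1 - S(t) from the Kaplan-Meier
product-limit estimator, not a crude proportion, because censoring is
ubiquitous in EHR follow-up.  The absolute risk difference between a
screening stratum and its reference converts to a number needed to harm
(NNH = 1 / risk difference).

Ties are handled with Efron's approximation by default (year-resolution
event times tie often); Breslow is available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "COVARIATES",
    "CoxResult",
    "SurvivalSummary",
    "km_cumulative_incidence",
    "cox_fit",
    "risk_difference_and_nnh",
    "summarize_survival",
]

COVARIATES = ["age", "sex_male", "smoking", "diabetes_duration", "ldl", "hypertension"]


def km_cumulative_incidence(time, event, horizon: float = 20.0) -> float:
    """Kaplan-Meier cumulative incidence 1 - S(horizon) with right censoring.

    If the largest observed time precedes the horizon the last estimate is
    carried forward with a warning.  Degenerate input (everyone censored
    at time zero) raises ``ValueError``.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if t.size == 0 or np.all(t <= 0):
        raise ValueError("no follow-up time to estimate from")
    if t.max() < horizon:
        warnings.warn(
            f"largest observed time {t.max():.3g} < horizon {horizon:g}; "
            "carrying the last Kaplan-Meier estimate forward",
            stacklevel=2,
        )
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    s = float(kmf.predict(min(horizon, t.max())))
    return 1.0 - s


@dataclass(frozen=True)
class CoxResult:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    n: int
    n_events: int


def cox_fit(
    df: pd.DataFrame,
    duration_col: str = "time_years",
    event_col: str = "event",
    covariates: Optional[list[str]] = None,
    tie_method: str = "efron",
) -> dict[str, CoxResult]:
    """Cox proportional-hazards fit; per-term HR, Wald 95% CI and p-value.

    Partial-likelihood maximisation with Efron (default) or Breslow tie
    handling.  Constant covariates and single-class event columns are
    rejected up front; non-convergence surfaces as a diagnostic error.
    """
    covariates = list(covariates) if covariates is not None else COVARIATES
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method: {tie_method!r}")
    if int(df[event_col].sum()) < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant; drop it from the formula")
    exog = df[covariates].astype(float)
    model = PHReg(
        df[duration_col].to_numpy(dtype=float),
        exog,
        status=df[event_col].to_numpy(dtype=int),
        ties=tie_method,
    )
    try:
        res = model.fit()
    except Exception as exc:  # convergence/separation diagnostics
        raise RuntimeError(f"Cox partial-likelihood fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise RuntimeError(
            "Cox fit did not converge to finite estimates (possible separation); "
            f"params={res.params}"
        )
    z975 = 1.959963984540054
    out = {}
    for i, term in enumerate(covariates):
        coef, se = float(res.params[i]), float(res.bse[i])
        out[term] = CoxResult(
            term=term,
            hr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - z975 * se)),
            ci_high=float(np.exp(coef + z975 * se)),
            p=float(res.pvalues[i]),
            coef=coef,
            se=se,
            n=int(len(df)),
            n_events=int(df[event_col].sum()),
        )
    return out


def risk_difference_and_nnh(
    rate_exposed: float, rate_reference: float
) -> tuple[float, Optional[float]]:
    """Absolute risk difference and its reciprocal, the number needed to harm.

    Rates are proportions in [0, 1].  NNH is defined only for a positive
    risk difference; otherwise ``None`` is returned (an explicit flag, not
    a coerced value).  Callers round NNH for display; full precision is
    returned here.
    """
    for name, r in (("rate_exposed", rate_exposed), ("rate_reference", rate_reference)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {r}")
    rd = rate_exposed - rate_reference
    nnh = 1.0 / rd if rd > 0 else None
    return rd, nnh


@dataclass
class SurvivalSummary:
    horizon: float
    incidence: dict = field(default_factory=dict)  # stratum -> 1 - S(horizon)
    hazard_ratios: dict = field(default_factory=dict)  # criterion -> CoxResult
    risk_difference: dict = field(default_factory=dict)  # criterion -> (rd, nnh)

    def as_dict(self) -> dict:
        return {
            "horizon_years": self.horizon,
            "km_cumulative_incidence_pct": {
                k: 100.0 * v for k, v in self.incidence.items()
            },
            "hazard_ratios": {
                k: {
                    "hr": v.hr,
                    "ci95": [v.ci_low, v.ci_high],
                    "p": v.p,
                    "n": v.n,
                    "n_events": v.n_events,
                }
                for k, v in self.hazard_ratios.items()
            },
            "risk_difference_pct": {
                k: 100.0 * rd for k, (rd, _) in self.risk_difference.items()
            },
            "nnh": {
                k: (round(nnh) if nnh is not None else None)
                for k, (_, nnh) in self.risk_difference.items()
            },
        }


def summarize_survival(
    records: pd.DataFrame,
    horizon: float = 20.0,
    covariates: Optional[list[str]] = None,
    tie_method: str = "efron",
) -> SurvivalSummary:
    """The full survival stage for a screened diabetic cohort.

    ``records`` needs time_years, event, boolean possible/likely flags and
    the adjustment covariates.  Each criterion is contrasted against its
    own complement in a separate adjusted Cox model; reported Kaplan-Meier
    incidences are per stratum, with "general" the complement of the
    possible criterion (the broadest reference).
    """
    covariates = list(covariates) if covariates is not None else COVARIATES
    out = SurvivalSummary(horizon=horizon)
    strata = {
        "possible": records["possible"].astype(bool),
        "likely": records["likely"].astype(bool),
    }
    out.incidence["general"] = km_cumulative_incidence(
        records.loc[~strata["possible"], "time_years"],
        records.loc[~strata["possible"], "event"],
        horizon,
    )
    for criterion, mask in strata.items():
        out.incidence[criterion] = km_cumulative_incidence(
            records.loc[mask, "time_years"], records.loc[mask, "event"], horizon
        )
        df = records.copy()
        df["exposed"] = mask.astype(int)
        fit = cox_fit(
            df,
            covariates=["exposed"] + covariates,
            tie_method=tie_method,
        )
        out.hazard_ratios[criterion] = fit["exposed"]
        reference = km_cumulative_incidence(
            records.loc[~mask, "time_years"], records.loc[~mask, "event"], horizon
        )
        out.risk_difference[criterion] = risk_difference_and_nnh(
            out.incidence[criterion], reference
        )
    return out
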