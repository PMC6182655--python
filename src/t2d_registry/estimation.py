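"""Estimators: stratified incidence rates with 95% CIs, period prevalence,
annual percent change by log-linear Poisson regression, interrupted time
series with a slope-change test, and Cox proportional-hazards models.

Rates are cases per ``rate_scale`` (default 100,000) person-years. The
default confidence interval is the log-normal interval
``rate × exp(±z/√cases)`` — the standard large-sample interval for a log
rate — with an exact Poisson (chi-square) interval available; for zero
cases no interval is reported. Trend models are Poisson GLMs with a log
person-years offset, so on noise-free log-linear (or piecewise log-linear)
expected counts they interpolate the generating slopes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._dates import add_years, year_start
from .config import StudyConfig

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class RateEstimate:
    stratum: tuple
    cases: int
    person_years: float
    rate: float
    ci_low: float | None
    ci_high: float | None


@dataclass(frozen=True)
class PrevalenceEstimate:
    calendar_year: int
    numerator: int
    denominator: int
    proportion: float


@dataclass(frozen=True)
class TrendFit:
    """Annual percent change (and, for ITS, per-segment slopes).

    ``apc`` is 100·(exp(β)−1) for the yearly log-linear slope β. For an
    interrupted time series, ``pre_slope_apc`` / ``post_slope_apc`` are the
    annualised slopes before and after the break and ``slope_change_p`` the
    Wald p value for the slope-change coefficient.
    """

    apc: float
    ci_low: float
    ci_high: float
    pre_slope_apc: float | None = None
    post_slope_apc: float | None = None
    slope_change_p: float | None = None
    params: dict = field(default_factory=dict)


def rate_with_ci(
    cases: int,
    person_years: float,
    config: StudyConfig | None = None,
    method: str = "lognormal",
    stratum: tuple = (),
) -> RateEstimate:
    """Incidence (or mortality, etc.) rate per ``rate_scale`` person-years."""
    cfg = config or StudyConfig()
    if person_years <= 0:
        raise ValueError("person_years must be > 0")
    if cases < 0:
        raise ValueError("cases must be >= 0")
    rate = cases / person_years * cfg.rate_scale
    if cases == 0:
        return RateEstimate(stratum, 0, person_years, 0.0, None, None)
    if method == "lognormal":
        f = math.exp(cfg.ci_z / math.sqrt(cases))
        lo, hi = rate / f, rate * f
    elif method == "exact":
        alpha = 2 * (1 - stats.norm.cdf(cfg.ci_z))
        lo = stats.chi2.ppf(alpha / 2, 2 * cases) / 2 / person_years * cfg.rate_scale
        hi = (
            stats.chi2.ppf(1 - alpha / 2, 2 * cases + 2)
            / 2
            / person_years
            * cfg.rate_scale
        )
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return RateEstimate(stratum, int(cases), person_years, rate, lo, hi)


def rates_table(
    strata: pd.DataFrame,
    by: list[str] | tuple[str, ...] | None = None,
    config: StudyConfig | None = None,
    method: str = "lognormal",
) -> pd.DataFrame:
    """Vectorised :func:`rate_with_ci` over a cases/person-years table."""
    cfg = config or StudyConfig()
    df = strata.copy()
    if by:
        df = (
            df.groupby(list(by), observed=True)[["cases", "person_years"]]
            .sum()
            .reset_index()
        )
    ests = [
        rate_with_ci(int(r.cases), float(r.person_years), cfg, method)
        for r in df.itertuples()
    ]
    df["rate"] = [e.rate for e in ests]
    df["ci_low"] = [e.ci_low for e in ests]
    df["ci_high"] = [e.ci_high for e in ests]
    return df


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def period_prevalence(
    persons: pd.DataFrame,
    met_dates: pd.Series,
    year: int,
    config: StudyConfig | None = None,
) -> PrevalenceEstimate:
    """Period prevalence for one calendar year.

    The denominator counts persons alive, resident and aged 30–89 at some
    time during the year; the numerator those of them whose case criteria
    were met in that year or earlier.
    """
    cfg = config or StudyConfig()
    if not cfg.study_start.year <= year <= cfg.prevalence_end.year:
        raise ValueError(f"year {year} outside the study period")
    jan1 = pd.Timestamp(year=year, month=1, day=1)
    dec31 = pd.Timestamp(year=year, month=12, day=31)

    birth_min = add_years(persons["birth_date"], cfg.min_age_years)
    birth_max = add_years(persons["birth_date"], cfg.max_age_years)
    in_age = (birth_min <= dec31) & (birth_max > jan1)
    alive = persons["death_date"].isna() | (persons["death_date"] >= jan1)
    arrived = persons["immigration_date"].isna() | (
        persons["immigration_date"] <= dec31
    )
    not_left = persons["emigration_date"].isna() | (
        persons["emigration_date"] > jan1
    )
    denom_mask = (in_age & alive & arrived & not_left).to_numpy()

    met = met_dates.reindex(persons["person_id"]).to_numpy()
    num_mask = denom_mask & pd.notna(met) & (met <= np.datetime64(dec31))
    denominator = int(denom_mask.sum())
    numerator = int(num_mask.sum())
    proportion = numerator / denominator if denominator else float("nan")
    return PrevalenceEstimate(year, numerator, denominator, proportion)


def prevalence_series(
    persons: pd.DataFrame,
    met_dates: pd.Series,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    cfg = config or StudyConfig()
    years = range(cfg.study_start.year, cfg.prevalence_end.year + 1)
    rows = [period_prevalence(persons, met_dates, y, cfg) for y in years]
    return pd.DataFrame(
        {
            "calendar_year": [r.calendar_year for r in rows],
            "numerator": [r.numerator for r in rows],
            "denominator": [r.denominator for r in rows],
            "proportion": [r.proportion for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# trends
# ---------------------------------------------------------------------------


def poisson_apc(
    yearly: pd.DataFrame, config: StudyConfig | None = None
) -> TrendFit:
    """Annual percent change from a log-linear Poisson model.

    ``yearly`` holds one row per calendar year with columns
    ``calendar_year``, ``cases`` and ``person_years`` (positive). The model
    is ``log E[cases] = α + β·year + log(person_years)``;
    APC = 100·(exp(β)−1) with a Wald CI.
    """
    cfg = config or StudyConfig()
    df = yearly.dropna(subset=["cases", "person_years"])
    df = df[df["person_years"] > 0]
    if len(df) < 2:
        raise ValueError("need at least two years with positive exposure")
    if (df["cases"] < 0).any() or df["cases"].sum() == 0:
        raise ValueError("cases must be non-negative and not all zero")
    t = df["calendar_year"].to_numpy(dtype=float)
    t = t - t.min()
    X = sm.add_constant(t)
    fit = sm.GLM(
        df["cases"].to_numpy(dtype=float),
        X,
        family=sm.families.Poisson(),
        offset=np.log(df["person_years"].to_numpy(dtype=float)),
    ).fit()
    beta = fit.params[1]
    se = fit.bse[1]
    z = cfg.ci_z
    return TrendFit(
        apc=100.0 * math.expm1(beta),
        ci_low=100.0 * math.expm1(beta - z * se),
        ci_high=100.0 * math.expm1(beta + z * se),
        params={"beta": beta, "se": se, "intercept": fit.params[0]},
    )


def monthly_periods(config: StudyConfig | None = None) -> pd.DatetimeIndex:
    """Month starts spanning the incidence period (closing edge included)."""
    cfg = config or StudyConfig()
    return pd.date_range(
        cfg.study_start,
        cfg.incidence_follow_up_end + pd.Timedelta(days=1),
        freq="MS",
    )


def its_fit(
    periods: pd.DataFrame,
    break_date,
    config: StudyConfig | None = None,
    level_change: bool = False,
) -> TrendFit:
    """Segmented Poisson regression with a slope change at ``break_date``.

    ``periods`` holds one row per (monthly or quarterly) period with
    columns ``period_start``, ``period_end`` (exclusive), ``cases`` and
    ``person_years``. Time is coded at the period midpoint in years; the
    model is ``log E[cases] = α + β₁·t + β₂·(t−t_b)⁺ [+ γ·1(t≥t_b)]
    + log(py)``. Reported are the annualised pre- and post-break slopes
    and the Wald p value for β₂.
    """
    cfg = config or StudyConfig()
    break_date = pd.Timestamp(break_date)
    df = periods[periods["person_years"] > 0].copy()
    start = pd.to_datetime(df["period_start"])
    end = pd.to_datetime(df["period_end"])
    mid = start + (end - start) / 2
    origin = mid.min()
    t = ((mid - origin) / pd.Timedelta(days=1) / DAYS_PER_YEAR).to_numpy()
    tb = (break_date - origin) / pd.Timedelta(days=1) / DAYS_PER_YEAR
    if not (t.min() < tb < t.max()):
        raise ValueError("break_date outside the observed period span")
    if (t < tb).sum() < 3 or (t >= tb).sum() < 3:
        raise ValueError("need at least three periods on each side of the break")

    cols = [np.ones_like(t), t, np.clip(t - tb, 0.0, None)]
    names = ["const", "t", "slope_change"]
    if level_change:
        cols.append((t >= tb).astype(float))
        names.append("level_change")
    X = np.column_stack(cols)
    fit = sm.GLM(
        df["cases"].to_numpy(dtype=float),
        X,
        family=sm.families.Poisson(),
        offset=np.log(df["person_years"].to_numpy(dtype=float)),
    ).fit()
    b1, b2 = fit.params[1], fit.params[2]
    se1 = fit.bse[1]
    z = cfg.ci_z
    wald = b2 / fit.bse[2]
    p = 2 * (1 - stats.norm.cdf(abs(wald)))
    return TrendFit(
        apc=100.0 * math.expm1(b1),
        ci_low=100.0 * math.expm1(b1 - z * se1),
        ci_high=100.0 * math.expm1(b1 + z * se1),
        pre_slope_apc=100.0 * math.expm1(b1),
        post_slope_apc=100.0 * math.expm1(b1 + b2),
        slope_change_p=float(p),
        params=dict(zip(names, fit.params)),
    )


def aggregate_periods(
    windows: pd.DataFrame,
    cases: pd.DataFrame,
    period_starts: pd.DatetimeIndex,
) -> pd.DataFrame:
    """Cases and person-years per period, for :func:`its_fit`."""
    from .cohort import person_time_by_period

    pt = person_time_by_period(windows, period_starts)
    starts = pd.DatetimeIndex(period_starts)
    onset = pd.to_datetime(cases["onset_date"])
    binned = pd.cut(onset, bins=starts, right=False, labels=starts[:-1])
    counts = binned.value_counts().sort_index()
    pt["cases"] = counts.reindex(starts[:-1]).fillna(0).astype(int).to_numpy()
    pt["period_end"] = starts[1:]
    return pt[["period_start", "period_end", "cases", "person_years"]]


# ---------------------------------------------------------------------------
# hazard ratios
# ---------------------------------------------------------------------------


def build_cox_frame(
    windows: pd.DataFrame,
    cases: pd.DataFrame,
    persons: pd.DataFrame,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """One row per person: follow-up duration, event flag, fixed covariates."""
    cfg = config or StudyConfig()
    df = windows.merge(
        persons[
            ["person_id", "sex", "birth_date", "education_level", "place_of_birth"]
        ],
        on="person_id",
        how="left",
    )
    df["duration_years"] = (
        (df["exit_date"] - df["entry_date"]).dt.days / DAYS_PER_YEAR
    )
    df["event"] = df["person_id"].isin(cases["person_id"]).astype(int)
    decade = (df["birth_date"].dt.year // 10 * 10).astype(int)
    df["birth_cohort"] = decade.astype(str) + "-" + (decade + 9).astype(str)
    df["entry_age"] = (
        (df["entry_date"] - df["birth_date"]).dt.days / DAYS_PER_YEAR
    )
    df["exit_age"] = df["entry_age"] + df["duration_years"]
    return df[
        [
            "person_id",
            "duration_years",
            "event",
            "sex",
            "birth_cohort",
            "education_level",
            "place_of_birth",
            "entry_age",
            "exit_age",
        ]
    ]


_REFERENCE_LEVELS = {
    "sex": "male",
    "birth_cohort": "1980-1989",
    "education_level": "high",
    "place_of_birth": "Norway",
}


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str] | tuple[str, ...],
    config: StudyConfig | None = None,
    time_scale: str = "follow_up",
    exclude_levels: dict[str, tuple[str, ...]] | None = None,
    penalizer: float = 0.0,
) -> pd.DataFrame:
    """Proportional-hazards model; returns tidy hazard-ratio estimates.

    ``covariates`` are categorical columns of ``data`` (see
    :func:`build_cox_frame`); reference levels follow the descriptive
    tables (male, 1980s birth cohort, high education, born in Norway).
    ``time_scale`` is "follow_up" (duration since entry) or "age" (delayed
    entry at the entry age, exit at the exit age). Missing-education
    persons are excluded from education contrasts by default. Covariate
    levels with no events (separation) are reported as non-estimable
    (NaN); if the partial likelihood still fails to converge, a weakly
    ridge-penalised fit is used and logged.
    """
    import logging

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cfg = config or StudyConfig()
    exclude_levels = exclude_levels or {"education_level": ("missing",)}
    df = data.copy()
    for cov in covariates:
        for lev in exclude_levels.get(cov, ()):
            df = df[df[cov] != lev]

    if time_scale == "follow_up":
        duration = df["duration_years"]
        entry = None
    elif time_scale == "age":
        duration = df["exit_age"]
        entry = df["entry_age"]
    else:
        raise ValueError("time_scale must be 'follow_up' or 'age'")
    keep = duration > (entry if entry is not None else 0)
    df = df[keep]

    events = df["event"].astype(bool)
    design = pd.DataFrame(index=df.index)
    name_map: list[tuple[str, str, str]] = []  # (column, covariate, level)
    dropped: list[tuple[str, str]] = []
    for cov in covariates:
        ref = _REFERENCE_LEVELS.get(cov)
        for lev in (l for l in sorted(df[cov].astype(str).unique()) if l != ref):
            mask = df[cov].astype(str) == lev
            # no events inside (or outside) a level: its log-HR is not
            # identified by the partial likelihood
            if not (mask & events).any() or not (~mask & events).any():
                dropped.append((cov, lev))
                continue
            col = f"{cov}[{lev}]"
            design[col] = mask.astype(float)
            name_map.append((col, cov, lev))

    if time_scale == "follow_up":
        design["duration"] = df["duration_years"].to_numpy()
        entry_col = None
    else:
        design["duration"] = df["exit_age"].to_numpy()
        design["entry"] = df["entry_age"].to_numpy()
        entry_col = "entry"
    design["event"] = df["event"].to_numpy()

    def _fit(pen):
        cph = CoxPHFitter(penalizer=pen)
        cph.fit(design, duration_col="duration", event_col="event", entry_col=entry_col)
        return cph

    try:
        cph = _fit(penalizer)
    except ConvergenceError:
        logging.getLogger(__name__).warning(
            "Cox partial likelihood did not converge; refitting with a weak "
            "ridge penalty (0.01)"
        )
        cph = _fit(max(penalizer, 0.01))

    rows = []
    for col, cov, lev in name_map:
        b = float(cph.params_[col])
        se = float(cph.standard_errors_[col])
        rows.append(
            {
                "covariate": cov,
                "level": lev,
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - cfg.ci_z * se)),
                "ci_high": float(np.exp(b + cfg.ci_z * se)),
            }
        )
    for cov, lev in dropped:
        rows.append(
            {
                "covariate": cov,
                "level": lev,
                "hr": float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
            }
        )
    for cov in covariates:
        ref = _REFERENCE_LEVELS.get(cov)
        if ref is not None and (df[cov].astype(str) == ref).any():
            rows.append(
                {"covariate": cov, "level": ref, "hr": 1.0, "ci_low": None, "ci_high": None}
            )
    out = pd.DataFrame(rows)
    out["adjustment"] = "+".join(covariates)
    return out
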