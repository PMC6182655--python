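import math

import numpy as np
import pandas as pd
import pytest

from conftest import person_row
from helpers_oracle import oracle_cox_loglik
from t2d_registry import (
    StudyConfig,
    cox_fit,
    its_fit,
    period_prevalence,
    poisson_apc,
    prevalence_series,
    rate_with_ci,
    rates_table,
)

# published national-cohort counts and person-years (arithmetic inputs) with
# the rates and 95% CIs they print to one decimal
TABLE_ROWS = [
    ("all", 75_496, 15_463_691, 488.2, 484.7, 491.7),
    ("male", 43_888, 7_642_520, 574.3, 568.9, 579.7),
    ("female", 31_608, 7_821_171, 404.1, 399.7, 408.6),
    ("born_1910s", 28, 4_327, 647.1, 446.8, 937.2),
    ("born_1920s", 5_038, 658_818, 764.7, 743.9, 786.1),
    ("edu_low", 26_057, 3_488_171, 747.0, 738.0, 756.1),
    ("edu_medium", 35_083, 6_702_359, 523.4, 518.0, 528.9),
    ("edu_high", 13_146, 4_944_843, 265.9, 261.3, 270.4),
    ("born_norway", 65_479, 13_565_793, 482.7, 479.0, 486.4),
    ("born_asia", 4_224, 486_508, 868.2, 842.4, 894.8),
]


@pytest.mark.parametrize("label,cases,py,rate,lo,hi", TABLE_ROWS)
def test_lognormal_interval_reproduces_published_rates(label, cases, py, rate, lo, hi):
    est = rate_with_ci(cases, py)
    assert round(est.rate, 1) == rate
    assert round(est.ci_low, 1) == lo
    assert round(est.ci_high, 1) == hi


def test_zero_cases_has_no_interval():
    est = rate_with_ci(0, 1000.0)
    assert est.rate == 0.0
    assert est.ci_low is None and est.ci_high is None


def test_rate_errors():
    with pytest.raises(ValueError):
        rate_with_ci(10, 0.0)
    with pytest.raises(ValueError):
        rate_with_ci(-1, 10.0)
    with pytest.raises(ValueError):
        rate_with_ci(5, 10.0, method="bogus")


def test_scale_equivariance_narrows_interval():
    a = rate_with_ci(50, 10_000.0)
    b = rate_with_ci(100, 20_000.0)
    assert b.rate == pytest.approx(a.rate)
    assert (b.ci_high - b.ci_low) < (a.ci_high - a.ci_low)


def test_exact_poisson_interval_close_to_lognormal_for_large_counts():
    ln = rate_with_ci(75_496, 15_463_691)
    ex = rate_with_ci(75_496, 15_463_691, method="exact")
    assert ex.ci_low == pytest.approx(ln.ci_low, rel=2e-4)
    assert ex.ci_high == pytest.approx(ln.ci_high, rel=2e-4)


def test_rates_table_reaggregates():
    strata = pd.DataFrame(
        {
            "calendar_year": [2009, 2009, 2010, 2010],
            "sex": ["male", "female"] * 2,
            "cases": [10, 20, 15, 25],
            "person_years": [1000.0, 2000.0, 1500.0, 2500.0],
        }
    )
    out = rates_table(strata, by=["calendar_year"])
    assert len(out) == 2
    assert out.loc[out.calendar_year == 2009, "cases"].item() == 30


# ---------------------------------------------------------------------------
# trend models: exact interpolation of noise-free data
# ---------------------------------------------------------------------------


def test_apc_zero_on_constant_rates():
    yearly = pd.DataFrame(
        {
            "calendar_year": range(2009, 2015),
            "cases": [100.0] * 6,
            "person_years": [10_000.0] * 6,
        }
    )
    fit = poisson_apc(yearly)
    assert fit.apc == pytest.approx(0.0, abs=1e-8)


def test_apc_interpolates_exact_log_linear_counts():
    years = np.arange(2009, 2015)
    py = np.array([10_000.0, 11_000, 9_500, 10_500, 9_800, 10_200])
    counts = py * 0.006 * 0.9 ** (years - 2009)
    fit = poisson_apc(
        pd.DataFrame({"calendar_year": years, "cases": counts, "person_years": py})
    )
    assert fit.apc == pytest.approx(-10.0, abs=1e-8)
    assert fit.ci_low < -10.0 < fit.ci_high


def test_apc_input_validation():
    with pytest.raises(ValueError):
        poisson_apc(
            pd.DataFrame({"calendar_year": [2009], "cases": [5], "person_years": [1.0]})
        )
    with pytest.raises(ValueError):
        poisson_apc(
            pd.DataFrame(
                {"calendar_year": [2009, 2010], "cases": [0, 0], "person_years": [1.0, 1.0]}
            )
        )


def _monthly_frame(pre_apc, post_apc, break_date, rate0=0.005, py=50_000.0):
    starts = pd.date_range("2009-01-01", "2014-07-01", freq="MS")
    s1 = math.log1p(pre_apc / 100)
    s2 = math.log1p(post_apc / 100) - s1
    rows = []
    tb = (pd.Timestamp(break_date) - starts[0]) / pd.Timedelta(days=1) / 365.25
    for p0, p1 in zip(starts[:-1], starts[1:]):
        mid = p0 + (p1 - p0) / 2
        t = (mid - starts[0]) / pd.Timedelta(days=1) / 365.25
        mu = py * rate0 * math.exp(s1 * t + s2 * max(0.0, t - tb))
        rows.append(
            {"period_start": p0, "period_end": p1, "cases": mu, "person_years": py}
        )
    return pd.DataFrame(rows)


def test_its_interpolates_exact_piecewise_slopes():
    break_date = "2012-09-01"
    df = _monthly_frame(-12.0, -7.9, break_date)
    fit = its_fit(df, break_date)
    assert fit.pre_slope_apc == pytest.approx(-12.0, abs=1e-6)
    assert fit.post_slope_apc == pytest.approx(-7.9, abs=1e-6)


def test_its_no_slope_change_gives_null_estimate():
    break_date = "2012-09-01"
    df = _monthly_frame(-10.0, -10.0, break_date)
    fit = its_fit(df, break_date)
    assert fit.post_slope_apc == pytest.approx(fit.pre_slope_apc, abs=1e-6)


def test_its_break_validation():
    df = _monthly_frame(-10.0, -10.0, "2012-09-01")
    with pytest.raises(ValueError, match="outside"):
        its_fit(df, "2020-01-01")
    with pytest.raises(ValueError, match="three periods"):
        its_fit(df, "2014-05-15")


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def _prev_persons():
    return pd.DataFrame(
        [
            person_row("P1", birth_date="1950-01-01"),
            person_row("P2", birth_date="1950-01-01", death_date="2012-06-01"),
            person_row("P3", birth_date="1990-01-01"),  # under 30 throughout
        ]
    )


def test_prevalence_counts_cases_from_year_met_onwards(study):
    persons = _prev_persons()
    met = pd.Series(
        [pd.Timestamp("2010-05-01"), pd.NaT, pd.NaT],
        index=pd.Index(["P1", "P2", "P3"], name="person_id"),
    )
    series = prevalence_series(persons, met, study).set_index("calendar_year")
    assert series.loc[2009, "numerator"] == 0
    assert (series.loc[2010:2014, "numerator"] == 1).all()
    # under-30 person never enters the denominator
    assert (series["denominator"] == [2, 2, 2, 2, 1, 1]).all()


def test_prevalence_death_removes_from_denominator(study):
    persons = _prev_persons()
    met = pd.Series(
        [pd.NaT, pd.Timestamp("2009-03-01"), pd.NaT],
        index=pd.Index(["P1", "P2", "P3"], name="person_id"),
    )
    est_2012 = period_prevalence(persons, met, 2012, study)
    assert est_2012.numerator == 1  # dies mid-2012 but was alive in-year
    est_2013 = period_prevalence(persons, met, 2013, study)
    assert est_2013.numerator == 0 and est_2013.denominator == 1


def test_prevalence_no_cases_and_year_range(study):
    persons = _prev_persons()
    met = pd.Series(pd.NaT, index=pd.Index(persons["person_id"], name="person_id"))
    assert period_prevalence(persons, met, 2011, study).proportion == 0.0
    with pytest.raises(ValueError):
        period_prevalence(persons, met, 2015, study)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def _toy_cox_data(n=30, seed=4):
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, n)
    true_beta = 0.7
    durations = rng.exponential(1.0 / np.exp(true_beta * group))
    events = durations < np.quantile(durations, 0.8)
    durations = np.minimum(durations, np.quantile(durations, 0.8))
    return durations, events.astype(int), group


def test_cox_matches_grid_search_oracle():
    durations, events, group = _toy_cox_data()
    df = pd.DataFrame(
        {
            "duration_years": durations,
            "event": events,
            "sex": np.where(group == 1, "female", "male"),
        }
    )
    out = cox_fit(df, ["sex"])
    hr = out.loc[out.level == "female", "hr"].item()

    betas = np.linspace(-3, 3, 12_001)
    lls = [oracle_cox_loglik(durations, events, group, b) for b in betas]
    beta_hat = betas[int(np.argmax(lls))]
    assert math.log(hr) == pytest.approx(beta_hat, abs=5e-4)


def test_cox_null_covariate_gives_unit_hazard_ratio():
    rng = np.random.default_rng(11)
    n = 4000
    group = rng.integers(0, 2, n)
    durations = rng.exponential(2.0, n)
    cens = np.minimum(durations, 3.0)
    events = (durations <= 3.0).astype(int)
    df = pd.DataFrame(
        {
            "duration_years": cens,
            "event": events,
            "sex": np.where(group == 1, "female", "male"),
        }
    )
    out = cox_fit(df, ["sex"])
    row = out[out.level == "female"].iloc[0]
    assert row.ci_low < 1.0 < row.ci_high
    assert row.hr == pytest.approx(1.0, abs=0.1)


def test_cox_reference_levels_and_missing_education_excluded():
    rng = np.random.default_rng(7)
    n = 3000
    df = pd.DataFrame(
        {
            "duration_years": rng.exponential(2.0, n),
            "event": rng.integers(0, 2, n),
            "sex": rng.choice(["male", "female"], n),
            "education_level": rng.choice(["low", "medium", "high", "missing"], n),
        }
    )
    out = cox_fit(df, ["sex", "education_level"])
    assert out.loc[(out.covariate == "sex") & (out.level == "male"), "hr"].item() == 1.0
    assert "missing" not in set(out[out.covariate == "education_level"].level)
    assert set(out[out.covariate == "education_level"].level) == {"low", "medium", "high"}
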