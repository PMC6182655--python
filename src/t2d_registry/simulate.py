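"""Synthetic national-registry simulator.

Generates the four linked registry tables (persons, pharmacy dispensings,
specialist-care and primary-care diagnoses) together with a hidden truth
table of latent onset dates, so every downstream stage — case
ascertainment, person-time accrual and the trend/association estimators —
can be exercised and validated without access to any real data.

Model sketch
------------
* Latent type 2 diabetes onsets follow a piecewise-exponential hazard on
  calendar time: log-linear with a configurable annual percent change,
  optionally with a slope break at the interrupted-time-series break date,
  multiplied by fixed per-person covariate effects (sex, 10-year birth
  cohort, education, place of birth). This is exactly the model family the
  Poisson/ITS/Cox estimators assume, so parameter-recovery tests are
  well-posed.
* Care contacts form a marked point process: a first registration shortly
  after onset, a prompt confirmatory follow-up visit, then repeat visits at
  a constant rate; each visit is routed to primary or specialist care and
  independently recorded per register. Pharmacologically treated cases
  additionally dispense their initial regimen within the treatment window
  and refill it at a fixed interval.
* Prevalent cases at study start have onsets before the study period with
  ongoing care from the start of data availability, so the washout rule has
  real work to do. Mortality and emigration are independent of disease.

The defaults emulate the published national study conditions: a marginal
incidence of about 609 per 100,000 person-years in the reference year 2009
declining about 10% per year, 48% of onsets pharmacologically treated,
initial-regimen shares dominated by metformin monotherapy, and care-routing
parameters calibrated so roughly 26/36/39% of incident cases appear in
one/two/three registers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from ._dates import add_years
from .config import StudyConfig
from .registry import (
    EDUCATION_LEVELS,
    PLACES_OF_BIRTH,
    RegistryBundle,
    empty_bundle,
)

DAYS_PER_YEAR = 365.25

TRUTH_COLUMNS = (
    "person_id",
    "onset_date",
    "registration_date",
    "prevalent_at_start",
    "treated",
    "regimen",
    "unclassifiable_coding",
    "med_without_dx",
)

REGIMENS = ("metformin_mono", "sulfonylurea_mono", "other_oral_mono", "insulin_only", "multi_drug")

_REGIMEN_CODES = {
    "metformin_mono": ("A10BA02",),
    "sulfonylurea_mono": ("A10BB01",),
    "other_oral_mono": ("A10BG03",),
    "insulin_only": ("A10AB01",),
    "multi_drug": ("A10BA02", "A10BB01"),
}
_UNCLASSIFIABLE_SPECIALIST_CODES = ("E10", "E13", "E14")
_UNCLASSIFIABLE_PRIMARY_CODE = "T89"


def _normalised(shares: Mapping[Any, float], what: str) -> dict[Any, float]:
    vals = np.array(list(shares.values()), dtype=float)
    if (vals < 0).any() or vals.sum() <= 0:
        raise ValueError(f"{what}: shares must be non-negative with positive sum")
    return {k: float(v / vals.sum()) for k, v in zip(shares.keys(), vals)}


@dataclass
class Demography:
    """Population structure and vital-event hazards.

    Birth-decade, education and place-of-birth shares default to the
    composition of the published study population; mortality is a Gompertz
    annual hazard (doubling every ~8 years of age), emigration a small
    constant hazard.
    """

    birth_decade_shares: dict[int, float] = field(
        default_factory=lambda: {
            1910: 0.003,
            1920: 0.054,
            1930: 0.081,
            1940: 0.144,
            1950: 0.183,
            1960: 0.218,
            1970: 0.222,
            1980: 0.095,
        }
    )
    female_share: float = 0.50
    education_shares: dict[str, float] = field(
        default_factory=lambda: {"low": 0.229, "medium": 0.419, "high": 0.316, "missing": 0.036}
    )
    place_of_birth_shares: dict[str, float] = field(
        default_factory=lambda: {
            "Norway": 0.851,
            "Europe-excl-Norway": 0.088,
            "Africa": 0.014,
            "Asia": 0.036,
            "North-Central-America": 0.006,
            "South-America": 0.004,
            "Oceania": 0.001,
        }
    )
    recent_immigrant_fraction: float = 0.25  # of the foreign-born, immigrate in-window
    emigration_rate_per_year: float = 0.003
    death_rate_at_30: float = 4.0e-4
    death_rate_doubling_years: float = 8.0

    def validate(self) -> None:
        self.birth_decade_shares = _normalised(self.birth_decade_shares, "birth_decade_shares")
        self.education_shares = _normalised(self.education_shares, "education_shares")
        self.place_of_birth_shares = _normalised(
            self.place_of_birth_shares, "place_of_birth_shares"
        )
        if set(self.education_shares) - set(EDUCATION_LEVELS):
            raise ValueError("education_shares keys must be education levels")
        if set(self.place_of_birth_shares) - set(PLACES_OF_BIRTH):
            raise ValueError("place_of_birth_shares keys must be places of birth")
        if not 0 <= self.female_share <= 1:
            raise ValueError("female_share must be in [0, 1]")
        if not 0 <= self.recent_immigrant_fraction <= 1:
            raise ValueError("recent_immigrant_fraction must be in [0, 1]")
        for name in ("emigration_rate_per_year", "death_rate_at_30"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.death_rate_doubling_years <= 0:
            raise ValueError("death_rate_doubling_years must be > 0")


@dataclass
class DiseaseModel:
    """Latent-onset hazard: log-linear calendar trend times covariate effects.

    ``baseline_rate_per_100k`` is the population-marginal rate in the
    reference year (the per-person intercept is normalised by the mean
    covariate multiplier implied by the demography). ``annual_percent_change``
    is the multiplicative trend (e.g. -10.1 for a 10.1%/year decline);
    ``its_post_annual_percent_change``, when set, replaces the slope after
    the study's interrupted-time-series break date. Covariate log hazard
    ratios default to the published adjusted associations.
    """

    baseline_rate_per_100k: float = 609.0
    reference_year: int = 2009
    annual_percent_change: float = -10.1
    its_post_annual_percent_change: float | None = None
    log_hr_female: float = math.log(0.66)
    log_hr_birth_decade: dict[int, float] = field(
        default_factory=lambda: {
            1910: math.log(8.73),
            1920: math.log(6.60),
            1930: math.log(4.15),
            1940: math.log(2.73),
            1950: math.log(1.98),
            1960: math.log(1.57),
            1970: math.log(1.29),
            1980: 0.0,
        }
    )
    log_hr_education: dict[str, float] = field(
        default_factory=lambda: {
            "low": math.log(2.10),
            "medium": math.log(1.60),
            "high": 0.0,
            "missing": 0.0,
        }
    )
    log_hr_place_of_birth: dict[str, float] = field(
        default_factory=lambda: {
            "Norway": 0.0,
            "Europe-excl-Norway": math.log(1.14),
            "Africa": math.log(2.72),
            "Asia": math.log(3.08),
            "North-Central-America": math.log(1.02),
            "South-America": math.log(1.83),
            "Oceania": math.log(0.76),
        }
    )
    prevalent_fraction_at_start: float = 0.045

    def validate(self) -> None:
        if self.baseline_rate_per_100k < 0:
            raise ValueError("baseline_rate_per_100k must be >= 0")
        if self.annual_percent_change <= -100:
            raise ValueError("annual_percent_change must be > -100")
        if (
            self.its_post_annual_percent_change is not None
            and self.its_post_annual_percent_change <= -100
        ):
            raise ValueError("its_post_annual_percent_change must be > -100")
        if not 0 <= self.prevalent_fraction_at_start < 1:
            raise ValueError("prevalent_fraction_at_start must be in [0, 1)")

    def annual_log_slope(self) -> float:
        return math.log1p(self.annual_percent_change / 100.0)

    def post_break_log_slope_change(self) -> float:
        if self.its_post_annual_percent_change is None:
            return 0.0
        return math.log1p(self.its_post_annual_percent_change / 100.0) - self.annual_log_slope()


@dataclass
class CareModel:
    """How latent onsets surface in the registers.

    Each case is registered shortly after onset, receives a prompt
    confirmatory follow-up visit and then repeat visits at a constant rate;
    every visit is routed to primary care with probability
    ``primary_care_share`` (else specialist care) and recorded in its
    register with the per-register recording probability. Treated cases
    dispense their initial regimen within the treatment window and refill
    at ``refill_interval_days``. A small fraction of onsets carry
    non-specific diabetes coding (never E11/T90) and a small fraction of
    disease-free persons dispense A10 drugs without any diagnosis — the two
    sensitivity-analysis categories.
    """

    treated_fraction: float = 0.48
    prevalent_treated_share: float = 0.764
    regimen_shares: dict[str, float] = field(
        default_factory=lambda: {
            "metformin_mono": 0.826,
            "sulfonylurea_mono": 0.044,
            "other_oral_mono": 0.003,
            "insulin_only": 0.009,
            "multi_drug": 0.110,
        }
    )
    registration_delay_mean_days: float = 14.0
    confirm_visit_mean_days: float = 60.0
    visit_rate_treated: float = 6.0
    visit_rate_untreated: float = 2.0
    primary_care_share: float = 0.93
    record_prob_prescription: float = 1.0
    record_prob_specialist: float = 1.0
    record_prob_primary: float = 1.0
    treatment_delay_max_days: float = 180.0
    refill_interval_days: float = 90.0
    unclassifiable_coding_rate: float = 0.03
    med_without_dx_rate: float = 0.002

    def validate(self) -> None:
        for name in (
            "treated_fraction",
            "prevalent_treated_share",
            "primary_care_share",
            "record_prob_prescription",
            "record_prob_specialist",
            "record_prob_primary",
            "unclassifiable_coding_rate",
            "med_without_dx_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        self.regimen_shares = _normalised(self.regimen_shares, "regimen_shares")
        if set(self.regimen_shares) - set(REGIMENS):
            raise ValueError("regimen_shares keys must be initial regimens")
        for name in (
            "registration_delay_mean_days",
            "confirm_visit_mean_days",
            "visit_rate_treated",
            "visit_rate_untreated",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("treatment_delay_max_days", "refill_interval_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SimulationConfig:
    """Full simulator configuration; same seed and config give identical bytes."""

    n_persons: int = 50_000
    seed: int = 0
    demography: Demography = field(default_factory=Demography)
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    care_model: CareModel = field(default_factory=CareModel)

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        self.demography.validate()
        self.disease_model.validate()
        self.care_model.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "SimulationConfig":
        data = dict(mapping)
        out = cls(
            n_persons=int(data.pop("n_persons", 50_000)),
            seed=int(data.pop("seed", 0)),
            demography=_sub(Demography, data.pop("demography", {})),
            disease_model=_sub(DiseaseModel, data.pop("disease_model", {})),
            care_model=_sub(CareModel, data.pop("care_model", {})),
        )
        if data:
            raise ValueError(f"unknown SimulationConfig keys: {sorted(data)}")
        out.validate()
        return out


def _sub(cls, mapping):
    if isinstance(mapping, cls):
        return mapping
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in mapping:
            val = mapping[f.name]
            if isinstance(val, Mapping) and f.name.endswith("_shares") or (
                isinstance(val, Mapping) and f.name.startswith("log_hr_") and f.name != "log_hr_female"
            ):
                val = {_maybe_int(k): float(v) for k, v in val.items()}
            kwargs[f.name] = val
    return cls(**kwargs)


def _maybe_int(key):
    try:
        return int(key)
    except (TypeError, ValueError):
        return key


def perfect_recording_config(n_persons: int, seed: int) -> SimulationConfig:
    """A limit configuration in which ascertainment is complete.

    No deaths or emigration, every contact recorded, immediate registration,
    a confirmatory visit within days, no non-specific coding and no
    undiagnosed medication users — under this configuration the phenotyping
    algorithm must recover exactly the truth table's incident cases.
    """
    cfg = SimulationConfig(n_persons=n_persons, seed=seed)
    cfg.demography.emigration_rate_per_year = 0.0
    cfg.demography.death_rate_at_30 = 0.0
    cfg.demography.recent_immigrant_fraction = 0.0
    cfg.care_model.record_prob_prescription = 1.0
    cfg.care_model.record_prob_specialist = 1.0
    cfg.care_model.record_prob_primary = 1.0
    cfg.care_model.registration_delay_mean_days = 0.0
    cfg.care_model.confirm_visit_mean_days = 2.0
    cfg.care_model.unclassifiable_coding_rate = 0.0
    cfg.care_model.med_without_dx_rate = 0.0
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


def _first_event_times(
    rng: np.random.Generator, hazard: np.ndarray, horizon_years: float
) -> np.ndarray:
    """First-event time (years from origin) under a per-year-loop hazard.

    ``hazard`` has shape (n, n_years) of annual hazards; returns float years
    (event uniform within its year) or NaN when no event occurs.
    """
    n, n_years = hazard.shape
    p = 1.0 - np.exp(-np.clip(hazard, 0.0, None))
    u = rng.random((n, n_years))
    hit = u < p
    any_hit = hit.any(axis=1)
    first = np.where(any_hit, hit.argmax(axis=1), -1)
    times = np.full(n, np.nan)
    if any_hit.any():
        times[any_hit] = first[any_hit] + rng.random(int(any_hit.sum()))
    times[times > horizon_years] = np.nan
    return times


def generate_population(
    sim_config: SimulationConfig, study_config: StudyConfig | None = None
) -> pd.DataFrame:
    """Draw the persons table: demographics, residency and vital dates."""
    sim_config.validate()
    cfg = study_config or StudyConfig()
    demo = sim_config.demography
    n = sim_config.n_persons
    rng = np.random.default_rng([sim_config.seed, 11])
    if n == 0:
        return empty_bundle().persons

    sim_start = cfg.prescription_start  # events observable from here
    data_end = cfg.prevalence_end
    horizon_years = (data_end - sim_start).days / DAYS_PER_YEAR

    decades = np.array(list(demo.birth_decade_shares.keys()))
    decade = rng.choice(decades, size=n, p=list(demo.birth_decade_shares.values()))
    birth_year = decade + rng.integers(0, 10, size=n)
    birth = pd.to_datetime(pd.DataFrame({"year": birth_year, "month": 1, "day": 1}))
    birth = birth + pd.to_timedelta(rng.integers(0, 365, size=n), unit="D")

    sex = np.where(rng.random(n) < demo.female_share, "female", "male")
    education = rng.choice(
        list(demo.education_shares.keys()), size=n, p=list(demo.education_shares.values())
    )
    place = rng.choice(
        list(demo.place_of_birth_shares.keys()),
        size=n,
        p=list(demo.place_of_birth_shares.values()),
    )

    immigration = pd.Series(pd.NaT, index=range(n))
    foreign = place != "Norway"
    recent = foreign & (rng.random(n) < demo.recent_immigrant_fraction)
    if recent.any():
        offs = rng.random(int(recent.sum())) * (data_end - sim_start).days
        imm = sim_start + pd.to_timedelta(np.floor(offs), unit="D")
        # immigration as an adult only
        adult = add_years(birth[recent], 18).to_numpy()
        immigration[recent] = np.maximum(imm.to_numpy(), adult)

    age_at_start = (sim_start - birth).dt.days.to_numpy() / DAYS_PER_YEAR
    years = np.arange(math.ceil(horizon_years))
    age_matrix = age_at_start[:, None] + years[None, :] + 0.5
    log2 = math.log(2.0)
    death_hazard = demo.death_rate_at_30 * np.exp(
        log2 * (age_matrix - 30.0) / demo.death_rate_doubling_years
    )
    death_t = _first_event_times(rng, death_hazard, horizon_years)
    emig_hazard = np.full_like(age_matrix, demo.emigration_rate_per_year)
    emig_t = _first_event_times(rng, emig_hazard, horizon_years)

    # a person leaves once; whichever event comes first voids the other
    both = ~np.isnan(death_t) & ~np.isnan(emig_t)
    death_t[both & (emig_t <= death_t)] = np.nan
    emig_t[both & ~(emig_t <= death_t)] = np.nan

    death = pd.Series(pd.NaT, index=range(n))
    mask = ~np.isnan(death_t)
    death[mask] = sim_start + pd.to_timedelta(
        np.floor(death_t[mask] * DAYS_PER_YEAR), unit="D"
    )
    emigration = pd.Series(pd.NaT, index=range(n))
    mask = ~np.isnan(emig_t)
    emigration[mask] = sim_start + pd.to_timedelta(
        np.floor(emig_t[mask] * DAYS_PER_YEAR), unit="D"
    )
    # vital events cannot precede immigration or birth
    for s in (death, emigration):
        bad = s.notna() & immigration.notna() & (s <= immigration)
        s[bad] = pd.NaT

    persons = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "sex": sex,
            "birth_date": birth,
            "death_date": pd.to_datetime(death),
            "immigration_date": pd.to_datetime(immigration),
            "emigration_date": pd.to_datetime(emigration),
            "education_level": education,
            "place_of_birth": place,
        }
    )
    return persons


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def _covariate_multiplier(persons: pd.DataFrame, dm: DiseaseModel) -> np.ndarray:
    decade = (persons["birth_date"].dt.year // 10 * 10).to_numpy()
    log_mult = np.where(persons["sex"].to_numpy() == "female", dm.log_hr_female, 0.0)
    log_mult = log_mult + np.vectorize(lambda d: dm.log_hr_birth_decade.get(int(d), 0.0))(decade)
    log_mult = log_mult + persons["education_level"].map(dm.log_hr_education).fillna(0.0).to_numpy()
    log_mult = log_mult + persons["place_of_birth"].map(dm.log_hr_place_of_birth).fillna(0.0).to_numpy()
    return np.exp(log_mult)


def _mean_multiplier(demo: Demography, dm: DiseaseModel) -> float:
    e_sex = (1 - demo.female_share) + demo.female_share * math.exp(dm.log_hr_female)
    e_dec = sum(
        share * math.exp(dm.log_hr_birth_decade.get(int(d), 0.0))
        for d, share in demo.birth_decade_shares.items()
    )
    e_edu = sum(
        share * math.exp(dm.log_hr_education.get(k, 0.0))
        for k, share in demo.education_shares.items()
    )
    e_pob = sum(
        share * math.exp(dm.log_hr_place_of_birth.get(k, 0.0))
        for k, share in demo.place_of_birth_shares.items()
    )
    return e_sex * e_dec * e_edu * e_pob


def _trend_factor(t_years: np.ndarray, dm: DiseaseModel, cfg: StudyConfig) -> np.ndarray:
    """Calendar trend multiplier at time t (years since mid reference year)."""
    s1 = dm.annual_log_slope()
    s2 = dm.post_break_log_slope_change()
    log_g = s1 * t_years
    if s2 != 0.0:
        ref_mid = pd.Timestamp(f"{dm.reference_year}-07-01")
        t_break = (cfg.its_break_date - ref_mid).days / DAYS_PER_YEAR
        log_g = log_g + s2 * np.clip(t_years - t_break, 0.0, None)
    return np.exp(log_g)


def generate_events(
    persons: pd.DataFrame,
    sim_config: SimulationConfig,
    study_config: StudyConfig | None = None,
) -> tuple[RegistryBundle, pd.DataFrame]:
    """Simulate onsets and their register traces for an existing population.

    Returns the full bundle (the given persons plus three event tables) and
    the truth table (one row per person: latent onset and first-registration
    dates, prevalent/treated/unclassifiable/medication-only flags and the
    true initial regimen).
    """
    sim_config.validate()
    cfg = study_config or StudyConfig()
    care = sim_config.care_model
    dm = sim_config.disease_model
    rng = np.random.default_rng([sim_config.seed, 23])
    n = len(persons)

    if n == 0:
        bundle = empty_bundle()
        truth = pd.DataFrame({c: pd.Series(dtype=object) for c in TRUTH_COLUMNS})
        return bundle, truth

    sim_start = cfg.prescription_start
    data_end = cfg.prevalence_end
    ref_mid = pd.Timestamp(f"{dm.reference_year}-07-01")

    pid = persons["person_id"].to_numpy()
    birth = persons["birth_date"]
    death = persons["death_date"]
    emigration = persons["emigration_date"]
    immigration = persons["immigration_date"]

    # observation ends the day after death (events may fall on the death day)
    end_obs = pd.Series(data_end, index=persons.index)
    end_obs = end_obs.where(death.isna(), np.minimum(end_obs, death))
    end_obs = end_obs.where(
        emigration.isna(), np.minimum(end_obs, emigration - pd.Timedelta(days=1))
    )
    resident_from = immigration.fillna(sim_start).where(lambda s: s > sim_start, sim_start)

    mult = _covariate_multiplier(persons, dm)
    m_bar = _mean_multiplier(sim_config.demography, dm)
    base_rate = dm.baseline_rate_per_100k / 1e5 / m_bar  # per person-year, reference pattern

    # -- prevalent cases at study start -------------------------------------
    resident_early = immigration.isna() | (
        immigration < cfg.study_start - pd.Timedelta(days=365)
    )
    p_prev = np.clip(dm.prevalent_fraction_at_start * mult / m_bar, 0.0, 0.95)
    prevalent = (rng.random(n) < p_prev) & resident_early.to_numpy()
    prev_onset = pd.Series(pd.NaT, index=persons.index)
    if prevalent.any():
        span = (cfg.study_start - pd.Timestamp("1996-01-01")).days
        offs = np.floor(rng.random(int(prevalent.sum())) * span)
        prev_onset[prevalent] = pd.Timestamp("1996-01-01") + pd.to_timedelta(offs, unit="D")

    # -- incident latent onsets: month loop, piecewise-constant hazard ------
    month_starts = pd.date_range(sim_start, data_end, freq="MS")
    onset = pd.Series(pd.NaT, index=persons.index)
    at_risk_base = ~prevalent
    not_onset = np.ones(n, dtype=bool)
    birth_np = birth.to_numpy()
    death_np = death.fillna(data_end + pd.Timedelta(days=1)).to_numpy()
    emig_np = emigration.fillna(data_end + pd.Timedelta(days=1)).to_numpy()
    resident_from_np = resident_from.to_numpy()
    onset_np = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    for mstart in month_starts:
        mend = min(mstart + pd.offsets.MonthBegin(1), data_end + pd.Timedelta(days=1))
        days_m = (mend - mstart).days
        mid = mstart + pd.Timedelta(days=days_m / 2)
        t_mid = np.array([(mid - ref_mid).days / DAYS_PER_YEAR])
        g = _trend_factor(t_mid, dm, cfg)[0]
        at_risk = (
            at_risk_base
            & not_onset
            & (resident_from_np <= np.datetime64(mstart))
            & (death_np > np.datetime64(mstart))
            & (emig_np > np.datetime64(mstart))
            & (birth_np <= np.datetime64(mstart))
        )
        idx = np.flatnonzero(at_risk)
        if idx.size == 0:
            continue
        haz = base_rate * mult[idx] * g * (days_m / DAYS_PER_YEAR)
        hit = rng.random(idx.size) < -np.expm1(-haz)
        if hit.any():
            hit_idx = idx[hit]
            day_off = np.floor(rng.random(hit_idx.size) * days_m)
            onset_np[hit_idx] = (mstart + pd.to_timedelta(day_off, unit="D")).to_numpy()
            not_onset[hit_idx] = False
    onset = pd.Series(onset_np, index=persons.index)
    onset[prevalent] = prev_onset[prevalent]
    is_case = onset.notna()

    # -- case marks ----------------------------------------------------------
    treated = np.zeros(n, dtype=bool)
    inc = is_case.to_numpy() & ~prevalent
    treated[inc] = rng.random(int(inc.sum())) < care.treated_fraction
    treated[prevalent] = rng.random(int(prevalent.sum())) < care.prevalent_treated_share
    unclassifiable = np.zeros(n, dtype=bool)
    unclassifiable[is_case.to_numpy()] = (
        rng.random(int(is_case.sum())) < care.unclassifiable_coding_rate
    )
    regimen = np.full(n, "", dtype=object)
    case_treated = is_case.to_numpy() & treated
    if case_treated.any():
        regimen[case_treated] = rng.choice(
            list(care.regimen_shares.keys()),
            size=int(case_treated.sum()),
            p=list(care.regimen_shares.values()),
        )

    med_only = np.zeros(n, dtype=bool)
    free = ~is_case.to_numpy()
    med_only[free] = rng.random(int(free.sum())) < care.med_without_dx_rate

    # -- first registration -------------------------------------------------
    reg_date = pd.Series(pd.NaT, index=persons.index)
    case_idx = np.flatnonzero(is_case.to_numpy())
    if case_idx.size:
        if care.registration_delay_mean_days > 0:
            delay = rng.exponential(care.registration_delay_mean_days, case_idx.size)
        else:
            delay = np.zeros(case_idx.size)
        r0 = onset.iloc[case_idx].to_numpy() + pd.to_timedelta(
            np.floor(delay), unit="D"
        ).to_numpy()
        # prevalent cases surface no earlier than data availability
        avail_floor = np.datetime64(min(cfg.primary_care_start, cfg.specialist_start))
        r0 = np.where(prevalent[case_idx], np.maximum(r0, avail_floor), r0)
        r0 = np.minimum(r0, end_obs.iloc[case_idx].to_numpy())
        reg_date.iloc[case_idx] = r0

    # -- visits (diagnosis registrations) -----------------------------------
    visit_person: list[np.ndarray] = []
    visit_date: list[np.ndarray] = []

    r0_np = reg_date.to_numpy()
    end_np = end_obs.to_numpy()
    alive_at_reg = case_idx[
        (r0_np[case_idx] <= end_np[case_idx])
        & (r0_np[case_idx] <= np.datetime64(data_end))
    ]
    visit_person.append(alive_at_reg)
    visit_date.append(r0_np[alive_at_reg])

    # confirmatory follow-up visit (all cases)
    if alive_at_reg.size:
        delay = 1.0 + np.floor(
            rng.exponential(max(care.confirm_visit_mean_days, 1e-9), alive_at_reg.size)
        )
        conf = r0_np[alive_at_reg] + pd.to_timedelta(delay, unit="D").to_numpy()
        conf = np.minimum(conf, end_np[alive_at_reg])
        keep = conf > r0_np[alive_at_reg]
        visit_person.append(alive_at_reg[keep])
        visit_date.append(conf[keep])

    # ongoing visits at a constant rate
    if alive_at_reg.size:
        span_years = (
            (end_np[alive_at_reg] - r0_np[alive_at_reg]) / np.timedelta64(1, "D")
        ) / DAYS_PER_YEAR
        span_years = np.clip(span_years, 0.0, None)
        rate = np.where(
            treated[alive_at_reg], care.visit_rate_treated, care.visit_rate_untreated
        )
        n_extra = rng.poisson(rate * span_years)
        if n_extra.sum() > 0:
            owner = np.repeat(alive_at_reg, n_extra)
            offs = rng.random(int(n_extra.sum())) * np.repeat(
                span_years * DAYS_PER_YEAR, n_extra
            )
            dates = r0_np[owner] + pd.to_timedelta(np.floor(offs), unit="D").to_numpy()
            visit_person.append(owner)
            visit_date.append(dates)

    vp = np.concatenate(visit_person) if visit_person else np.array([], dtype=int)
    vd = (
        np.concatenate(visit_date)
        if visit_date
        else np.array([], dtype="datetime64[ns]")
    )

    # route and record each visit
    spec_rows = {"person_id": [], "event_date": [], "code": []}
    prim_rows = {"person_id": [], "event_date": [], "code": []}
    if vp.size:
        to_primary = rng.random(vp.size) < care.primary_care_share
        recorded = np.where(
            to_primary,
            rng.random(vp.size) < care.record_prob_primary,
            rng.random(vp.size) < care.record_prob_specialist,
        )
        uncls = unclassifiable[vp]
        # non-specific specialist codes drawn once per visit
        alt_codes = rng.choice(_UNCLASSIFIABLE_SPECIALIST_CODES, size=vp.size)

        prim_ok = (
            to_primary
            & recorded
            & (vd >= np.datetime64(cfg.primary_care_start))
            & (vd <= np.datetime64(data_end))
        )
        spec_ok = (
            ~to_primary
            & recorded
            & (vd >= np.datetime64(cfg.specialist_start))
            & (vd <= np.datetime64(data_end))
        )
        prim_rows["person_id"] = pid[vp[prim_ok]]
        prim_rows["event_date"] = vd[prim_ok]
        prim_rows["code"] = np.where(
            uncls[prim_ok], _UNCLASSIFIABLE_PRIMARY_CODE, "T90"
        )
        spec_rows["person_id"] = pid[vp[spec_ok]]
        spec_rows["event_date"] = vd[spec_ok]
        spec_rows["code"] = np.where(uncls[spec_ok], alt_codes[spec_ok], "E11")

    # -- prescriptions -------------------------------------------------------
    rx_person: list[np.ndarray] = []
    rx_date: list[np.ndarray] = []
    rx_code: list[np.ndarray] = []

    treated_idx = np.flatnonzero(case_treated)
    if treated_idx.size:
        first_disp = np.where(
            prevalent[treated_idx],
            np.maximum(
                onset.iloc[treated_idx].to_numpy(), np.datetime64(cfg.prescription_start)
            )
            + pd.to_timedelta(
                np.floor(rng.random(treated_idx.size) * 60), unit="D"
            ).to_numpy(),
            r0_np[treated_idx]
            + pd.to_timedelta(
                np.floor(rng.random(treated_idx.size) * care.treatment_delay_max_days),
                unit="D",
            ).to_numpy(),
        )
        ok = first_disp <= end_np[treated_idx]
        treated_ok = treated_idx[ok]
        first_ok = first_disp[ok]
        for reg_name, codes in _REGIMEN_CODES.items():
            sel = regimen[treated_ok] == reg_name
            if not sel.any():
                continue
            owners = treated_ok[sel]
            starts = first_ok[sel]
            for j, code in enumerate(codes):
                if j == 0:
                    drug_start = starts.copy()
                else:
                    # later drugs of a multi-drug start land inside the first month
                    off = 1.0 + np.floor(rng.random(owners.size) * 25)
                    drug_start = starts + pd.to_timedelta(off, unit="D").to_numpy()
                span_days = (
                    (end_np[owners] - drug_start) / np.timedelta64(1, "D")
                ).astype(float)
                valid = span_days >= 0
                ow, st, sp = owners[valid], drug_start[valid], span_days[valid]
                n_refill = np.floor(sp / care.refill_interval_days).astype(int)
                owner_rep = np.repeat(ow, n_refill + 1)
                k = np.concatenate([np.arange(c + 1) for c in n_refill]) if ow.size else np.array([], dtype=int)
                dates = np.repeat(st, n_refill + 1) + pd.to_timedelta(
                    k * care.refill_interval_days, unit="D"
                ).to_numpy()
                rx_person.append(owner_rep)
                rx_date.append(dates)
                rx_code.append(np.full(owner_rep.size, code, dtype=object))

    med_idx = np.flatnonzero(med_only)
    if med_idx.size:
        start_lo = np.maximum(resident_from_np[med_idx], np.datetime64(cfg.prescription_start))
        span = ((end_np[med_idx] - start_lo) / np.timedelta64(1, "D")).astype(float)
        ok = span > 0
        med_ok = med_idx[ok]
        first = start_lo[ok] + pd.to_timedelta(
            np.floor(rng.random(med_ok.size) * span[ok]), unit="D"
        ).to_numpy()
        use_years = rng.exponential(2.0, med_ok.size)
        stop = np.minimum(
            first + pd.to_timedelta(np.floor(use_years * DAYS_PER_YEAR), unit="D").to_numpy(),
            end_np[med_ok],
        )
        sp = ((stop - first) / np.timedelta64(1, "D")).astype(float)
        n_refill = np.floor(np.clip(sp, 0, None) / care.refill_interval_days).astype(int)
        owner_rep = np.repeat(med_ok, n_refill + 1)
        k = np.concatenate([np.arange(c + 1) for c in n_refill]) if med_ok.size else np.array([], dtype=int)
        dates = np.repeat(first, n_refill + 1) + pd.to_timedelta(
            k * care.refill_interval_days, unit="D"
        ).to_numpy()
        rx_person.append(owner_rep)
        rx_date.append(dates)
        rx_code.append(np.full(owner_rep.size, "A10BA02", dtype=object))

    if rx_person:
        rxp = np.concatenate(rx_person)
        rxd = np.concatenate(rx_date)
        rxc = np.concatenate(rx_code)
        keep = (rxd >= np.datetime64(cfg.prescription_start)) & (
            rxd <= np.datetime64(data_end)
        )
        rec = rng.random(rxp.size) < care.record_prob_prescription
        keep &= rec
        prescriptions = pd.DataFrame(
            {
                "person_id": pid[rxp[keep]],
                "dispense_date": pd.to_datetime(rxd[keep]),
                "atc_code": rxc[keep],
            }
        )
    else:
        prescriptions = empty_bundle().prescriptions

    specialist = pd.DataFrame(
        {
            "person_id": spec_rows["person_id"],
            "event_date": pd.to_datetime(spec_rows["event_date"]),
            "code": spec_rows["code"],
        }
    ) if len(spec_rows["person_id"]) else empty_bundle().specialist_dx
    primary = pd.DataFrame(
        {
            "person_id": prim_rows["person_id"],
            "event_date": pd.to_datetime(prim_rows["event_date"]),
            "code": prim_rows["code"],
        }
    ) if len(prim_rows["person_id"]) else empty_bundle().primary_dx

    truth = pd.DataFrame(
        {
            "person_id": pid,
            "onset_date": onset.to_numpy(),
            "registration_date": reg_date.to_numpy(),
            "prevalent_at_start": prevalent,
            "treated": treated & is_case.to_numpy(),
            "regimen": regimen,
            "unclassifiable_coding": unclassifiable,
            "med_without_dx": med_only,
        }
    )

    bundle = RegistryBundle(
        persons=persons.reset_index(drop=True),
        prescriptions=prescriptions,
        specialist_dx=specialist,
        primary_dx=primary,
    ).sort()
    return bundle, truth.sort_values("person_id").reset_index(drop=True)


def generate_registry(
    sim_config: SimulationConfig, study_config: StudyConfig | None = None
) -> tuple[RegistryBundle, pd.DataFrame]:
    """Population plus events in one call (same seed → identical output)."""
    persons = generate_population(sim_config, study_config)
    return generate_events(persons, sim_config, study_config)
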