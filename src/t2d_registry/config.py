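"""Study configuration: analysis windows, ascertainment windows and scales.

The defaults encode the national open-cohort design this package implements:
residents aged 30–89 followed from 1 January 2009, incident-case onsets
counted until 30 June 2014 (six months before the end of data availability,
so the six-month treatment-ascertainment window is always fully observed),
and register data available from source-specific start dates (pharmacy
dispensings from 2004, specialist care from 2008, primary care from 2006).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

_DATE_FIELDS = (
    "study_start",
    "incidence_follow_up_end",
    "prevalence_end",
    "its_break_date",
    "prescription_start",
    "specialist_start",
    "primary_care_start",
)


@dataclass(frozen=True)
class StudyConfig:
    """Analysis-defining constants.

    Parameters
    ----------
    study_start
        First day of follow-up and of the incidence washout boundary; any
        diabetes evidence strictly before this date excludes a person from
        the incidence analysis.
    incidence_follow_up_end
        Last day (inclusive) on which an incident onset may occur.
    prevalence_end
        Last day of data availability; prevalence is computed through this
        year, and confirmatory registrations may occur up to it.
    min_age_years, max_age_years
        Age range of the open cohort, half-open ``[min, max)``.
    immigration_lag_days
        Residency run-in after immigration before follow-up may start.
    treatment_window_days
        Window after the first type 2 diabetes registration within which a
        non-insulin glucose-lowering dispensing makes a case
        pharmacologically treated ("6 months", fixed at 183 days).
    first_month_window_days
        Window after the first dispensing used to classify the initial
        drug regimen ("first month", fixed at 30 days).
    its_break_date
        Pre-specified break point for the interrupted time series (the
        national adoption of HbA1c-based diagnosis, September 2012).
    ci_z
        Normal quantile for confidence intervals (1.96 for 95%).
    rate_scale
        Rates are reported per this many person-years (100,000).
    """

    study_start: pd.Timestamp = pd.Timestamp("2009-01-01")
    incidence_follow_up_end: pd.Timestamp = pd.Timestamp("2014-06-30")
    prevalence_end: pd.Timestamp = pd.Timestamp("2014-12-31")
    min_age_years: int = 30
    max_age_years: int = 90
    immigration_lag_days: int = 365
    treatment_window_days: int = 183
    first_month_window_days: int = 30
    its_break_date: pd.Timestamp = pd.Timestamp("2012-09-01")
    ci_z: float = 1.96
    rate_scale: float = 100_000.0
    prescription_start: pd.Timestamp = pd.Timestamp("2004-01-01")
    specialist_start: pd.Timestamp = pd.Timestamp("2008-01-01")
    primary_care_start: pd.Timestamp = pd.Timestamp("2006-01-01")

    def __post_init__(self) -> None:
        for name in _DATE_FIELDS:
            object.__setattr__(self, name, pd.Timestamp(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if not (self.study_start < self.incidence_follow_up_end <= self.prevalence_end):
            raise ValueError(
                "require study_start < incidence_follow_up_end <= prevalence_end"
            )
        if not (0 < self.min_age_years < self.max_age_years):
            raise ValueError("require 0 < min_age_years < max_age_years")
        for name in (
            "immigration_lag_days",
            "treatment_window_days",
            "first_month_window_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ci_z <= 0 or self.rate_scale <= 0:
            raise ValueError("ci_z and rate_scale must be > 0")

    # -- flat key/value (de)serialisation -------------------------------
    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        for name in _DATE_FIELDS:
            out[name] = str(pd.Timestamp(out[name]).date())
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
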