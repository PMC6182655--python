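"""Open-cohort follow-up and Lexis expansion.

Follow-up for the incidence analysis starts at the latest of study start,
the 30th birthday and one year after immigration, and ends at the earliest
of first diabetes evidence (diagnosis or dispensing), emigration, death,
the 90th birthday and the end of the incidence period. Each person's
window is then sliced at every 1 January and at every age-band boundary
birthday so that each fragment lies within a single calendar year and
attained-age band, carrying the person's fixed covariates.

Conventions: intervals are half-open ``[start, end)``. Exits triggered by
an event that occurs *on* a day the person is still observed (diabetes
evidence, death) are placed the day after the event so the event day
contributes person-time; emigration and the 90th birthday exclude their
day; the period end is followed inclusively. Ties resolve in the listed
priority order. Person-years use the 365.25-day convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dates import add_years, year_start
from .config import StudyConfig
from .phenotyping import INCIDENT_CASE

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

EXIT_REASONS = (
    "case_onset",
    "any_dx_or_drug",
    "emigration",
    "death",
    "age_90",
    "period_end",
)

DEFAULT_AGE_BANDS = (30, 50, 70, 90)


@dataclass(frozen=True)
class FollowUpWindow:
    person_id: str
    entry_date: pd.Timestamp
    exit_date: pd.Timestamp  # exclusive
    exit_reason: str


class ConsistencyError(ValueError):
    """A case's onset falls outside its person's follow-up window."""


def eligibility_windows(
    persons: pd.DataFrame,
    cases: pd.DataFrame | None = None,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Follow-up window per person for the incidence analysis.

    ``cases`` is the phenotyping output (used for the first-evidence exit
    and to label exits at an incident onset as ``case_onset``); pass None
    for a disease-free cohort. Persons with an empty window are dropped,
    with the counts logged per reason.
    """
    cfg = config or StudyConfig()
    p = persons.reset_index(drop=True)
    n = len(p)
    if n == 0:
        return pd.DataFrame(
            columns=["person_id", "entry_date", "exit_date", "exit_reason"]
        )

    birth30 = add_years(p["birth_date"], cfg.min_age_years)
    birth_max = add_years(p["birth_date"], cfg.max_age_years)
    imm_entry = p["immigration_date"] + pd.Timedelta(days=cfg.immigration_lag_days)
    entry = pd.concat(
        [
            pd.Series(cfg.study_start, index=p.index),
            birth30,
            imm_entry,
        ],
        axis=1,
    ).max(axis=1)

    day = pd.Timedelta(days=1)
    far = cfg.prevalence_end + pd.Timedelta(days=3650)
    if cases is not None:
        ev = (
            cases.set_index("person_id")["first_evidence_date"]
            .reindex(p["person_id"])
            .reset_index(drop=True)
        )
        onset = (
            cases.set_index("person_id")
            .loc[lambda df: df["status"] == INCIDENT_CASE, "onset_date"]
            .reindex(p["person_id"])
            .reset_index(drop=True)
        )
    else:
        ev = pd.Series(pd.NaT, index=p.index)
        onset = pd.Series(pd.NaT, index=p.index)

    exits = pd.DataFrame(
        {
            "evidence": (ev + day).fillna(far),
            "emigration": p["emigration_date"].fillna(far),
            "death": (p["death_date"] + day).fillna(far),
            "age_90": birth_max,
            "period_end": pd.Series(cfg.incidence_follow_up_end + day, index=p.index),
        }
    )
    exit_pos = exits.to_numpy().argmin(axis=1)  # first occurrence wins ties
    exit_date = pd.Series(exits.to_numpy().min(axis=1), index=p.index)

    reason = np.array(["any_dx_or_drug", "emigration", "death", "age_90", "period_end"])[
        exit_pos
    ].astype(object)
    evidence_exit = exit_pos == 0
    is_case_exit = (
        evidence_exit
        & onset.notna().to_numpy()
        & (onset.to_numpy() == ev.to_numpy())
    )
    reason[is_case_exit] = "case_onset"

    out = pd.DataFrame(
        {
            "person_id": p["person_id"],
            "entry_date": entry,
            "exit_date": exit_date,
            "exit_reason": reason,
        }
    )
    empty = out["entry_date"] >= out["exit_date"]
    if empty.any():
        dropped = out.loc[empty, "exit_reason"].value_counts()
        logger.info(
            "dropped %d person(s) with empty follow-up windows: %s",
            int(empty.sum()),
            dropped.to_dict(),
        )
    return out[~empty].reset_index(drop=True)


def eligibility_window(
    person: pd.Series | dict,
    case: pd.Series | dict | None = None,
    config: StudyConfig | None = None,
) -> FollowUpWindow | None:
    """Single-person form of :func:`eligibility_windows` (None if empty)."""
    p = pd.DataFrame([dict(person)])
    cases = None
    if case is not None:
        row = dict(case)
        row.setdefault("person_id", p.loc[0, "person_id"])
        cases = pd.DataFrame([row])
        for col in ("status", "onset_date", "first_evidence_date"):
            if col not in cases:
                cases[col] = pd.NaT if col != "status" else ""
    out = eligibility_windows(p, cases, config)
    if out.empty:
        return None
    r = out.iloc[0]
    return FollowUpWindow(
        person_id=r["person_id"],
        entry_date=r["entry_date"],
        exit_date=r["exit_date"],
        exit_reason=r["exit_reason"],
    )


def _band_labels(age_bands) -> list[str]:
    return [f"{lo}-{hi - 1}" for lo, hi in zip(age_bands[:-1], age_bands[1:])]


def lexis_split(
    windows: pd.DataFrame,
    persons: pd.DataFrame,
    config: StudyConfig | None = None,
    age_bands: tuple[int, ...] = DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """Slice follow-up windows into (calendar year × attained-age band) cells.

    Cut points fall at every 1 January and at every band-boundary birthday
    inside the window; the band of a segment is the attained-age band at
    its start. Segments tile each window exactly (in days) and carry the
    person's fixed covariates and 10-year birth-cohort label.
    """
    cfg = config or StudyConfig()
    cols = [
        "person_id",
        "start",
        "end",
        "calendar_year",
        "age_band",
        "birth_cohort",
        "sex",
        "education_level",
        "place_of_birth",
        "duration_years",
    ]
    if windows.empty:
        return pd.DataFrame(columns=cols)

    w = windows.merge(
        persons[
            ["person_id", "birth_date", "sex", "education_level", "place_of_birth"]
        ],
        on="person_id",
        how="left",
    )

    # explode to one row per calendar year overlapped
    y0 = w["entry_date"].dt.year.to_numpy()
    y1 = (w["exit_date"] - pd.Timedelta(days=1)).dt.year.to_numpy()
    reps = y1 - y0 + 1
    idx = np.repeat(np.arange(len(w)), reps)
    step = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    year = y0[idx] + step

    seg = w.iloc[idx].reset_index(drop=True)
    seg["calendar_year"] = year
    jan1 = year_start(year)
    jan1_next = year_start(year + 1)
    seg["start"] = np.maximum(seg["entry_date"].to_numpy(), jan1.to_numpy())
    seg["end"] = np.minimum(seg["exit_date"].to_numpy(), jan1_next.to_numpy())

    # split at band-boundary birthdays strictly inside a segment
    interior = list(age_bands[1:-1])
    for bound in interior:
        bday = add_years(seg["birth_date"], bound)
        inside = (bday > seg["start"]) & (bday < seg["end"])
        if inside.any():
            left = seg[inside].copy()
            right = seg[inside].copy()
            left["end"] = bday[inside]
            right["start"] = bday[inside]
            seg = pd.concat(
                [seg[~inside], left, right], ignore_index=True
            )

    # attained-age band at segment start (segments never straddle a boundary)
    labels = _band_labels(age_bands)
    band = pd.Series(labels[0], index=seg.index, dtype=object)
    for bound, label in zip(age_bands[1:-1], labels[1:]):
        bday = add_years(seg["birth_date"], bound)
        band[seg["start"] >= bday] = label
    seg["age_band"] = band

    decade = (seg["birth_date"].dt.year // 10 * 10).astype(int)
    seg["birth_cohort"] = decade.astype(str) + "-" + (decade + 9).astype(str)
    seg["duration_years"] = (
        (seg["end"] - seg["start"]).dt.days / DAYS_PER_YEAR
    )
    seg = seg.sort_values(["person_id", "start"], kind="mergesort").reset_index(drop=True)
    return seg[cols]


def incident_cases_in_windows(
    cases: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Incident cases whose onset lies inside their follow-up window.

    Cases whose onset postdates an earlier censoring event (e.g. a
    non-specific diabetes code or a dispensing before the first type 2
    registration) are dropped, with the count logged.
    """
    inc = cases[cases["status"] == INCIDENT_CASE][["person_id", "onset_date"]]
    m = inc.merge(windows, on="person_id", how="left")
    ok = (
        m["entry_date"].notna()
        & (m["onset_date"] >= m["entry_date"])
        & (m["onset_date"] < m["exit_date"])
    )
    if (~ok).any():
        logger.info(
            "dropped %d incident case(s) with onset outside the follow-up window",
            int((~ok).sum()),
        )
    return m.loc[ok, ["person_id", "onset_date"]].reset_index(drop=True)


def aggregate_strata(
    segments: pd.DataFrame,
    cases: pd.DataFrame,
    by: list[str] | tuple[str, ...] = ("calendar_year",),
    strict: bool = True,
) -> pd.DataFrame:
    """Person-years and case counts per stratum.

    ``cases`` must hold person_id and onset_date for incident cases only
    (see :func:`incident_cases_in_windows`); each case is attributed to the
    segment containing its onset. With ``strict``, a case without a
    containing segment raises :class:`ConsistencyError`.
    """
    by = list(by)
    py = (
        segments.groupby(by, observed=True)["duration_years"]
        .sum()
        .rename("person_years")
    )
    if cases is None or cases.empty:
        out = py.reset_index()
        out["cases"] = 0
        return out[by + ["cases", "person_years"]]

    m = cases[["person_id", "onset_date"]].merge(
        segments, on="person_id", how="left"
    )
    hit = (m["onset_date"] >= m["start"]) & (m["onset_date"] < m["end"])
    located = m[hit]
    missing = cases.loc[
        ~cases["person_id"].isin(located["person_id"]), "person_id"
    ]
    if strict and len(missing):
        raise ConsistencyError(
            f"{len(missing)} case(s) have onsets outside their person's "
            f"follow-up (e.g. {missing.head(3).tolist()}); filter with "
            "incident_cases_in_windows first"
        )
    counts = located.groupby(by, observed=True).size().rename("cases")
    out = pd.concat([counts, py], axis=1).fillna({"cases": 0}).reset_index()
    out["cases"] = out["cases"].astype(int)
    return out[by + ["cases", "person_years"]]


def person_time_by_period(
    windows: pd.DataFrame, period_starts: pd.DatetimeIndex
) -> pd.DataFrame:
    """Exact person-days of follow-up in each period.

    Periods are half-open ``[period_starts[i], period_starts[i+1])``; the
    final entry closes the last period and is not itself reported.
    """
    starts = pd.DatetimeIndex(period_starts)
    entry = windows["entry_date"].to_numpy()
    exit_ = windows["exit_date"].to_numpy()
    rows = []
    for p0, p1 in zip(starts[:-1], starts[1:]):
        lo = np.maximum(entry, np.datetime64(p0))
        hi = np.minimum(exit_, np.datetime64(p1))
        days = np.clip((hi - lo) / np.timedelta64(1, "D"), 0, None)
        rows.append({"period_start": p0, "person_days": float(days.sum())})
    out = pd.DataFrame(rows)
    out["person_years"] = out["person_days"] / DAYS_PER_YEAR
    return out
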