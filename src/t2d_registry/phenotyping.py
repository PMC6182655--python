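"""Rule-based ascertainment of type 2 diabetes from linked register events.

A person is a type 2 diabetes case when they have at least one type-2-
specific registration (ICD-10 E11 in specialist care or ICPC-2 T90 in
primary care) together with a non-insulin glucose-lowering dispensing
(ATC A10B) within the treatment window of that first registration, or —
if not so treated — type 2 diabetes registrations on at least two distinct
calendar dates (pooled across the two diagnosis sources). Onset is the
first qualifying registration date; the confirmatory second registration
may occur any time up to the end of data availability.

For incidence, persons with any diabetes evidence (any E10–E14/T89/T90
diagnosis or any A10 dispensing) strictly before study start are washed
out. Persons with some diabetes evidence who never satisfy the case
criteria fall into two sensitivity-analysis categories: possible
unclassified diabetes (a diagnosis that never qualifies) and glucose-
lowering medication without any registered diabetes diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig
from .registry import (
    RegistryBundle,
    RegistryValidationError,
    empty_bundle,
    validate_bundle,
)

# status values
INCIDENT_CASE = "incident_case"
PREVALENT_AT_BASELINE = "prevalent_at_baseline"
EXCLUDED_WASHOUT = "excluded_washout"
POSSIBLE_UNCLASSIFIED = "possible_unclassified"
MEDICATION_WITHOUT_DIAGNOSIS = "medication_without_diagnosis"
NON_CASE = "non_case"

PHARMACOLOGICAL = "pharmacological"
NON_PHARMACOLOGICAL = "non_pharmacological"

RULE_ONE_DX_PLUS_A10B = "one_dx_plus_A10B"
RULE_TWO_OCCASIONS = "two_occasions"

REGISTERS = ("prescription", "specialist", "primary_care")

CASE_COLUMNS = (
    "person_id",
    "status",
    "onset_date",
    "treatment_class",
    "qualifying_rule",
    "registers_involved",
    "n_registers",
    "initial_regimen",
    "first_evidence_date",
    "first_dx_date",
    "first_rx_date",
)


@dataclass(frozen=True)
class CaseRecord:
    """Classification result for one person."""

    person_id: str
    status: str
    onset_date: pd.Timestamp | None = None
    treatment_class: str | None = None
    qualifying_rule: str | None = None
    registers_involved: frozenset = frozenset()
    n_registers: int = 0
    initial_regimen: str | None = None
    first_evidence_date: pd.Timestamp | None = None


def _per_person_min(df: pd.DataFrame, date_col: str, index) -> pd.Series:
    if df.empty:
        return pd.Series(pd.NaT, index=index)
    return df.groupby("person_id")[date_col].min().reindex(index)


def classify_bundle(
    bundle: RegistryBundle, config: StudyConfig | None = None, validate: bool = False
) -> pd.DataFrame:
    """Classify every person in the bundle; returns one row per person.

    Columns mirror :class:`CaseRecord` plus the first-evidence / first-
    diagnosis / first-dispensing dates used by the cohort engine and the
    sensitivity summaries. ``registers_involved`` is a ``|``-joined subset
    of {prescription, specialist, primary_care}.
    """
    cfg = config or StudyConfig()
    if validate:
        validate_bundle(bundle, cfg)
    pid_index = pd.Index(bundle.persons["person_id"], name="person_id")
    n = len(pid_index)

    spec = bundle.specialist_dx
    prim = bundle.primary_dx
    rx = bundle.prescriptions

    spec_stem = spec["code"].astype(str).str[:3]
    prim_stem = prim["code"].astype(str).str[:3]

    t2d = pd.concat(
        [
            spec.loc[spec_stem == "E11", ["person_id", "event_date"]].assign(
                source="specialist"
            ),
            prim.loc[prim_stem == "T90", ["person_id", "event_date"]].assign(
                source="primary_care"
            ),
        ],
        ignore_index=True,
    )
    t2d = t2d[t2d["event_date"] <= cfg.prevalence_end]

    any_dx = pd.concat(
        [spec[["person_id", "event_date"]], prim[["person_id", "event_date"]]],
        ignore_index=True,
    )
    any_dx = any_dx[any_dx["event_date"] <= cfg.prevalence_end]
    rx = rx[rx["dispense_date"] <= cfg.prevalence_end]
    is_a10b = rx["atc_code"].astype(str).str.startswith("A10B")

    first_dx = _per_person_min(any_dx, "event_date", pid_index)
    first_rx = _per_person_min(rx, "dispense_date", pid_index)
    first_evidence = first_dx.combine(first_rx, lambda a, b: min(a, b) if pd.notna(a) and pd.notna(b) else (a if pd.notna(a) else b))
    washed = (first_evidence < cfg.study_start).fillna(False).to_numpy()

    # distinct T2D registration dates, pooled across sources
    t2du = t2d.drop_duplicates(["person_id", "event_date"])
    if t2du.empty:
        onset = pd.Series(pd.NaT, index=pid_index)
        n_dates = pd.Series(0, index=pid_index)
    else:
        grp = t2du.groupby("person_id")["event_date"]
        onset = grp.min().reindex(pid_index)
        n_dates = grp.nunique().reindex(pid_index).fillna(0).astype(int)

    has_spec_t2d = (
        t2d[t2d["source"] == "specialist"].groupby("person_id").size().reindex(pid_index).notna()
        if not t2d.empty
        else pd.Series(False, index=pid_index)
    )
    has_prim_t2d = (
        t2d[t2d["source"] == "primary_care"].groupby("person_id").size().reindex(pid_index).notna()
        if not t2d.empty
        else pd.Series(False, index=pid_index)
    )

    # dispensings relative to onset
    window = pd.Timedelta(days=cfg.treatment_window_days)
    if rx.empty or onset.notna().sum() == 0:
        qual_b = pd.Series(False, index=pid_index)
        qual_any = pd.Series(False, index=pid_index)
        anchor = pd.Series(pd.NaT, index=pid_index)
    else:
        rxm = rx.merge(
            onset.rename("onset").reset_index(), on="person_id", how="inner"
        )
        rxm = rxm[rxm["onset"].notna()]
        in_win = (rxm["dispense_date"] >= rxm["onset"]) & (
            rxm["dispense_date"] <= rxm["onset"] + window
        )
        rxw = rxm[in_win]
        b_mask = rxw["atc_code"].astype(str).str.startswith("A10B")
        qual_b = (
            rxw[b_mask].groupby("person_id").size().reindex(pid_index).notna()
        )
        qual_any = rxw.groupby("person_id").size().reindex(pid_index).notna()
        anchor = rxw.groupby("person_id")["dispense_date"].min().reindex(pid_index)

    # pre-study-start facts for the baseline-prevalence split of washed-out persons
    pre_t2d = t2du[t2du["event_date"] < cfg.study_start]
    pre_t2d_n = (
        pre_t2d.groupby("person_id")["event_date"].nunique().reindex(pid_index).fillna(0).astype(int)
        if not pre_t2d.empty
        else pd.Series(0, index=pid_index)
    )
    pre_b = rx[is_a10b & (rx["dispense_date"] < cfg.study_start)]
    pre_has_b = (
        pre_b.groupby("person_id").size().reindex(pid_index).notna()
        if not pre_b.empty
        else pd.Series(False, index=pid_index)
    )
    prevalent_before = ((pre_t2d_n >= 1) & pre_has_b) | (pre_t2d_n >= 2)

    has_onset = onset.notna().to_numpy()
    onset_np = onset.to_numpy()
    in_window = (
        has_onset
        & (onset_np >= np.datetime64(cfg.study_start))
        & (onset_np <= np.datetime64(cfg.incidence_follow_up_end))
    )
    late_onset = has_onset & (onset_np > np.datetime64(cfg.incidence_follow_up_end))
    has_any_dx = first_dx.notna().to_numpy()
    has_any_rx = first_rx.notna().to_numpy()
    qb = qual_b.fillna(False).to_numpy()
    qa = qual_any.fillna(False).to_numpy()
    nd = n_dates.to_numpy()

    status = np.full(n, NON_CASE, dtype=object)
    treatment = np.full(n, "", dtype=object)
    rule = np.full(n, "", dtype=object)

    incident_pharm = ~washed & in_window & qb
    incident_two = ~washed & in_window & ~qb & (nd >= 2)
    status[incident_pharm | incident_two] = INCIDENT_CASE
    treatment[incident_pharm] = PHARMACOLOGICAL
    rule[incident_pharm] = RULE_ONE_DX_PLUS_A10B
    rule[incident_two] = RULE_TWO_OCCASIONS
    treatment[incident_two & qa] = PHARMACOLOGICAL
    treatment[incident_two & ~qa] = NON_PHARMACOLOGICAL

    lone = ~washed & in_window & ~qb & (nd < 2)
    status[lone] = POSSIBLE_UNCLASSIFIED
    # diabetes-coded but never qualifying (incl. onsets after the incident window)
    other_dx = ~washed & ~in_window & has_any_dx
    status[other_dx & ~late_onset] = POSSIBLE_UNCLASSIFIED
    status[other_dx & late_onset] = NON_CASE
    med_only = ~washed & ~has_any_dx & has_any_rx
    status[med_only] = MEDICATION_WITHOUT_DIAGNOSIS
    status[washed & prevalent_before.to_numpy()] = PREVALENT_AT_BASELINE
    status[washed & ~prevalent_before.to_numpy()] = EXCLUDED_WASHOUT

    incident = status == INCIDENT_CASE
    onset_out = pd.Series(pd.NaT, index=pid_index)
    onset_out[incident] = onset[incident]
    onset_out[status == PREVALENT_AT_BASELINE] = onset[status == PREVALENT_AT_BASELINE]

    # registers contributing qualifying evidence (incident cases only)
    reg_rx = incident & qa
    reg_spec = incident & has_spec_t2d.to_numpy()
    reg_prim = incident & has_prim_t2d.to_numpy()
    parts = np.char.array(np.where(reg_rx, "prescription|", "")) + np.char.array(
        np.where(reg_spec, "specialist|", "")
    ) + np.char.array(np.where(reg_prim, "primary_care|", ""))
    registers = pd.Series(parts.astype(str), index=pid_index).str.rstrip("|")
    n_registers = reg_rx.astype(int) + reg_spec.astype(int) + reg_prim.astype(int)

    regimen = _initial_regimens(rx, anchor, incident & (treatment == PHARMACOLOGICAL), pid_index, cfg)
    regimen[incident & (treatment == NON_PHARMACOLOGICAL)] = "none"

    return pd.DataFrame(
        {
            "person_id": pid_index.to_numpy(),
            "status": status,
            "onset_date": onset_out.to_numpy(),
            "treatment_class": treatment,
            "qualifying_rule": rule,
            "registers_involved": registers.to_numpy(),
            "n_registers": n_registers,
            "initial_regimen": regimen.to_numpy(),
            "first_evidence_date": first_evidence.to_numpy(),
            "first_dx_date": first_dx.to_numpy(),
            "first_rx_date": first_rx.to_numpy(),
        }
    )


def _initial_regimens(
    rx: pd.DataFrame,
    anchor: pd.Series,
    pharmacological: np.ndarray,
    pid_index: pd.Index,
    cfg: StudyConfig,
) -> pd.Series:
    """Initial-regimen class from substances dispensed within the first month.

    Anchored at the first qualifying dispensing; one substance resolves by
    ATC family (A10BA02 metformin, A10BB* sulfonylurea, other A10B* other
    oral); an all-insulin (A10A*) set is insulin_only; two or more distinct
    substances crossing families is a multi-drug start.
    """
    out = pd.Series("", index=pid_index, dtype=object)
    idx = pid_index[pharmacological & anchor.notna().to_numpy()]
    if len(idx) == 0 or rx.empty:
        return out
    month = pd.Timedelta(days=cfg.first_month_window_days)
    rxm = rx.merge(
        anchor.loc[idx].rename("anchor").reset_index(), on="person_id", how="inner"
    )
    rxm = rxm[
        (rxm["dispense_date"] >= rxm["anchor"])
        & (rxm["dispense_date"] <= rxm["anchor"] + month)
    ]
    g = rxm.groupby("person_id")["atc_code"]
    n_sub = g.nunique()
    all_insulin = g.agg(lambda s: bool(len(s)) and all(str(c).startswith("A10A") for c in s))
    first_code = g.min().astype(str)

    label = pd.Series("", index=n_sub.index, dtype=object)
    label[all_insulin] = "insulin_only"
    multi = (~all_insulin) & (n_sub >= 2)
    label[multi] = "multi_drug"
    single = (~all_insulin) & (n_sub == 1)
    label[single & (first_code == "A10BA02")] = "metformin_mono"
    label[single & first_code.str.startswith("A10BB")] = "sulfonylurea_mono"
    label[
        single
        & first_code.str.startswith("A10B")
        & (first_code != "A10BA02")
        & ~first_code.str.startswith("A10BB")
    ] = "other_oral_mono"
    # a lone insulin dispensing is caught by all_insulin above
    out.loc[label.index] = label
    return out


# ---------------------------------------------------------------------------
# single-person operations
# ---------------------------------------------------------------------------


def _one_person_bundle(
    person_id: str,
    prescriptions: pd.DataFrame | None,
    specialist_dx: pd.DataFrame | None,
    primary_dx: pd.DataFrame | None,
) -> RegistryBundle:
    base = empty_bundle()
    persons = pd.DataFrame(
        {
            "person_id": [person_id],
            "sex": ["female"],
            "birth_date": [pd.Timestamp("1950-01-01")],
            "death_date": [pd.NaT],
            "immigration_date": [pd.NaT],
            "emigration_date": [pd.NaT],
            "education_level": ["missing"],
            "place_of_birth": ["Norway"],
        }
    )
    return RegistryBundle(
        persons=persons,
        prescriptions=prescriptions if prescriptions is not None and len(prescriptions) else base.prescriptions,
        specialist_dx=specialist_dx if specialist_dx is not None and len(specialist_dx) else base.specialist_dx,
        primary_dx=primary_dx if primary_dx is not None and len(primary_dx) else base.primary_dx,
    )


def _check_availability(bundle: RegistryBundle, cfg: StudyConfig) -> None:
    if (bundle.prescriptions["dispense_date"] < cfg.prescription_start).any():
        raise RegistryValidationError("dispensing before data availability")
    if (bundle.specialist_dx["event_date"] < cfg.specialist_start).any():
        raise RegistryValidationError("specialist event before data availability")
    if (bundle.primary_dx["event_date"] < cfg.primary_care_start).any():
        raise RegistryValidationError("primary-care event before data availability")


def washout_flag(
    person_id: str,
    prescriptions: pd.DataFrame | None = None,
    specialist_dx: pd.DataFrame | None = None,
    primary_dx: pd.DataFrame | None = None,
    config: StudyConfig | None = None,
) -> str:
    """'excluded_washout' if any diabetes evidence strictly predates study start."""
    cfg = config or StudyConfig()
    dates = []
    if prescriptions is not None and len(prescriptions):
        dates.append(prescriptions["dispense_date"].min())
    if specialist_dx is not None and len(specialist_dx):
        dates.append(specialist_dx["event_date"].min())
    if primary_dx is not None and len(primary_dx):
        dates.append(primary_dx["event_date"].min())
    dates = [d for d in dates if pd.notna(d)]
    if dates and min(dates) < cfg.study_start:
        return EXCLUDED_WASHOUT
    return "eligible"


def classify_person(
    person_id: str,
    prescriptions: pd.DataFrame | None = None,
    specialist_dx: pd.DataFrame | None = None,
    primary_dx: pd.DataFrame | None = None,
    config: StudyConfig | None = None,
) -> CaseRecord:
    """Classify a single person's event stream (see :func:`classify_bundle`)."""
    cfg = config or StudyConfig()
    bundle = _one_person_bundle(person_id, prescriptions, specialist_dx, primary_dx)
    _check_availability(bundle, cfg)
    row = classify_bundle(bundle, cfg).iloc[0]
    registers = frozenset(
        r for r in str(row["registers_involved"]).split("|") if r
    )
    return CaseRecord(
        person_id=person_id,
        status=row["status"],
        onset_date=row["onset_date"] if pd.notna(row["onset_date"]) else None,
        treatment_class=row["treatment_class"] or None,
        qualifying_rule=row["qualifying_rule"] or None,
        registers_involved=registers,
        n_registers=int(row["n_registers"]),
        initial_regimen=row["initial_regimen"] or None,
        first_evidence_date=(
            row["first_evidence_date"] if pd.notna(row["first_evidence_date"]) else None
        ),
    )


def classify_regimen(
    case: CaseRecord, prescriptions: pd.DataFrame, config: StudyConfig | None = None
) -> str:
    """Initial-regimen class for a pharmacologically treated case."""
    cfg = config or StudyConfig()
    if case.treatment_class != PHARMACOLOGICAL:
        raise ValueError("classify_regimen requires a pharmacologically treated case")
    rx = prescriptions[prescriptions["person_id"] == case.person_id]
    window = pd.Timedelta(days=cfg.treatment_window_days)
    onset = pd.Timestamp(case.onset_date)
    in_win = rx[
        (rx["dispense_date"] >= onset) & (rx["dispense_date"] <= onset + window)
    ]
    if in_win.empty:
        raise ValueError("no qualifying dispensing within the treatment window")
    anchor = in_win["dispense_date"].min()
    month = pd.Timedelta(days=cfg.first_month_window_days)
    sub = rx[
        (rx["dispense_date"] >= anchor) & (rx["dispense_date"] <= anchor + month)
    ]["atc_code"].astype(str)
    codes = sorted(set(sub))
    if codes and all(c.startswith("A10A") for c in codes):
        return "insulin_only"
    if len(codes) >= 2:
        return "multi_drug"
    code = codes[0]
    if code == "A10BA02":
        return "metformin_mono"
    if code.startswith("A10BB"):
        return "sulfonylurea_mono"
    return "other_oral_mono"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def unclassified_summary(
    cases: pd.DataFrame, config: StudyConfig | None = None
) -> pd.DataFrame:
    """Yearly counts of the two sensitivity-analysis categories.

    possible_unclassified persons are counted in the year of their first
    diabetes registration; medication_without_diagnosis persons in the year
    of their first A10 dispensing.
    """
    cfg = config or StudyConfig()
    years = range(cfg.study_start.year, cfg.prevalence_end.year + 1)
    out = pd.DataFrame(
        0,
        index=pd.Index(years, name="year"),
        columns=[POSSIBLE_UNCLASSIFIED, MEDICATION_WITHOUT_DIAGNOSIS],
    )
    unc = cases[cases["status"] == POSSIBLE_UNCLASSIFIED]
    med = cases[cases["status"] == MEDICATION_WITHOUT_DIAGNOSIS]
    for df, col, date_col in (
        (unc, POSSIBLE_UNCLASSIFIED, "first_dx_date"),
        (med, MEDICATION_WITHOUT_DIAGNOSIS, "first_rx_date"),
    ):
        if df.empty:
            continue
        counts = pd.to_datetime(df[date_col]).dt.year.value_counts()
        for year, c in counts.items():
            if year in out.index:
                out.loc[year, col] += int(c)
    return out.reset_index()


def register_overlap_summary(cases: pd.DataFrame) -> pd.DataFrame:
    """Distribution of incident cases over the number of registers involved."""
    inc = cases[cases["status"] == INCIDENT_CASE]
    if inc.empty:
        return pd.DataFrame(columns=["n_registers", "count", "proportion"])
    counts = (
        inc["n_registers"].value_counts().reindex([1, 2, 3], fill_value=0).sort_index()
    )
    return pd.DataFrame(
        {
            "n_registers": counts.index,
            "count": counts.to_numpy(),
            "proportion": counts.to_numpy() / counts.sum(),
        }
    )


def prevalence_met_dates(
    bundle: RegistryBundle, config: StudyConfig | None = None
) -> pd.Series:
    """Date each person first satisfies the (prevalent) case criteria, or NaT.

    The drug route is satisfied when both a type 2 diabetes registration and
    an A10B dispensing exist (at the later of the two first dates); the
    two-occasion route at the second distinct registration date.
    """
    cfg = config or StudyConfig()
    pid_index = pd.Index(bundle.persons["person_id"], name="person_id")

    spec = bundle.specialist_dx
    prim = bundle.primary_dx
    t2d = pd.concat(
        [
            spec.loc[spec["code"].astype(str).str[:3] == "E11", ["person_id", "event_date"]],
            prim.loc[prim["code"].astype(str).str[:3] == "T90", ["person_id", "event_date"]],
        ],
        ignore_index=True,
    )
    t2d = t2d[t2d["event_date"] <= cfg.prevalence_end].drop_duplicates(
        ["person_id", "event_date"]
    )
    rx = bundle.prescriptions
    rx_b = rx[
        rx["atc_code"].astype(str).str.startswith("A10B")
        & (rx["dispense_date"] <= cfg.prevalence_end)
    ]

    first_t2d = _per_person_min(t2d, "event_date", pid_index)
    first_b = _per_person_min(rx_b, "dispense_date", pid_index)
    drug_route = pd.concat([first_t2d, first_b], axis=1).max(axis=1)
    drug_route[first_t2d.isna() | first_b.isna()] = pd.NaT

    if t2d.empty:
        second = pd.Series(pd.NaT, index=pid_index)
    else:
        second = (
            t2d.sort_values(["person_id", "event_date"])
            .groupby("person_id")["event_date"]
            .nth(1)
            .reindex(pid_index)
        )
    met = pd.concat([drug_route, second], axis=1).min(axis=1)
    met.name = "met_date"
    return met
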