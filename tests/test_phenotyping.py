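from itertools import combinations

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import bundle_for, dx_frame, person_row, rx_frame
from helpers_oracle import oracle_classify
from t2d_registry import (
    StudyConfig,
    classify_bundle,
    classify_person,
    classify_regimen,
    register_overlap_summary,
    unclassified_summary,
    washout_flag,
)
from t2d_registry.registry import RegistryBundle, RegistryValidationError, empty_bundle


@pytest.mark.parametrize(
    "rx,spec,prim,expected",
    [
        # lone pre-study metformin dispensing
        ([("2007-04-01", "A10BA02")], [], [], "excluded_washout"),
        # any diabetes type triggers washout
        ([], [("2008-11-30", "E14")], [], "excluded_washout"),
        # boundary: evidence on Jan 2 2009 is not strictly before study start
        ([], [], [("2009-01-02", "T90")], "eligible"),
        ([], [], [("2008-12-31", "T90")], "excluded_washout"),
    ],
)
def test_washout_rule(rx, spec, prim, expected, study):
    flag = washout_flag(
        "P1",
        prescriptions=rx_frame("P1", *rx) if rx else None,
        specialist_dx=dx_frame("P1", *spec) if spec else None,
        primary_dx=dx_frame("P1", *prim) if prim else None,
        config=study,
    )
    assert flag == expected


def test_treated_case_one_dx_plus_drug(study):
    rec = classify_person(
        "P1",
        prescriptions=rx_frame("P1", ("2010-03-15", "A10BA02")),
        primary_dx=dx_frame("P1", ("2010-03-01", "T90")),
        config=study,
    )
    assert rec.status == "incident_case"
    assert rec.treatment_class == "pharmacological"
    assert rec.onset_date == pd.Timestamp("2010-03-01")
    assert rec.qualifying_rule == "one_dx_plus_A10B"
    assert rec.registers_involved == {"prescription", "primary_care"}


def test_untreated_case_two_occasions_across_sources(study):
    rec = classify_person(
        "P1",
        specialist_dx=dx_frame("P1", ("2011-05-02", "E11")),
        primary_dx=dx_frame("P1", ("2011-08-10", "T90")),
        config=study,
    )
    assert rec.status == "incident_case"
    assert rec.treatment_class == "non_pharmacological"
    assert rec.onset_date == pd.Timestamp("2011-05-02")
    assert rec.qualifying_rule == "two_occasions"
    assert rec.registers_involved == {"specialist", "primary_care"}
    assert rec.n_registers == 2
    assert rec.initial_regimen == "none"


def test_single_registration_is_possible_unclassified(study):
    rec = classify_person(
        "P1", specialist_dx=dx_frame("P1", ("2012-02-02", "E11")), config=study
    )
    assert rec.status == "possible_unclassified"
    assert rec.onset_date is None


def test_duplicate_same_day_registrations_collapse(study):
    rec = classify_person(
        "P1",
        primary_dx=dx_frame("P1", ("2012-02-02", "T90"), ("2012-02-02", "T90")),
        specialist_dx=dx_frame("P1", ("2012-02-02", "E11")),
        config=study,
    )
    assert rec.status == "possible_unclassified"  # one occasion, despite 3 rows


def test_non_t2d_codes_never_qualify(study):
    rec = classify_person(
        "P1",
        specialist_dx=dx_frame("P1", ("2010-01-01", "E10"), ("2010-06-01", "E13")),
        primary_dx=dx_frame("P1", ("2011-01-01", "T89")),
        config=study,
    )
    assert rec.status == "possible_unclassified"


def test_onset_after_incidence_window_is_not_incident(study):
    rec = classify_person(
        "P1",
        primary_dx=dx_frame("P1", ("2014-08-01", "T90"), ("2014-10-01", "T90")),
        config=study,
    )
    assert rec.status == "non_case"


def test_insulin_only_start_via_two_occasions(study):
    rec = classify_person(
        "P1",
        specialist_dx=dx_frame("P1", ("2010-01-04", "E11")),
        primary_dx=dx_frame("P1", ("2010-02-01", "T90")),
        prescriptions=rx_frame("P1", ("2010-01-10", "A10AB05")),
        config=study,
    )
    assert rec.status == "incident_case"
    assert rec.qualifying_rule == "two_occasions"
    assert rec.treatment_class == "pharmacological"  # insulin within the window
    assert rec.initial_regimen == "insulin_only"
    assert rec.n_registers == 3


@pytest.mark.parametrize(
    "items,expected",
    [
        ([("2010-03-15", "A10BA02")], "metformin_mono"),
        ([("2010-03-15", "A10BA02"), ("2010-04-04", "A10BB01")], "multi_drug"),
        ([("2010-03-15", "A10BB01")], "sulfonylurea_mono"),
        ([("2010-03-15", "A10BG03")], "other_oral_mono"),
        # refill of the same substance after the first month stays monotherapy
        ([("2010-03-15", "A10BA02"), ("2010-06-20", "A10BB01")], "metformin_mono"),
    ],
)
def test_initial_regimen_classification(items, expected, study):
    rx = rx_frame("P1", *items)
    rec = classify_person(
        "P1",
        prescriptions=rx,
        primary_dx=dx_frame("P1", ("2010-03-01", "T90")),
        config=study,
    )
    assert rec.status == "incident_case"
    assert rec.initial_regimen == expected
    assert classify_regimen(rec, rx, study) == expected


def test_classify_regimen_rejects_untreated_case(study):
    rec = classify_person(
        "P1",
        primary_dx=dx_frame("P1", ("2011-05-02", "T90"), ("2011-08-10", "T90")),
        config=study,
    )
    with pytest.raises(ValueError, match="pharmacologically"):
        classify_regimen(rec, rx_frame("P1"), study)


def test_event_outside_availability_window_rejected(study):
    with pytest.raises(RegistryValidationError):
        classify_person(
            "P1",
            specialist_dx=dx_frame("P1", ("2006-05-02", "E11")),
            config=study,
        )


# ---------------------------------------------------------------------------
# oracle equivalence on enumerated event streams
# ---------------------------------------------------------------------------

DATES = ["2008-03-01", "2008-11-01", "2009-04-01", "2010-06-01"]
CODES = [
    ("E10", "spec"),
    ("E11", "spec"),
    ("T89", "prim"),
    ("T90", "prim"),
    ("A10AB01", "rx"),
    ("A10BA02", "rx"),
]
EVENT_TYPES = [
    (pd.Timestamp(d), code, source) for d in DATES for code, source in CODES
]


def build_enumeration_bundle(max_events: int):
    """One synthetic person per event-stream subset of size <= max_events."""
    streams = []
    for k in range(max_events + 1):
        streams.extend(combinations(range(len(EVENT_TYPES)), k))
    rx_rows, spec_rows, prim_rows, persons = [], [], [], []
    for i, stream in enumerate(streams):
        pid = f"S{i:06d}"
        persons.append(person_row(pid))
        for event_idx in stream:
            date, code, source = EVENT_TYPES[event_idx]
            if source == "rx":
                rx_rows.append((pid, date, code))
            elif source == "spec":
                spec_rows.append((pid, date, code))
            else:
                prim_rows.append((pid, date, code))
    base = empty_bundle()
    bundle = RegistryBundle(
        persons=pd.DataFrame(persons),
        prescriptions=pd.DataFrame(
            rx_rows, columns=["person_id", "dispense_date", "atc_code"]
        )
        if rx_rows
        else base.prescriptions,
        specialist_dx=pd.DataFrame(
            spec_rows, columns=["person_id", "event_date", "code"]
        )
        if spec_rows
        else base.specialist_dx,
        primary_dx=pd.DataFrame(
            prim_rows, columns=["person_id", "event_date", "code"]
        )
        if prim_rows
        else base.primary_dx,
    )
    stream_events = [
        [EVENT_TYPES[event_idx] for event_idx in stream] for stream in streams
    ]
    return bundle, stream_events


def assert_matches_oracle(max_events: int, cfg: StudyConfig):
    bundle, streams = build_enumeration_bundle(max_events)
    cases = classify_bundle(bundle, cfg)
    assert len(cases) == len(streams)
    for row, events in zip(cases.itertuples(), streams):
        status, onset, treatment, rule = oracle_classify(events, cfg)
        assert row.status == status, (events, row.status, status)
        if status == "incident_case":
            assert row.onset_date == onset, events
            assert row.treatment_class == treatment, events
            assert row.qualifying_rule == rule, events


def test_classifier_matches_bruteforce_oracle_small_streams(study):
    # exhaustive streams of up to 3 events; the acceptance suite runs <= 4
    assert_matches_oracle(3, study)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

event_strategy = st.tuples(
    st.sampled_from(CODES),
    st.integers(min_value=0, max_value=2500),  # days after 2008-01-15
)


def _frames_from(events):
    rx, spec, prim = [], [], []
    origin = pd.Timestamp("2008-01-15")
    parsed = []
    for (code, source), off in events:
        date = origin + pd.Timedelta(days=off)  # always inside all availability windows
        parsed.append((date, code, source))
        (rx if source == "rx" else spec if source == "spec" else prim).append(
            (date, code)
        )
    return parsed, rx, spec, prim


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(event_strategy, max_size=7))
def test_classifier_matches_oracle_on_random_streams(events):
    cfg = StudyConfig()
    parsed, rx, spec, prim = _frames_from(events)
    rec = classify_person(
        "P1",
        prescriptions=rx_frame("P1", *rx) if rx else None,
        specialist_dx=dx_frame("P1", *spec) if spec else None,
        primary_dx=dx_frame("P1", *prim) if prim else None,
        config=cfg,
    )
    status, onset, treatment, rule = oracle_classify(parsed, cfg)
    assert rec.status == status
    if status == "incident_case":
        assert rec.onset_date == onset
        assert (rec.treatment_class, rec.qualifying_rule) == (treatment, rule)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(event_strategy, max_size=6))
def test_adding_qualifying_dispensing_never_unmakes_a_case(events):
    cfg = StudyConfig()
    parsed, rx, spec, prim = _frames_from(events)
    before = classify_person(
        "P1",
        prescriptions=rx_frame("P1", *rx) if rx else None,
        specialist_dx=dx_frame("P1", *spec) if spec else None,
        primary_dx=dx_frame("P1", *prim) if prim else None,
        config=cfg,
    )
    t2d_dates = [
        d
        for d, c, s in parsed
        if (s == "spec" and c == "E11") or (s == "prim" and c == "T90")
    ]
    if not t2d_dates:
        return
    onset = min(t2d_dates)
    after = classify_person(
        "P1",
        prescriptions=rx_frame("P1", *(rx + [(onset, "A10BA02")])),
        specialist_dx=dx_frame("P1", *spec) if spec else None,
        primary_dx=dx_frame("P1", *prim) if prim else None,
        config=cfg,
    )
    if before.status == "incident_case":
        assert after.status == "incident_case"
        assert after.treatment_class == "pharmacological"
    if before.status in ("excluded_washout", "prevalent_at_baseline"):
        # washout dominance: pre-study evidence keeps the person washed out
        assert after.status in ("excluded_washout", "prevalent_at_baseline")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_unclassified_summary_counts_by_year(study):
    bundle = bundle_for(
        [person_row("P1"), person_row("P2"), person_row("P3")],
        prescriptions=rx_frame("P1", ("2011-05-01", "A10BA02")),
        specialist_dx=dx_frame("P2", ("2012-03-01", "E11")),
    )
    cases = classify_bundle(bundle, study)
    out = unclassified_summary(cases, study).set_index("year")
    assert out.loc[2011, "medication_without_diagnosis"] == 1
    assert out.loc[2012, "possible_unclassified"] == 1
    assert out.to_numpy().sum() == 2

    empty = classify_bundle(bundle_for([person_row("P9")]), study)
    zero = unclassified_summary(empty, study)
    assert (zero[["possible_unclassified", "medication_without_diagnosis"]] == 0).all().all()


def test_register_overlap_summary_normalises(study):
    bundle = bundle_for(
        [person_row("P1"), person_row("P2")],
        primary_dx=dx_frame(
            "P1", ("2010-01-01", "T90"), ("2010-05-01", "T90")
        )._append(
            dx_frame("P2", ("2011-01-01", "T90"), ("2011-05-01", "T90")),
            ignore_index=True,
        ),
    )
    cases = classify_bundle(bundle, study)
    out = register_overlap_summary(cases)
    assert out["proportion"].sum() == pytest.approx(1.0)
    assert out.set_index("n_registers").loc[1, "proportion"] == pytest.approx(1.0)

    assert register_overlap_summary(cases[cases["status"] == "non_case"]).empty
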