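"""Independent brute-force oracles used by the unit and acceptance tests.

These re-state the study rules in plain per-person Python, deliberately
sharing no code with the vectorised implementations they check.
"""

from __future__ import annotations

from datetime import timedelta

import pandas as pd

from t2d_registry import StudyConfig

# an event is (date: Timestamp, code: str, source: 'rx' | 'spec' | 'prim')


def oracle_classify(events, cfg: StudyConfig):
    """(status, onset, treatment_class, qualifying_rule) for one event stream."""
    dx = [(d, c, s) for d, c, s in events if s in ("spec", "prim")]
    rx = [(d, c) for d, c, s in events if s == "rx"]
    all_dates = [d for d, _, _ in events]

    def is_t2d(code, source):
        return (source == "spec" and code.startswith("E11")) or (
            source == "prim" and code.startswith("T90")
        )

    if all_dates and min(all_dates) < cfg.study_start:
        pre_t2d = sorted(
            {d for d, c, s in dx if d < cfg.study_start and is_t2d(c, s)}
        )
        pre_b = any(
            d < cfg.study_start and c.startswith("A10B") for d, c in rx
        )
        if (len(pre_t2d) >= 1 and pre_b) or len(pre_t2d) >= 2:
            return ("prevalent_at_baseline", pre_t2d[0] if pre_t2d else None, "", "")
        return ("excluded_washout", None, "", "")

    t2d_dates = sorted({d for d, c, s in dx if is_t2d(c, s)})
    if t2d_dates:
        onset = t2d_dates[0]
        if onset > cfg.incidence_follow_up_end:
            return ("non_case", None, "", "")
        window_end = onset + timedelta(days=cfg.treatment_window_days)
        b_in = any(onset <= d <= window_end and c.startswith("A10B") for d, c in rx)
        any_in = any(onset <= d <= window_end for d, _ in rx)
        if b_in:
            return ("incident_case", onset, "pharmacological", "one_dx_plus_A10B")
        if len(t2d_dates) >= 2:
            return (
                "incident_case",
                onset,
                "pharmacological" if any_in else "non_pharmacological",
                "two_occasions",
            )
        return ("possible_unclassified", None, "", "")
    if dx:
        return ("possible_unclassified", None, "", "")
    if rx:
        return ("medication_without_diagnosis", None, "", "")
    return ("non_case", None, "", "")


def oracle_day_count(entry, exit_, birth, age_bands=(30, 50, 70, 90)):
    """Day-by-day person-time per (calendar year, attained-age band).

    Walks every day of the half-open window and assigns it to its year and
    band by comparing against the band-boundary anniversaries.
    """

    def anniversary(birth, years):
        try:
            return birth.replace(year=birth.year + years)
        except ValueError:  # Feb 29
            return birth.replace(year=birth.year + years, month=3, day=1)

    bounds = [anniversary(birth, b) for b in age_bands]
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(age_bands[:-1], age_bands[1:])]
    counts: dict[tuple[int, str], int] = {}
    day = entry
    one = timedelta(days=1)
    while day < exit_:
        band = None
        for i in range(len(labels)):
            if bounds[i] <= day < bounds[i + 1]:
                band = labels[i]
                break
        key = (day.year, band)
        counts[key] = counts.get(key, 0) + 1
        day = day + one
    return counts


def oracle_cox_loglik(durations, events, group, beta):
    """Partial log-likelihood for one binary covariate (no tied times)."""
    import math

    order = sorted(range(len(durations)), key=lambda i: durations[i])
    total = 0.0
    for pos, i in enumerate(order):
        if not events[i]:
            continue
        risk = order[pos:]
        denom = sum(math.exp(beta * group[j]) for j in risk)
        total += beta * group[i] - math.log(denom)
    return total
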