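"""Deterministic end-to-end orchestration: simulate → phenotype →
person-time → estimates → report, with a run manifest of checksums.

A single master seed fans out to the simulator through a fixed
SeedSequence derivation, so identical config + seed reproduce every
output file byte for byte and stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cohort, estimation, phenotyping
from .config import StudyConfig
from .registry import RegistryBundle, read_registry, write_registry
from .simulate import SimulationConfig, generate_registry

logger = logging.getLogger(__name__)

TRUTH_FILE = "truth.tsv"
CASES_FILE = "cases.tsv"
WINDOWS_FILE = "windows.tsv"
STRATA_FILE = "strata_year.tsv"
RATES_FILE = "rates_year.tsv"
PREVALENCE_FILE = "prevalence.tsv"
TREND_FILE = "trend.tsv"
ITS_FILE = "its.tsv"
COX_FILE = "cox.tsv"
REPORT_FILE = "report.json"
MANIFEST_FILE = "manifest.json"


def derive_stage_seed(master_seed: int, stage: str) -> int:
    """Fixed derivation of a per-stage seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(stage.encode()).digest()
    stage_key = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence([int(master_seed), stage_key])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def load_run_config(config: Mapping[str, Any] | str | Path | None):
    if config is None:
        data: dict[str, Any] = {}
    elif isinstance(config, (str, Path)):
        data = yaml.safe_load(Path(config).read_text()) or {}
    else:
        data = dict(config)
    study = StudyConfig.from_dict(data.get("study", {}))
    sim = data.get("simulation", {})
    if not isinstance(sim, SimulationConfig):
        sim = SimulationConfig.from_dict(sim)
    return sim, study


def run_pipeline(
    config: Mapping[str, Any] | str | Path | None,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run every stage in order and return the manifest (also written out).

    ``config`` is a mapping (or YAML file) with optional ``simulation`` and
    ``study`` sections; ``seed`` overrides the simulation seed through the
    fixed per-stage derivation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config, study = load_run_config(config)
    if seed is not None:
        sim_config.seed = derive_stage_seed(seed, "simulate")

    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)
                else:
                    logger.info("stage %s: done in %.2fs", name, timings[name])

        return _T()

    try:
        with stage("simulate"):
            bundle, truth = generate_registry(sim_config, study)
            write_registry(bundle, out)
            _write_tsv(truth, out / TRUTH_FILE)

        with stage("phenotype"):
            cases = phenotyping.classify_bundle(bundle, study)
            _write_tsv(cases, out / CASES_FILE)
            flow = cases["status"].value_counts().to_dict()
            logger.info("case classification counts: %s", flow)

        with stage("persontime"):
            windows = cohort.eligibility_windows(bundle.persons, cases, study)
            _write_tsv(windows, out / WINDOWS_FILE)
            segments = cohort.lexis_split(windows, bundle.persons, study)
            inc = cohort.incident_cases_in_windows(cases, windows)
            strata = cohort.aggregate_strata(
                segments, inc, by=["calendar_year", "age_band", "sex"]
            )
            _write_tsv(strata, out / STRATA_FILE)

        with stage("rates"):
            yearly = cohort.aggregate_strata(segments, inc, by=["calendar_year"])
            _write_tsv(
                estimation.rates_table(yearly, config=study), out / RATES_FILE
            )

        with stage("prevalence"):
            met = phenotyping.prevalence_met_dates(bundle, study)
            prev = estimation.prevalence_series(bundle.persons, met, study)
            _write_tsv(prev, out / PREVALENCE_FILE)

        with stage("trend"):
            fit = estimation.poisson_apc(yearly, study)
            _write_tsv(
                pd.DataFrame(
                    [{"apc": fit.apc, "ci_low": fit.ci_low, "ci_high": fit.ci_high}]
                ),
                out / TREND_FILE,
            )

        with stage("its"):
            periods = estimation.aggregate_periods(
                windows, inc, estimation.monthly_periods(study)
            )
            its = estimation.its_fit(periods, study.its_break_date, study)
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "pre_slope_apc": its.pre_slope_apc,
                            "post_slope_apc": its.post_slope_apc,
                            "slope_change_p": its.slope_change_p,
                        }
                    ]
                ),
                out / ITS_FILE,
            )

        with stage("cox"):
            frame = estimation.build_cox_frame(windows, inc, bundle.persons, study)
            hr = estimation.cox_fit(
                frame,
                ["sex", "birth_cohort", "education_level", "place_of_birth"],
                study,
            )
            _write_tsv(hr, out / COX_FILE)

        with stage("report"):
            report = {
                "n_persons": int(len(bundle.persons)),
                "classification_counts": {
                    k: int(v) for k, v in flow.items()
                },
                "n_followed": int(len(windows)),
                "person_years": float(yearly["person_years"].sum()),
                "incident_cases": int(yearly["cases"].sum()),
                "apc": fit.apc,
                "prevalence_first_year": float(prev["proportion"].iloc[0]),
                "prevalence_last_year": float(prev["proportion"].iloc[-1]),
            }
            (out / REPORT_FILE).write_text(json.dumps(report, indent=2, sort_keys=True))
    except Exception as exc:  # annotate with the failing stage, then re-raise
        failed = next((k for k in timings if timings[k] is None), None)
        raise RuntimeError(f"pipeline failed ({failed or 'see log'}): {exc}") from exc

    config_blob = yaml.safe_dump(
        {"simulation": sim_config.to_dict(), "study": study.to_dict()},
        sort_keys=True,
    )
    outputs = sorted(p for p in out.iterdir() if p.suffix in {".tsv", ".json"} and p.name != MANIFEST_FILE)
    manifest = {
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": seed,
        "simulation_seed": sim_config.seed,
        "stage_timings_s": timings,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    (out / MANIFEST_FILE).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
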