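"""Data model and delimited-file IO for the four linked registry tables.

The bundle mirrors a national-registry linkage: one person table (central
population register plus census covariates) and three longitudinal event
tables — pharmacy dispensings coded with ATC (A10*), specialist-care
diagnoses coded with ICD-10 (E10–E14) and primary-care diagnoses coded with
ICPC-2 (T89/T90). Files are tab-delimited UTF-8 with a header row,
ISO-8601 dates and the empty string for absent dates; rows are sorted by
(person_id, date) so two writes of the same bundle are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import StudyConfig

SEXES = ("male", "female")
EDUCATION_LEVELS = ("low", "medium", "high", "missing")
PLACES_OF_BIRTH = (
    "Norway",
    "Europe-excl-Norway",
    "Africa",
    "Asia",
    "North-Central-America",
    "South-America",
    "Oceania",
)
ICD10_DIABETES_STEMS = ("E10", "E11", "E12", "E13", "E14")
ICPC2_DIABETES_STEMS = ("T89", "T90")

PERSON_COLUMNS = (
    "person_id",
    "sex",
    "birth_date",
    "death_date",
    "immigration_date",
    "emigration_date",
    "education_level",
    "place_of_birth",
)
PRESCRIPTION_COLUMNS = ("person_id", "dispense_date", "atc_code")
SPECIALIST_COLUMNS = ("person_id", "event_date", "code")
PRIMARY_COLUMNS = ("person_id", "event_date", "code")

TABLE_FILES = {
    "persons": "persons.tsv",
    "prescriptions": "prescriptions.tsv",
    "specialist_dx": "specialist_dx.tsv",
    "primary_dx": "primary_dx.tsv",
}

_DATE_COLS = {
    "persons": ("birth_date", "death_date", "immigration_date", "emigration_date"),
    "prescriptions": ("dispense_date",),
    "specialist_dx": ("event_date",),
    "primary_dx": ("event_date",),
}
_REQUIRED_DATE_COLS = {
    "persons": ("birth_date",),
    "prescriptions": ("dispense_date",),
    "specialist_dx": ("event_date",),
    "primary_dx": ("event_date",),
}
_COLUMNS = {
    "persons": PERSON_COLUMNS,
    "prescriptions": PRESCRIPTION_COLUMNS,
    "specialist_dx": SPECIALIST_COLUMNS,
    "primary_dx": PRIMARY_COLUMNS,
}
_SORT_KEYS = {
    "persons": ["person_id"],
    "prescriptions": ["person_id", "dispense_date", "atc_code"],
    "specialist_dx": ["person_id", "event_date", "code"],
    "primary_dx": ["person_id", "event_date", "code"],
}


class RegistryError(ValueError):
    """Base class for registry IO/validation failures."""


class RegistryParseError(RegistryError):
    """Malformed field (e.g. a date) in an input file; names the rows."""


class RegistryLinkageError(RegistryError):
    """Event rows whose person_id has no PersonRecord."""


class RegistryValidationError(RegistryError):
    """A documented invariant is violated (codes, date windows, categories)."""


@dataclass
class RegistryBundle:
    """The four tables of one linked registry extract.

    Each table is a pandas DataFrame with the documented columns; date
    columns are ``datetime64[ns]`` (NaT for absent dates).
    """

    persons: pd.DataFrame
    prescriptions: pd.DataFrame
    specialist_dx: pd.DataFrame
    primary_dx: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "prescriptions": self.prescriptions,
            "specialist_dx": self.specialist_dx,
            "primary_dx": self.primary_dx,
        }

    def sort(self) -> "RegistryBundle":
        """Return a copy with canonical row order and a fresh RangeIndex."""
        out = {}
        for name, df in self.tables().items():
            out[name] = (
                df.sort_values(_SORT_KEYS[name], kind="mergesort")
                .reset_index(drop=True)[list(_COLUMNS[name])]
            )
        return RegistryBundle(**out)

    def equals(self, other: "RegistryBundle") -> bool:
        a, b = self.sort(), other.sort()
        return all(a.tables()[k].equals(b.tables()[k]) for k in TABLE_FILES)


def empty_bundle() -> RegistryBundle:
    """A valid bundle with zero rows in every table."""
    return RegistryBundle(
        persons=_empty_frame("persons"),
        prescriptions=_empty_frame("prescriptions"),
        specialist_dx=_empty_frame("specialist_dx"),
        primary_dx=_empty_frame("primary_dx"),
    )


def _empty_frame(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in _COLUMNS[name]})
    for c in _DATE_COLS[name]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


def _resolve_paths(path_or_paths) -> dict[str, Path]:
    if isinstance(path_or_paths, Mapping):
        return {k: Path(v) for k, v in path_or_paths.items()}
    base = Path(path_or_paths)
    return {k: base / v for k, v in TABLE_FILES.items()}


def _parse_dates(df: pd.DataFrame, name: str, path: Path) -> pd.DataFrame:
    for col in _DATE_COLS[name]:
        raw = df[col].astype(str).str.strip()
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & (raw != "")
        if col in _REQUIRED_DATE_COLS[name]:
            bad |= raw == ""
        if bad.any():
            # +2: header line plus 1-based line numbering
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()[:10]
            raise RegistryParseError(
                f"{path}: column '{col}' has malformed or missing dates "
                f"at line(s) {lines}"
            )
        df[col] = parsed
    return df


def read_registry(
    path_or_paths, config: StudyConfig | None = None, validate: bool = True
) -> RegistryBundle:
    """Read the four tab-delimited tables into a validated bundle.

    ``path_or_paths`` is either a directory containing the canonical file
    names or a mapping ``{table_name: path}``.
    """
    paths = _resolve_paths(path_or_paths)
    frames = {}
    for name, filename in TABLE_FILES.items():
        path = paths[name]
        if not path.exists():
            raise RegistryError(f"missing registry file: {path}")
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        expected = list(_COLUMNS[name])
        if list(df.columns) != expected:
            raise RegistryError(
                f"{path}: header {list(df.columns)} != expected {expected}"
            )
        frames[name] = _parse_dates(df, name, path)
    bundle = RegistryBundle(**frames).sort()
    if validate:
        validate_bundle(bundle, config)
    return bundle


def write_registry(bundle: RegistryBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as four tab-delimited files with deterministic bytes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in bundle.sort().tables().items():
        out = df.copy()
        for col in _DATE_COLS[name]:
            out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
        path = out_dir / TABLE_FILES[name]
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written[name] = path
    return written


def _offending(df: pd.DataFrame, mask: pd.Series, what: str, limit: int = 5) -> str:
    rows = df.loc[mask].head(limit)
    return f"{what}: {int(mask.sum())} row(s), e.g.\n{rows.to_string(index=False)}"


def validate_bundle(bundle: RegistryBundle, config: StudyConfig | None = None) -> None:
    """Enforce every documented invariant; raise on the first violation class.

    Checks person categories and date ordering, person_id linkage for the
    three event tables, code families per source, and source-specific
    data-availability windows when a StudyConfig is given.
    """
    cfg = config or StudyConfig()
    p = bundle.persons

    if p["person_id"].duplicated().any():
        raise RegistryValidationError(
            _offending(p, p["person_id"].duplicated(keep=False), "duplicate person_id")
        )
    for col, allowed in (
        ("sex", SEXES),
        ("education_level", EDUCATION_LEVELS),
        ("place_of_birth", PLACES_OF_BIRTH),
    ):
        bad = ~p[col].isin(allowed)
        if bad.any():
            raise RegistryValidationError(_offending(p, bad, f"invalid {col}"))
    both = p["birth_date"].notna() & p["death_date"].notna()
    bad = both & ~(p["birth_date"] < p["death_date"])
    if bad.any():
        raise RegistryValidationError(_offending(p, bad, "birth_date >= death_date"))
    both = p["immigration_date"].notna() & p["emigration_date"].notna()
    bad = both & ~(p["immigration_date"] < p["emigration_date"])
    if bad.any():
        raise RegistryValidationError(
            _offending(p, bad, "immigration_date >= emigration_date")
        )

    known = set(p["person_id"])
    for name in ("prescriptions", "specialist_dx", "primary_dx"):
        df = bundle.tables()[name]
        orphan = ~df["person_id"].isin(known)
        if orphan.any():
            raise RegistryLinkageError(
                _offending(df, orphan, f"{name}: unknown person_id")
            )

    rx = bundle.prescriptions
    bad = ~rx["atc_code"].astype(str).str.startswith("A10")
    if bad.any():
        raise RegistryValidationError(
            _offending(rx, bad, "prescriptions: ATC code outside A10")
        )
    bad = rx["dispense_date"] < cfg.prescription_start
    if bad.any():
        raise RegistryValidationError(
            _offending(rx, bad, "prescriptions: dispense_date before data availability")
        )

    spec = bundle.specialist_dx
    bad = ~spec["code"].astype(str).str[:3].isin(ICD10_DIABETES_STEMS)
    if bad.any():
        raise RegistryValidationError(
            _offending(spec, bad, "specialist_dx: code outside ICD-10 E10–E14")
        )
    bad = spec["event_date"] < cfg.specialist_start
    if bad.any():
        raise RegistryValidationError(
            _offending(spec, bad, "specialist_dx: event_date before data availability")
        )

    prim = bundle.primary_dx
    bad = ~prim["code"].astype(str).str[:3].isin(ICPC2_DIABETES_STEMS)
    if bad.any():
        raise RegistryValidationError(
            _offending(prim, bad, "primary_dx: code outside ICPC-2 T89/T90")
        )
    bad = prim["event_date"] < cfg.primary_care_start
    if bad.any():
        raise RegistryValidationError(
            _offending(prim, bad, "primary_dx: event_date before data availability")
        )
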