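from __future__ import annotations

import pandas as pd
import pytest

from t2d_registry import StudyConfig, empty_bundle
from t2d_registry.registry import RegistryBundle


@pytest.fixture(scope="session")
def study() -> StudyConfig:
    return StudyConfig()


def rx_frame(person_id: str, *items) -> pd.DataFrame:
    """items: (date, atc_code) pairs."""
    return pd.DataFrame(
        {
            "person_id": [person_id] * len(items),
            "dispense_date": pd.to_datetime([d for d, _ in items]),
            "atc_code": [c for _, c in items],
        }
    )


def dx_frame(person_id: str, *items) -> pd.DataFrame:
    """items: (date, code) pairs."""
    return pd.DataFrame(
        {
            "person_id": [person_id] * len(items),
            "event_date": pd.to_datetime([d for d, _ in items]),
            "code": [c for _, c in items],
        }
    )


def person_row(
    person_id: str = "P1",
    sex: str = "female",
    birth_date: str = "1950-06-15",
    death_date: str | None = None,
    immigration_date: str | None = None,
    emigration_date: str | None = None,
    education_level: str = "medium",
    place_of_birth: str = "Norway",
) -> dict:
    return {
        "person_id": person_id,
        "sex": sex,
        "birth_date": pd.Timestamp(birth_date),
        "death_date": pd.Timestamp(death_date) if death_date else pd.NaT,
        "immigration_date": pd.Timestamp(immigration_date) if immigration_date else pd.NaT,
        "emigration_date": pd.Timestamp(emigration_date) if emigration_date else pd.NaT,
        "education_level": education_level,
        "place_of_birth": place_of_birth,
    }


def bundle_for(
    persons: list[dict],
    prescriptions: pd.DataFrame | None = None,
    specialist_dx: pd.DataFrame | None = None,
    primary_dx: pd.DataFrame | None = None,
) -> RegistryBundle:
    base = empty_bundle()
    return RegistryBundle(
        persons=pd.DataFrame(persons),
        prescriptions=prescriptions if prescriptions is not None else base.prescriptions,
        specialist_dx=specialist_dx if specialist_dx is not None else base.specialist_dx,
        primary_dx=primary_dx if primary_dx is not None else base.primary_dx,
    )
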