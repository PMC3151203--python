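import numpy as np
import pandas as pd
import pytest

from trailrisk import Registry
from trailrisk.registry import year_column


def make_registry(persons, first_year=1996, last_year=2006):
    """Build a small registry from per-person dicts.

    Each dict: gender, dob (ISO string), optionally dod, and trail — either
    a single code applied to all in-life years, or a {year: code} mapping
    (missing years stay empty).
    """
    years = list(range(first_year, last_year + 1))
    rows = []
    for i, p in enumerate(persons):
        dob = pd.Timestamp(p["dob"])
        dod = pd.Timestamp(p["dod"]) if p.get("dod") else pd.NaT
        row = {
            "person_id": p.get("person_id", f"T{i:04d}"),
            "gender": p.get("gender", "F"),
            "date_of_birth": dob,
            "date_of_death": dod,
        }
        trail = p.get("trail", "")
        for y in years:
            in_life = dob.year <= y and (pd.isna(dod) or y <= dod.year)
            if isinstance(trail, dict):
                code = trail.get(y, "")
            else:
                code = trail if in_life else ""
            row[year_column(y)] = code
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["date_of_birth"] = pd.to_datetime(frame["date_of_birth"])
    frame["date_of_death"] = pd.to_datetime(frame["date_of_death"])
    return Registry(frame, first_year, last_year)


@pytest.fixture
def toy_registry():
    """Five clean persons: mid-window birth, mid-window death, three stable."""
    return make_registry([
        {"gender": "M", "dob": "1962-07-15", "trail": "H3A2T5"},
        {"gender": "F", "dob": "1975-03-02", "trail": "H3A2T5"},
        {"gender": "F", "dob": "2000-06-01", "trail": "J4B1C8"},   # born 2000
        {"gender": "M", "dob": "1950-01-20", "dod": "2003-05-10",
         "trail": "K1A0B1"},                                        # dies 2003
        {"gender": "M", "dob": "1990-11-30", "trail": "H3A2T5"},
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
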