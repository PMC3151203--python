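"""Per-postal-code uniqueness from aggregate counts via uniform birthdays.

When only aggregate census-style counts are available — residents per
(postal code x birth year x gender) cell — individual dates of birth can
be simulated by assigning each person a day of birth uniformly at random
within their birth year.  Exact uniqueness on (date of birth, gender,
postal code) is then computed per postal code, the assignment repeated R
times, and the per-code mean reported.  Urban and rural postal codes are
summarized separately, since rural codes cover larger populations and
show markedly lower uniqueness once dates of birth are generalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generalize import GeneralizationLevel

COUNT_COLUMNS = ("postal_code", "birth_year", "gender", "count")


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check an aggregate-counts table and normalize its dtypes."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"aggregate counts table is missing columns: {missing}")
    if len(counts) == 0:
        raise ValueError("aggregate counts table is empty")
    out = counts.copy()
    out["count"] = out["count"].astype(int)
    if (out["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if out.duplicated(["postal_code", "birth_year", "gender"]).any():
        raise ValueError("(postal_code, birth_year, gender) cells must be unique")
    if "urban" not in out.columns:
        out["urban"] = 1
    return out


def ages_to_birth_years(counts: pd.DataFrame, reference_year: int) -> pd.DataFrame:
    """Convert an ``age`` column to ``birth_year`` against a reference year."""
    if "age" not in counts.columns:
        raise ValueError("counts table has no 'age' column")
    out = counts.copy()
    out["birth_year"] = reference_year - out["age"].astype(int)
    return out.drop(columns=["age"])


@dataclass
class AggregateResult:
    """Per-code mean uniqueness over R uniform-birthday repetitions."""

    per_code: pd.DataFrame  # postal_code, urban, mean_uniqueness, n_residents
    R: int


def _days_in_year(years: np.ndarray) -> np.ndarray:
    leap = (years % 4 == 0) & ((years % 100 != 0) | (years % 400 == 0))
    return np.where(leap, 366, 365)


def assign_uniform_birthdays(
    counts: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Expand counts into persons with uniformly drawn days of birth.

    Each cell of ``count`` persons becomes that many rows; every person
    receives a date of birth uniform over the calendar days of their
    birth year (365 or 366 days).  Gender and postal code carry through.
    """
    counts = validate_counts(counts)
    reps = counts["count"].to_numpy()
    code = np.repeat(counts["postal_code"].to_numpy(), reps)
    year = np.repeat(counts["birth_year"].to_numpy().astype(int), reps)
    gender = np.repeat(counts["gender"].to_numpy(), reps)
    urban = np.repeat(counts["urban"].to_numpy(), reps)
    doy = 1 + np.floor(rng.random(len(year)) * _days_in_year(year)).astype(int)
    dob = pd.to_datetime(pd.Series(year * 1000 + doy), format="%Y%j")
    return pd.DataFrame({
        "postal_code": code,
        "gender": gender,
        "birth_year": year,
        "date_of_birth": dob,
        "urban": urban,
    })


def aggregate_uniqueness(
    counts: pd.DataFrame,
    quasi: GeneralizationLevel | None = None,
    R: int = 1000,
    seed: int = 0,
) -> AggregateResult:
    """Mean per-code uniqueness on (generalized DOB, gender, postal code).

    For each repetition, every person is given a uniform day of birth
    within their birth year and exact uniqueness is computed per postal
    code (each code's own residents are the denominator); the per-code
    mean over ``R`` repetitions is returned.  ``quasi.dob_level`` selects
    full date, month/year, or year of birth; ``quasi.include_gender``
    keeps or drops gender.  At the ``year`` level birthday draws are
    irrelevant and the result is deterministic.
    """
    counts = validate_counts(counts)
    quasi = quasi or GeneralizationLevel("full", 6, True)
    if quasi.dob_level == "suppressed":
        raise ValueError("aggregate uniqueness needs an unsuppressed dob level")
    rng = np.random.default_rng(seed)

    reps = counts["count"].to_numpy()
    year = np.repeat(counts["birth_year"].to_numpy().astype(int), reps)
    code_labels, code_idx = np.unique(
        np.repeat(counts["postal_code"].to_numpy(), reps), return_inverse=True)
    _, gender_idx = np.unique(
        np.repeat(counts["gender"].to_numpy(), reps), return_inverse=True)
    n = len(year)
    if n == 0:
        raise ValueError("aggregate counts contain no persons")
    residents = np.bincount(code_idx, minlength=len(code_labels))

    # fixed part of the key: code, gender (if kept), birth year
    base = code_idx.astype(np.int64)
    if quasi.include_gender:
        base = base * (gender_idx.max() + 1) + gender_idx
    base = base * 10000 + year

    days = _days_in_year(year)
    deterministic = quasi.dob_level == "year"
    month_starts = np.array(  # cumulative days before each month, non-leap
        [0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])

    sums = np.zeros(len(code_labels))
    n_reps = 1 if deterministic else R
    for _ in range(n_reps):
        doy = 1 + np.floor(rng.random(n) * days).astype(int)
        if quasi.dob_level == "full":
            key = base * 1000 + doy
        elif quasi.dob_level == "month_year":
            leap = days == 366
            adj = doy - (leap & (doy > 59)).astype(int)  # collapse Feb 29
            month = np.searchsorted(month_starts, np.minimum(adj, 365),
                                    side="left")
            key = base * 100 + month
        else:
            key = base
        _, inv, cnt = np.unique(key, return_inverse=True, return_counts=True)
        unique_person = cnt[inv] == 1
        sums += np.bincount(code_idx, weights=unique_person,
                            minlength=len(code_labels))
    mean_u = sums / (n_reps * residents)

    urban_by_code = (counts.groupby("postal_code")["urban"].first()
                     .reindex(code_labels).to_numpy())
    per_code = pd.DataFrame({
        "postal_code": code_labels,
        "urban": urban_by_code.astype(int),
        "mean_uniqueness": mean_u,
        "n_residents": residents,
    })
    return AggregateResult(per_code=per_code, R=R)


def urban_rural_summary(result: AggregateResult) -> pd.DataFrame:
    """Median per-code uniqueness within the urban and rural strata.

    Strata with no postal codes are simply absent from the output.
    """
    rows = []
    for label, flag in (("urban", 1), ("rural", 0)):
        sub = result.per_code[result.per_code["urban"] == flag]
        if len(sub):
            rows.append({
                "stratum": label,
                "n_codes": len(sub),
                "median_uniqueness": float(sub["mean_uniqueness"].median()),
            })
    return pd.DataFrame(rows, columns=["stratum", "n_codes", "median_uniqueness"])
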