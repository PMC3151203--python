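"""Quasi-identifier construction over a generalization lattice.

The three quasi-identifiers are date of birth, postal code, and gender.
Date of birth generalizes full -> month/year -> year -> suppressed; the
postal code generalizes by cropping trailing characters (6 down to 1, or
0 = suppressed); gender is on or off.  A residential trail contributes
one (cropped) postal code per selected calendar year, and the keys are
year-labelled: the adversary is assumed to know in which year a target
lived at each address, and whether the target was yet to be born or
already dead (sentinel codes crop like ordinary strings and can never
collide with real codes, which never start with 'U' or 'D').
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .registry import DEAD_SENTINEL, UNBORN_SENTINEL, Registry, year_column

DOB_LEVELS = ("full", "month_year", "year", "suppressed")


@dataclass(frozen=True)
class GeneralizationLevel:
    """One cell of the generalization lattice.

    ``dob_level`` is one of ``full``, ``month_year``, ``year``,
    ``suppressed``; ``postal_chars`` is the number of leading postal
    characters kept (0 = suppressed); ``include_gender`` keeps or drops
    gender.  At least one component must be unsuppressed.
    """

    dob_level: str = "full"
    postal_chars: int = 6
    include_gender: bool = True

    def __post_init__(self):
        if self.dob_level not in DOB_LEVELS:
            raise ValueError(f"dob_level must be one of {DOB_LEVELS}")
        if not 0 <= self.postal_chars <= 6:
            raise ValueError("postal_chars must be in 0..6")
        if (self.dob_level == "suppressed" and self.postal_chars == 0
                and not self.include_gender):
            raise ValueError("at least one quasi-identifier must be unsuppressed")


@dataclass(frozen=True)
class TrailSpec:
    """The calendar years whose postal snapshots enter the key."""

    years: tuple

    def __post_init__(self):
        ys = self.years
        if len(ys) < 1:
            raise ValueError("a trail needs at least one year")
        if any(b <= a for a, b in zip(ys, ys[1:])):
            raise ValueError("trail years must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.years)


def crop_postal(code: str, k: int) -> str:
    """Crop a postal code (or sentinel) to its first ``k`` characters."""
    if not 0 <= k <= 6:
        raise ValueError(f"postal crop length must be in 0..6, got {k}")
    return code[:k]


def generalize_dob(dob, level: str) -> str:
    """Generalize a date of birth to the requested granularity."""
    if level == "full":
        return f"{dob.year:04d}-{dob.month:02d}-{dob.day:02d}"
    if level == "month_year":
        return f"{dob.year:04d}-{dob.month:02d}"
    if level == "year":
        return f"{dob.year:04d}"
    if level == "suppressed":
        return ""
    raise ValueError(f"dob_level must be one of {DOB_LEVELS}")


_DOB_FORMAT = {"full": "%Y-%m-%d", "month_year": "%Y-%m", "year": "%Y"}


def build_quasi_identifiers(
    registry: Registry,
    level: GeneralizationLevel,
    trail: TrailSpec,
    *,
    include_sentinels: bool = True,
) -> pd.Series:
    """One quasi-identifier key per person (never dropping anyone).

    Keys are strings whose fields are the generalized date of birth, the
    gender (if included), and one year-labelled cropped postal code per
    selected trail year; two keys are equal iff all components are equal.
    ``include_sentinels=False`` blanks unborn/dead sentinel codes before
    cropping, emulating an adversary without vital-status knowledge.
    """
    bad = [y for y in trail.years if not registry.first_year <= y <= registry.last_year]
    if bad:
        raise ValueError(f"trail years {bad} outside window "
                         f"{registry.first_year}-{registry.last_year}")

    parts = []
    if level.dob_level == "suppressed":
        parts.append(pd.Series("", index=registry.frame.index))
    else:
        parts.append(registry.frame["date_of_birth"].dt.strftime(
            _DOB_FORMAT[level.dob_level]))
    if level.include_gender:
        parts.append(registry.frame["gender"].astype(str))
    for y in trail.years:
        col = registry.frame[year_column(y)].astype(str)
        if not include_sentinels:
            col = col.replace({UNBORN_SENTINEL: "", DEAD_SENTINEL: ""})
        parts.append(str(y) + "=" + col.str.slice(0, level.postal_chars))

    key = parts[0]
    for p in parts[1:]:
        key = key + "|" + p
    return key.rename("key")


def enumerate_lattice(window_years: int) -> list[tuple[GeneralizationLevel, int]]:
    """All study points: generalization levels crossed with trail lengths.

    The cross product of dob level (4) x postal characters (7) x gender
    flag (2) x trail length (1..window_years), excluding the combinations
    with both date of birth and postal code suppressed — 54 levels per
    trail length.
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    points = []
    for dob, chars, gender in itertools.product(
            DOB_LEVELS, range(7), (True, False)):
        if dob == "suppressed" and chars == 0:
            continue
        for k in range(1, window_years + 1):
            points.append((GeneralizationLevel(dob, chars, gender), k))
    return points


def lattice_frame(points: list[tuple[GeneralizationLevel, int]]) -> pd.DataFrame:
    """Serialize lattice points as a table."""
    return pd.DataFrame(
        [(lv.dob_level, lv.postal_chars, lv.include_gender, k)
         for lv, k in points],
        columns=["dob_level", "postal_chars", "gender_included", "trail_length"],
    )
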