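"""Registry CSV reading/writing, quality-control filtering, and sentinel coding.

The CSV dialect is one row per person: ``person_id``, ``gender`` ({M,F}),
``date_of_birth`` (ISO 8601), ``date_of_death`` (ISO 8601 or empty), and
``pc_<year>`` for each window year (6-character postal code without the
space, empty string when missing).

Quality control mirrors how administrative registries are cleaned before
a disclosure-risk analysis: persons with no postal codes in any year are
removed, as are persons with inconsistent trails (a postal code recorded
strictly before birth or strictly after death).  After QC, the empty
out-of-life years of retained persons are encoded with the sentinel
postal codes ``UUUUUU`` (unborn) and ``DDDDDD`` (dead), which models an
adversary who knows a target's vital status.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .registry import (
    DEAD_SENTINEL,
    REQUIRED_COLUMNS,
    UNBORN_SENTINEL,
    Registry,
    year_column,
)


@dataclass(frozen=True)
class QCReport:
    """Outcome of quality-control filtering."""

    n_input: int
    n_removed_missing_all: int
    n_removed_inconsistent: int
    n_retained: int

    def __post_init__(self):
        total = (self.n_removed_missing_all + self.n_removed_inconsistent
                 + self.n_retained)
        if total != self.n_input:
            raise ValueError("QC counts do not add up to the input size")

    @property
    def removal_fraction(self) -> float:
        if self.n_input == 0:
            return 0.0
        return (self.n_input - self.n_retained) / self.n_input

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["removal_fraction"] = self.removal_fraction
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def write_registry(registry: Registry, path) -> None:
    """Write a registry in the standard CSV dialect (dates ISO 8601)."""
    frame = registry.frame.copy()
    frame["date_of_birth"] = frame["date_of_birth"].dt.strftime("%Y-%m-%d")
    dod = frame["date_of_death"]
    frame["date_of_death"] = np.where(dod.isna(), "", dod.dt.strftime("%Y-%m-%d"))
    frame.to_csv(path, index=False)


def read_registry(path, window: tuple[int, int]) -> Registry:
    """Read a registry CSV for the given (first_year, last_year) window.

    Missing mandatory columns raise immediately.  Rows with unparseable
    dates are dropped and recorded, with their (0-based) data row number
    and a message, in the returned registry's ``parse_errors`` list.
    """
    first, last = window
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = list(REQUIRED_COLUMNS) + [year_column(y) for y in range(first, last + 1)]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"registry file {path} is missing columns: {missing}")

    dob = pd.to_datetime(frame["date_of_birth"], format="%Y-%m-%d", errors="coerce")
    dod_raw = frame["date_of_death"]
    dod = pd.to_datetime(dod_raw, format="%Y-%m-%d", errors="coerce")

    errors = []
    bad = dob.isna()
    for i in np.flatnonzero(bad):
        errors.append((int(i), f"unparseable date_of_birth {frame['date_of_birth'][i]!r}"))
    bad_dod = dod.isna() & (dod_raw != "")
    for i in np.flatnonzero(bad_dod & ~bad):
        errors.append((int(i), f"unparseable date_of_death {dod_raw[i]!r}"))
    bad |= bad_dod

    frame = frame.loc[~bad].reset_index(drop=True)
    frame["date_of_birth"] = dob[~bad].reset_index(drop=True)
    frame["date_of_death"] = dod[~bad.values].reset_index(drop=True)
    return Registry(frame, first, last, parse_errors=errors)


def qc_filter(registry: Registry) -> tuple[Registry, QCReport]:
    """Remove all-missing and inconsistent persons; report the counts.

    Rule (a): a person whose postal fields are empty in every window year
    is removed.  Rule (b): a person with a non-empty postal code in a year
    strictly before their birth year or strictly after their death year is
    removed.  A person matching both cannot exist (rule (a) implies no
    codes at all), so the counts partition the input.  Record order is
    preserved; the registry must not yet be sentinel-encoded.
    """
    trail = registry.trail_matrix()
    if (trail == UNBORN_SENTINEL).any() or (trail == DEAD_SENTINEL).any():
        raise ValueError("qc_filter must run before sentinel encoding")

    nonempty = trail != ""
    missing_all = ~nonempty.any(axis=1)

    years = np.array(registry.years)
    by = registry.birth_years()
    dy = registry.death_years()
    out_of_life = (years[None, :] < by[:, None]) | (years[None, :] > dy[:, None])
    inconsistent = (nonempty & out_of_life).any(axis=1) & ~missing_all

    keep = ~missing_all & ~inconsistent
    report = QCReport(
        n_input=registry.n_persons,
        n_removed_missing_all=int(missing_all.sum()),
        n_removed_inconsistent=int(inconsistent.sum()),
        n_retained=int(keep.sum()),
    )
    return registry.subset(keep), report


def encode_sentinels(registry: Registry) -> Registry:
    """Replace out-of-life empty years with unborn/dead sentinel codes.

    Years strictly before the birth year become ``UUUUUU``; years strictly
    after the death year become ``DDDDDD``.  A person exists in year Y iff
    birth year <= Y <= death year (residence snapshots are taken at the
    beginning of each year, so the birth year itself carries a real code).
    An empty postal value inside a retained person's lifespan violates the
    post-QC contract and raises.
    """
    trail = registry.trail_matrix().copy()
    years = np.array(registry.years)
    by = registry.birth_years()
    dy = registry.death_years()

    before = years[None, :] < by[:, None]
    after = years[None, :] > dy[:, None]
    trail[before] = UNBORN_SENTINEL
    trail[after] = DEAD_SENTINEL

    in_life_empty = (trail == "") & ~before & ~after
    if in_life_empty.any():
        i = int(np.argwhere(in_life_empty)[0][0])
        raise ValueError(
            f"person {registry.frame['person_id'][i]!r} has an empty in-life "
            "postal code; run qc_filter first or clean the registry")

    out = registry.copy()
    out.frame[registry.year_columns] = trail
    return out
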