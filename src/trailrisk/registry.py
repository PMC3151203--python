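"""Core container for a person-level population registry.

A registry holds one row per person with gender, date of birth, an
optional date of death, and one postal-code column per calendar year of
the study window (an annual snapshot of residence taken at the beginning
of each year).  Postal codes are 6-character Canadian-style codes stored
without the space; the empty string means missing; the sentinel codes
``UUUUUU`` (not yet born) and ``DDDDDD`` (deceased) are written by
:func:`trailrisk.registry_io.encode_sentinels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel postal code for years strictly before a person's birth year.
UNBORN_SENTINEL = "UUUUUU"
#: Sentinel postal code for years strictly after a person's death year.
DEAD_SENTINEL = "DDDDDD"

REQUIRED_COLUMNS = ("person_id", "gender", "date_of_birth", "date_of_death")


def year_column(year: int) -> str:
    """Name of the postal-code column for a calendar year."""
    return f"pc_{year}"


@dataclass
class Registry:
    """A person-level registry over a fixed window of calendar years.

    Parameters
    ----------
    frame
        One row per person.  Required columns: ``person_id`` (str),
        ``gender`` ({'M','F'}), ``date_of_birth`` (datetime64),
        ``date_of_death`` (datetime64, NaT if alive), and ``pc_<year>``
        (str) for every year of the window.
    first_year, last_year
        Inclusive bounds of the study window.
    """

    frame: pd.DataFrame
    first_year: int
    last_year: int
    parse_errors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ValueError(
                f"last_year {self.last_year} precedes first_year {self.first_year}"
            )
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        missing += [
            year_column(y) for y in self.years if year_column(y) not in self.frame.columns
        ]
        if missing:
            raise ValueError(f"registry frame is missing columns: {missing}")

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.last_year + 1))

    @property
    def year_columns(self) -> list[str]:
        return [year_column(y) for y in self.years]

    @property
    def n_persons(self) -> int:
        return len(self.frame)

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    def trail_matrix(self) -> np.ndarray:
        """Postal codes as an (n_persons, n_years) object array."""
        return self.frame[self.year_columns].to_numpy(dtype=object)

    def birth_years(self) -> np.ndarray:
        return self.frame["date_of_birth"].dt.year.to_numpy()

    def death_years(self) -> np.ndarray:
        """Death year per person; alive persons get a sentinel far future year."""
        dy = self.frame["date_of_death"].dt.year.to_numpy(dtype=float)
        return np.where(np.isnan(dy), np.iinfo(np.int32).max, dy).astype(np.int64)

    def copy(self) -> "Registry":
        return Registry(
            self.frame.copy(),
            self.first_year,
            self.last_year,
            list(self.parse_errors),
        )

    def subset(self, mask) -> "Registry":
        """Registry restricted to rows where ``mask`` is True (order preserved)."""
        return Registry(
            self.frame.loc[mask].reset_index(drop=True),
            self.first_year,
            self.last_year,
        )
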