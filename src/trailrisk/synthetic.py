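"""Synthetic population registries with realistic disclosure-risk structure.

This module generates person-level registries that mimic the statistical
shape of a provincial health-insurance population file: Canadian-style
6-character postal codes with a consistent prefix hierarchy and
right-skewed cell sizes, an address-change (residential mobility) profile,
births and deaths inside the study window, and the two data-quality
defects such files exhibit in practice (persons with no postal codes at
all, and persons with postal codes recorded outside their lifespan).

Defaults are calibrated to a large Canadian metropolitan area: 6-character
postal codes average ~48 residents with median ~30, ~48% of people never
change address over an 11-year window (21% once, 17% twice, 8% three
times, 6% four or more times), ~1% of records have no postal codes and
~5% have inconsistent ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registry import DEAD_SENTINEL, UNBORN_SENTINEL, Registry, year_column

# Letters that may appear in generated postal codes.  Canada Post excludes
# D, F, I, O, Q and U everywhere; excluding D and U also keeps real codes
# disjoint from the unborn/dead sentinel prefixes.
POSTAL_LETTERS = np.array(list("ABCEGHJKLMNPRSTVXYZ"))
POSTAL_DIGITS = np.array(list("0123456789"))

_ALIVE = np.iinfo(np.int32).max  # death-year sentinel for living persons


# ---------------------------------------------------------------------------
# postal universe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PostalUniverse:
    """The set of postal codes a synthetic population can live in.

    ``codes`` are unique 6-character letter-digit alternating strings
    (no space); ``shares`` are per-code target population shares summing
    to 1; ``urban`` flags each code as urban (True) or rural (False).
    Cropping a code to k characters yields its k-character prefix, so the
    prefix hierarchy is consistent by construction.
    """

    codes: np.ndarray
    shares: np.ndarray
    urban: np.ndarray

    def __post_init__(self):
        if len(self.codes) != len(set(self.codes)):
            raise ValueError("postal codes must be unique")
        for c in self.codes[: min(len(self.codes), 10_000)]:
            if len(c) != 6:
                raise ValueError(f"postal code {c!r} is not 6 characters")
            if c[0] in "UD":
                raise ValueError(f"postal code {c!r} collides with a sentinel prefix")
        if not np.isclose(self.shares.sum(), 1.0):
            raise ValueError("population shares must sum to 1")

    @property
    def n_codes(self) -> int:
        return len(self.codes)

    def urban_map(self) -> dict:
        return dict(zip(self.codes.tolist(), (int(u) for u in self.urban)))


def build_postal_universe(
    n_codes: int,
    mean_cell_size: float = 48.0,
    seed: int = 0,
    *,
    median_cell_size: float | None = None,
    ldus_per_fsa: int = 75,
    rural_fraction: float = 0.10,
) -> PostalUniverse:
    """Build a postal-code universe with log-normal population shares.

    Per-code shares are log-normal, so implied cell sizes (share x total
    population) are right-skewed: with the defaults the mean/median ratio
    matches the 48/30 profile of 6-character metropolitan postal codes.
    Rural codes (the ``rural_fraction`` largest cells) are flagged, since
    rural postal codes cover larger populations than urban ones.

    Parameters
    ----------
    n_codes
        Number of distinct 6-character codes.
    mean_cell_size
        Target mean residents per code; with ``n_codes`` it fixes the
        implied total population used for calibration checks.
    median_cell_size
        Target median residents per code; defaults to ``0.625 * mean``
        (the metropolitan 48:30 ratio).  Sets the log-normal sigma via
        ``sigma = sqrt(2 ln(mean / median))``.
    ldus_per_fsa
        Average number of codes sharing a 3-character forward-sortation
        prefix; shapes the prefix hierarchy.
    """
    if n_codes < 1:
        raise ValueError(f"n_codes must be >= 1, got {n_codes}")
    if mean_cell_size <= 0:
        raise ValueError(f"mean_cell_size must be positive, got {mean_cell_size}")
    if median_cell_size is None:
        median_cell_size = 0.625 * mean_cell_size
    if not 0 < median_cell_size <= mean_cell_size:
        raise ValueError("median_cell_size must be in (0, mean_cell_size]")

    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(2.0 * np.log(mean_cell_size / median_cell_size)))

    # forward sortation areas (first three characters), then unique
    # letter-digit-letter... suffixes within each FSA
    n_fsa = max(1, -(-n_codes // ldus_per_fsa))  # ceil
    fsas = _unique_codes(rng, n_fsa, pattern="LDL")
    codes = []
    per_fsa = np.bincount(np.arange(n_codes) % n_fsa, minlength=n_fsa)
    for fsa, m in zip(fsas, per_fsa):
        for sfx in _unique_codes(rng, int(m), pattern="DLD"):
            codes.append(fsa + sfx)
    codes = np.array(codes)

    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_codes)
    shares = raw / raw.sum()

    urban = np.ones(n_codes, dtype=bool)
    n_rural = int(round(rural_fraction * n_codes))
    if n_rural and n_codes > 1:
        urban[np.argsort(shares)[-n_rural:]] = False

    return PostalUniverse(codes=codes, shares=shares, urban=urban)


def _unique_codes(rng: np.random.Generator, n: int, pattern: str) -> list[str]:
    """n distinct strings following a letter (L) / digit (D) pattern."""
    pools = [POSTAL_LETTERS if p == "L" else POSTAL_DIGITS for p in pattern]
    capacity = int(np.prod([len(p) for p in pools]))
    if n > capacity:
        raise ValueError(f"cannot draw {n} unique codes from pattern {pattern}")
    chosen = rng.choice(capacity, size=n, replace=False)
    out = []
    for idx in chosen:
        s, rem = [], int(idx)
        for pool in reversed(pools):
            s.append(pool[rem % len(pool)])
            rem //= len(pool)
        out.append("".join(reversed(s)))
    return out


# ---------------------------------------------------------------------------
# behavioural models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MobilityModel:
    """Distribution of the number of address changes over the window.

    ``move_counts`` gives probabilities for 0, 1, 2 and 3 changes plus an
    open "4 or more" category; the open category is expanded into a
    truncated geometric tail capped at ``window years - 1`` (the number
    of between-snapshot change points).  A mover's destination is drawn
    from the postal universe weighted by population share, excluding the
    current code.
    """

    p0: float = 0.48
    p1: float = 0.21
    p2: float = 0.17
    p3: float = 0.08
    p4_plus: float = 0.06
    tail_decay: float = 0.5  # geometric ratio inside the 4+ category

    def __post_init__(self):
        total = self.p0 + self.p1 + self.p2 + self.p3 + self.p4_plus
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"move-count probabilities sum to {total}, not 1")
        if not 0 < self.tail_decay < 1:
            raise ValueError("tail_decay must be in (0, 1)")

    def expand(self, max_moves: int) -> np.ndarray:
        """Full probability vector over 0..max_moves changes."""
        if max_moves < 0:
            raise ValueError("max_moves must be >= 0")
        base = np.array([self.p0, self.p1, self.p2, self.p3])
        if max_moves < 4:
            probs = base[: max_moves + 1]
            return probs / probs.sum()
        tail = self.tail_decay ** np.arange(max_moves - 3)
        tail = tail / tail.sum() * self.p4_plus
        return np.concatenate([base, tail])


@dataclass(frozen=True)
class DemographyModel:
    """Age pyramid, gender ratio and vital events for the synthetic population.

    ``age_breaks``/``age_masses`` define a piecewise-uniform distribution
    of age (in whole years) at the start of the window for persons born
    before it; ``birth_fraction`` of persons are instead born during the
    window (uniformly over window years).  ``death_hazards`` maps age
    bands to annual death probabilities applied year by year.
    """

    age_breaks: tuple = (0, 20, 40, 65, 91)
    age_masses: tuple = (0.35, 0.28, 0.24, 0.13)
    female_fraction: float = 0.51
    birth_fraction: float = 0.10
    death_hazards: tuple = ((40, 0.0015), (65, 0.008), (80, 0.03), (1000, 0.10))

    def __post_init__(self):
        if len(self.age_masses) != len(self.age_breaks) - 1:
            raise ValueError("age_masses must have one entry per age band")
        if abs(sum(self.age_masses) - 1.0) > 1e-9:
            raise ValueError("age_masses must sum to 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if not 0 <= self.birth_fraction <= 1:
            raise ValueError("birth_fraction must be in [0, 1]")
        for _, h in self.death_hazards:
            if not 0 <= h <= 1:
                raise ValueError("death hazards must be probabilities")

    @staticmethod
    def cross_sectional(**kwargs) -> "DemographyModel":
        """A demography with no in-window vital events.

        Everyone is alive for the whole window with ages spread 0-90 at
        the window start — the right population for single-snapshot
        (cross-sectional) uniqueness studies, where unborn/dead sentinel
        years never arise.
        """
        kwargs.setdefault("birth_fraction", 0.0)
        kwargs.setdefault("death_hazards", ((1000, 0.0),))
        return DemographyModel(**kwargs)

    def sample_start_ages(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Integer ages at the window start, from the piecewise pyramid."""
        lo = np.array(self.age_breaks[:-1])
        hi = np.array(self.age_breaks[1:])
        band = rng.choice(len(lo), size=n, p=np.array(self.age_masses))
        return lo[band] + np.floor(rng.random(n) * (hi[band] - lo[band])).astype(int)

    def hazard(self, ages: np.ndarray) -> np.ndarray:
        """Annual death probability for each age."""
        out = np.zeros(len(ages))
        prev = -1
        for upper, h in self.death_hazards:
            out[(ages > prev) & (ages <= upper)] = h
            prev = upper
        return out


@dataclass(frozen=True)
class CorruptionModel:
    """Data-quality defects injected into an otherwise clean registry.

    With probability ``p_missing_all`` a person's postal codes are all
    blanked; with probability ``p_inconsistent`` a person receives a
    postal code in a year strictly before birth or strictly after death.
    The two defects are mutually exclusive per person.
    """

    p_missing_all: float = 0.01
    p_inconsistent: float = 0.05

    def __post_init__(self):
        if not 0 <= self.p_missing_all <= 1 or not 0 <= self.p_inconsistent <= 1:
            raise ValueError("corruption probabilities must be in [0, 1]")
        if self.p_missing_all + self.p_inconsistent > 1:
            raise ValueError("p_missing_all + p_inconsistent must be <= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to generate one synthetic registry."""

    n_persons: int
    first_year: int = 1996
    last_year: int = 2006
    seed: int = 0
    universe: PostalUniverse | None = None
    mobility: MobilityModel = field(default_factory=MobilityModel)
    demography: DemographyModel = field(default_factory=DemographyModel)
    corruption: CorruptionModel = field(default_factory=CorruptionModel)

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.last_year < self.first_year:
            raise ValueError("last_year must be >= first_year")

    @staticmethod
    def metropolitan(n_persons: int, seed: int = 0, *,
                     mean_cell_size: float = 48.0, **kwargs) -> "SyntheticConfig":
        """Config with a postal universe sized so cells average ~48 residents."""
        n_codes = max(1, int(round(n_persons / mean_cell_size)))
        universe = build_postal_universe(n_codes, mean_cell_size, seed=seed + 1)
        return SyntheticConfig(n_persons=n_persons, seed=seed,
                               universe=universe, **kwargs)

    @staticmethod
    def from_dict(payload: dict) -> "SyntheticConfig":
        """Build a config from a plain key/value mapping (e.g. parsed JSON).

        Nested keys ``universe`` (passed to :func:`build_postal_universe`),
        ``mobility``, ``demography`` and ``corruption`` (dataclass fields)
        are optional; tuples inside the demography model may be given as
        lists.
        """
        payload = dict(payload)
        universe = None
        if "universe" in payload:
            universe = build_postal_universe(**payload.pop("universe"))
        mobility = MobilityModel(**payload.pop("mobility", {}))
        demog_kwargs = {
            k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
            if isinstance(v, list) else v
            for k, v in payload.pop("demography", {}).items()}
        demography = DemographyModel(**demog_kwargs)
        corruption = CorruptionModel(**payload.pop("corruption", {}))
        return SyntheticConfig(universe=universe, mobility=mobility,
                               demography=demography, corruption=corruption,
                               **payload)

    @staticmethod
    def from_json(path) -> "SyntheticConfig":
        """Build a config from a JSON file of :meth:`from_dict` keys."""
        import json
        with open(path) as fh:
            return SyntheticConfig.from_dict(json.load(fh))

    def with_universe(self) -> "SyntheticConfig":
        if self.universe is not None:
            return self
        return replace(self, universe=build_postal_universe(
            max(1, int(round(self.n_persons / 48.0))), 48.0, seed=self.seed + 1))


# ---------------------------------------------------------------------------
# population synthesis
# ---------------------------------------------------------------------------

def generate_population(config: SyntheticConfig) -> Registry:
    """Generate a clean synthetic registry (no corruption applied).

    Every person has gender, date of birth, an optional in-window date of
    death, and a postal code for each window year between birth and death;
    years outside the person's lifespan are empty until
    :func:`trailrisk.registry_io.encode_sentinels` runs.  The number of
    address changes is drawn from the mobility model's move-count
    distribution and the change years are placed uniformly at random
    among the person's in-life change points (truncating the drawn count
    for persons alive for only part of the window).  Deterministic for a
    fixed config and seed.
    """
    config = config.with_universe()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    first, last = config.first_year, config.last_year
    years = np.arange(first, last + 1)
    ny = len(years)
    demog, universe = config.demography, config.universe

    gender = np.where(rng.random(n) < demog.female_fraction, "F", "M")

    window_born = rng.random(n) < demog.birth_fraction
    start_ages = demog.sample_start_ages(rng, n)
    birth_year = np.where(window_born,
                          rng.integers(first, last + 1, size=n),
                          first - 1 - start_ages)
    birth_doy = 1 + np.floor(rng.random(n) * _days_in_year(birth_year)).astype(int)

    # year-by-year survival under age-band hazards
    death_year = np.full(n, _ALIVE, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    for y in years:
        at_risk = alive & (birth_year <= y)
        h = demog.hazard(y - birth_year)
        dies = at_risk & (rng.random(n) < h)
        death_year[dies] = y
        alive &= ~dies

    dead = death_year != _ALIVE
    death_doy = np.ones(n, dtype=int)
    if dead.any():
        dy = np.where(dead, death_year, birth_year)
        span = _days_in_year(dy).astype(float)
        lo = np.where(dead & (death_year == birth_year), birth_doy, 1)
        death_doy = (lo + np.floor(rng.random(n) * (span - lo + 1))).astype(int)

    first_in = np.maximum(birth_year, first)
    last_in = np.minimum(np.where(dead, death_year, last), last)

    # move counts: draw from the full-window distribution, truncate to the
    # person's available change points
    probs = config.mobility.expand(ny - 1)
    m = rng.choice(len(probs), size=n, p=probs)
    cap = np.maximum(last_in - first_in, 0)
    m = np.minimum(m, cap)

    # place the m change years uniformly without replacement among the
    # person's in-life change points (random-sort trick)
    grid = np.broadcast_to(years, (n, ny))
    changeable = (grid > first_in[:, None]) & (grid <= last_in[:, None])
    u = rng.random((n, ny))
    u[~changeable] = np.inf
    ranks = np.argsort(np.argsort(u, axis=1), axis=1)
    is_change = changeable & (ranks < m[:, None])

    # one code per residence segment; consecutive segments must differ
    n_seg = ny  # at most ny segments
    seg_codes = rng.choice(universe.n_codes, size=(n, n_seg), p=universe.shares)
    if universe.n_codes > 1:
        for s in range(1, n_seg):
            clash = seg_codes[:, s] == seg_codes[:, s - 1]
            while clash.any():
                seg_codes[clash, s] = rng.choice(
                    universe.n_codes, size=int(clash.sum()), p=universe.shares)
                clash = seg_codes[:, s] == seg_codes[:, s - 1]
    segment = np.cumsum(is_change, axis=1)
    code_idx = np.take_along_axis(seg_codes, segment, axis=1)

    trail = universe.codes[code_idx].astype(object)
    in_life = (grid >= first_in[:, None]) & (grid <= last_in[:, None])
    trail[~in_life] = ""

    frame = pd.DataFrame({
        "person_id": [f"P{i:07d}" for i in range(n)],
        "gender": gender,
        "date_of_birth": _dates_from(birth_year, birth_doy),
        "date_of_death": _dates_from(death_year, death_doy, valid=dead),
    })
    for j, y in enumerate(years):
        frame[year_column(int(y))] = trail[:, j]
    return Registry(frame, first, last)


def _days_in_year(year: np.ndarray) -> np.ndarray:
    y = np.asarray(year)
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    return np.where(leap, 366, 365)


def _dates_from(year, doy, valid=None) -> pd.Series:
    """Datetimes from (year, day-of-year); NaT where ``valid`` is False."""
    year = np.asarray(year)
    doy = np.asarray(doy)
    if valid is None:
        valid = np.ones(len(year), dtype=bool)
    safe_year = np.where(valid, year, 2000)
    stamps = pd.to_datetime(
        pd.Series(safe_year * 1000 + doy), format="%Y%j", errors="coerce")
    stamps[~valid] = pd.NaT
    return stamps


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def apply_corruption(registry: Registry, corruption: CorruptionModel,
                     seed: int = 0) -> Registry:
    """Inject missing-trail and inconsistent-trail defects into a registry.

    Independently per person, with probability ``p_missing_all`` every
    postal field is blanked; with probability ``p_inconsistent`` a postal
    code is written into a year strictly before birth or strictly after
    death.  Only persons with such out-of-life years can be made
    inconsistent, so inconsistency targets are re-drawn among eligible
    persons; the registry must not yet be sentinel-encoded.
    """
    trail = registry.trail_matrix()
    if (trail == UNBORN_SENTINEL).any() or (trail == DEAD_SENTINEL).any():
        raise ValueError("corruption must be applied before sentinel encoding")

    rng = np.random.default_rng(seed)
    n = registry.n_persons
    u = rng.random(n)
    missing = u < corruption.p_missing_all
    n_inconsistent = int(
        ((u >= corruption.p_missing_all)
         & (u < corruption.p_missing_all + corruption.p_inconsistent)).sum())

    by = registry.birth_years()
    dy = registry.death_years()
    years = np.array(registry.years)
    eligible = (by > registry.first_year) | (dy < registry.last_year)
    pool = np.flatnonzero(eligible & ~missing)

    targets = np.array([], dtype=int)
    if n_inconsistent > 0:
        if pool.size == 0:
            warnings.warn(
                "p_inconsistent > 0 but no person has out-of-life years; "
                "no inconsistent records can be created", UserWarning)
        else:
            if pool.size < n_inconsistent:
                warnings.warn(
                    f"only {pool.size} persons eligible for inconsistency "
                    f"injection; {n_inconsistent} requested", UserWarning)
            targets = rng.choice(pool, size=min(n_inconsistent, pool.size),
                                 replace=False)

    trail = trail.copy()
    trail[missing, :] = ""
    for i in targets:
        bad_years = np.flatnonzero((years < by[i]) | (years > dy[i]))
        j = int(rng.choice(bad_years))
        real = [c for c in trail[i] if c]
        trail[i, j] = real[0] if real else "A1A1A1"

    out = registry.copy()
    out.frame[registry.year_columns] = trail
    return out


# ---------------------------------------------------------------------------
# summaries used for calibration
# ---------------------------------------------------------------------------

def count_moves(registry: Registry) -> np.ndarray:
    """Number of address changes per person.

    A change is counted whenever two consecutive observed (non-empty,
    non-sentinel) annual postal codes differ; missing or sentinel years
    are skipped.
    """
    trail = registry.trail_matrix()
    n = registry.n_persons
    moves = np.zeros(n, dtype=int)
    last = np.full(n, None, dtype=object)
    for j in range(trail.shape[1]):
        col = trail[:, j]
        valid = (col != "") & (col != UNBORN_SENTINEL) & (col != DEAD_SENTINEL)
        seen = last != None  # noqa: E711  (elementwise against object array)
        moves += (valid & seen & (col != last)).astype(int)
        last = np.where(valid, col, last)
    return moves


def full_window_mask(registry: Registry) -> np.ndarray:
    """True for persons alive for the entire study window."""
    by = registry.birth_years()
    dy = registry.death_years()
    return (by <= registry.first_year) & (dy >= registry.last_year)


def aggregate_counts_from_registry(
    registry: Registry,
    reference_year: int,
    *,
    by: str = "birth_year",
    urban: dict | None = None,
) -> pd.DataFrame:
    """Aggregate a registry into (postal code x age/birth-year x gender) counts.

    Counts cover persons alive in ``reference_year`` with an observed
    postal code for that year.  ``by`` selects whether the output carries
    ``birth_year`` or ``age`` (age attained in the reference year, i.e.
    reference year minus birth year).  ``urban`` optionally maps postal
    codes to 0/1 flags; unknown codes default to urban (1).
    """
    if not registry.first_year <= reference_year <= registry.last_year:
        raise ValueError(
            f"reference_year {reference_year} outside window "
            f"{registry.first_year}-{registry.last_year}")
    if by not in ("birth_year", "age"):
        raise ValueError("by must be 'birth_year' or 'age'")

    col = registry.frame[year_column(reference_year)]
    bys = registry.birth_years()
    dys = registry.death_years()
    alive = (bys <= reference_year) & (dys >= reference_year)
    observed = alive & (col != "") & (col != UNBORN_SENTINEL) & (col != DEAD_SENTINEL)

    sub = pd.DataFrame({
        "postal_code": col[observed],
        by: (reference_year - bys[observed]) if by == "age" else bys[observed],
        "gender": registry.frame["gender"][observed],
    })
    counts = (sub.groupby(["postal_code", by, "gender"], observed=True)
              .size().rename("count").reset_index())
    urban = urban or {}
    counts["urban"] = counts["postal_code"].map(lambda c: urban.get(c, 1)).astype(int)
    return counts
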