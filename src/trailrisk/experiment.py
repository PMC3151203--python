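"""The study-point loop: trail resampling, stopping rule, strata, policies.

A *study point* is one generalization level combined with one trail
length ``k``.  Because a k-year trail can be any k-subset of the window
years, the uniqueness of a study point is defined as the average over
random trail-year subsets: each iteration draws a fresh subset, builds
quasi-identifier keys, computes (or estimates) uniqueness, and updates a
running mean until the mean stabilizes.

The module also provides the youth/adult split (youth = under 20 in the
sampled years), closed-form sensitivity bounds for the records removed by
quality control, and policy tables flagging which study points fall below
the 5% / 20% uniqueness thresholds used for research data disclosures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .generalize import GeneralizationLevel, TrailSpec, build_quasi_identifiers
from .registry import Registry
from .uniqueness import (
    SamplingDesign,
    exact_uniqueness,
    frequency_spectrum,
    zayatz_estimate,
)


@dataclass(frozen=True)
class StoppingRule:
    """Stop iterating once the running mean uniqueness stabilizes.

    The loop stops when the change in the cumulative mean stays below
    ``delta`` over ``window`` iterations (and at least ``min_iterations``
    have run), or at ``max_iterations``.  ``mode='consecutive'`` requires
    every one of the last ``window`` iteration-to-iteration changes to be
    below ``delta``; ``mode='lag'`` compares the mean to its value
    ``window`` iterations earlier.
    """

    delta: float = 1e-4
    window: int = 10
    max_iterations: int = 1000
    min_iterations: int = 10
    mode: str = "consecutive"

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 1 <= self.min_iterations <= self.max_iterations:
            raise ValueError("need 1 <= min_iterations <= max_iterations")
        if self.mode not in ("consecutive", "lag"):
            raise ValueError("mode must be 'consecutive' or 'lag'")

    def should_stop(self, means: list[float]) -> bool:
        i = len(means)
        if i >= self.max_iterations:
            return True
        if i < self.min_iterations:
            return False
        if self.mode == "lag":
            return abs(means[-1] - means[-min(self.window + 1, i)]) < self.delta
        deltas = [abs(b - a) for a, b in zip(means, means[1:])]
        w = min(self.window, len(deltas))
        return all(d < self.delta for d in deltas[-w:])


@dataclass(frozen=True)
class PolicyThresholds:
    """Acceptable-uniqueness ceilings for data disclosure decisions."""

    strict: float = 0.05
    relaxed: float = 0.20

    def __post_init__(self):
        if not 0 < self.strict < self.relaxed < 1:
            raise ValueError("need 0 < strict < relaxed < 1")


@dataclass(frozen=True)
class SensitivityInput:
    """Observed uniqueness on retained records plus the QC removal fraction."""

    u: float
    r: float = 0.06

    def __post_init__(self):
        if not 0 <= self.u <= 1 or not 0 <= self.r <= 1:
            raise ValueError("u and r must be in [0, 1]")


@dataclass
class EstimateResult:
    """Averaged uniqueness for one study point."""

    level: GeneralizationLevel
    k: int
    stratum: str
    mean: float
    n_iterations: int
    values: list[float] = field(repr=False, default_factory=list)
    method: str = "exact"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mean <= 1:
            raise ValueError(f"mean uniqueness {self.mean} outside [0, 1]")


def sample_trail_years(window_years, k: int, rng: np.random.Generator) -> TrailSpec:
    """Uniform random k-subset of the window years (sorted, no repeats)."""
    years = list(window_years)
    if not 1 <= k <= len(years):
        raise ValueError(f"trail length {k} outside 1..{len(years)}")
    chosen = rng.choice(len(years), size=k, replace=False)
    return TrailSpec(tuple(sorted(years[i] for i in chosen)))


def run_study_point(
    registry: Registry,
    level: GeneralizationLevel,
    k: int,
    rule: StoppingRule | None = None,
    method: str = "exact",
    design: SamplingDesign | None = None,
    seed: int = 0,
    *,
    stratum: str = "all",
    include_sentinels: bool = True,
) -> EstimateResult:
    """Average uniqueness at one study point over random trail-year subsets.

    Each iteration draws a k-subset of window years, builds keys at
    ``level``, and computes uniqueness — exactly (``method='exact'``) or
    with the Zayatz estimator (``method='zayatz'``, which treats the
    registry as a simple random sample under ``design``).  When only one
    subset exists (k equals the window length) a single iteration is run.
    """
    if registry.n_persons == 0:
        raise ValueError("cannot run a study point on an empty registry")
    if method not in ("exact", "zayatz"):
        raise ValueError("method must be 'exact' or 'zayatz'")
    if method == "zayatz" and design is None:
        raise ValueError("the zayatz method needs a SamplingDesign")
    rule = rule or StoppingRule()
    rng = np.random.default_rng(seed)
    years = registry.years
    if not 1 <= k <= len(years):
        raise ValueError(f"trail length {k} outside 1..{len(years)}")

    single_subset = comb(len(years), k) == 1
    values: list[float] = []
    means: list[float] = []
    while True:
        trail = sample_trail_years(years, k, rng)
        keys = build_quasi_identifiers(
            registry, level, trail, include_sentinels=include_sentinels)
        spectrum = frequency_spectrum(keys)
        if method == "exact":
            u = exact_uniqueness(spectrum).value
        else:
            u = zayatz_estimate(spectrum, design).value
        values.append(u)
        means.append(float(np.mean(values)))
        if single_subset or rule.should_stop(means):
            break

    return EstimateResult(level=level, k=k, stratum=stratum, mean=means[-1],
                          n_iterations=len(values), values=values,
                          method=method, seed=seed)


def stratify_youth_adult(
    registry: Registry, trail: TrailSpec, *, rule: str = "all"
) -> tuple[Registry, Registry]:
    """Split a registry into youth and adult strata for a given trail.

    A person's age in a snapshot year is ``year - birth_year`` (ages are
    taken at the start-of-year snapshot).  With ``rule='all'`` (default) a
    youth is under 20 in every selected year; ``rule='any'`` requires it
    in at least one selected year.  The two registries partition the input.
    """
    if rule not in ("all", "any"):
        raise ValueError("rule must be 'all' or 'any'")
    by = registry.birth_years()
    ages = np.stack([y - by for y in trail.years], axis=1)
    youth = (ages < 20).all(axis=1) if rule == "all" else (ages < 20).any(axis=1)
    return registry.subset(youth), registry.subset(~youth)


def sensitivity_bounds(inp: SensitivityInput) -> tuple[float, float]:
    """Extreme-case uniqueness bounds for the records removed by QC.

    If a fraction ``r`` of records was removed and the retained records
    show uniqueness ``u``, then had the removed records been corrected and
    retained, uniqueness would lie between ``(1-r)*u`` (none of them
    unique) and ``(1-r)*u + r`` (all of them unique).
    """
    u_min = (1.0 - inp.r) * inp.u
    u_max = u_min + inp.r
    return u_min, u_max


def policy_table(
    results: list[EstimateResult],
    thresholds: PolicyThresholds | None = None,
) -> pd.DataFrame:
    """Flag study points acceptable under the strict and relaxed thresholds.

    A study point is acceptable when its mean uniqueness does not exceed
    the threshold, so every strictly-acceptable point is also acceptable
    under the relaxed threshold.
    """
    thresholds = thresholds or PolicyThresholds()
    rows = []
    for r in results:
        rows.append({
            "stratum": r.stratum,
            "trail_length": r.k,
            "dob_level": r.level.dob_level,
            "postal_chars": r.level.postal_chars,
            "gender_included": r.level.include_gender,
            "method": r.method,
            "mean_uniqueness": r.mean,
            "n_iterations": r.n_iterations,
            "acceptable_strict": r.mean <= thresholds.strict,
            "acceptable_relaxed": r.mean <= thresholds.relaxed,
        })
    return pd.DataFrame(rows)


def run_lattice(
    registry: Registry,
    points: list[tuple[GeneralizationLevel, int]],
    rule: StoppingRule | None = None,
    method: str = "exact",
    design: SamplingDesign | None = None,
    seed: int = 0,
) -> list[EstimateResult]:
    """Run every study point in ``points`` with per-point derived seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(points))
    return [
        run_study_point(registry, level, k, rule=rule, method=method,
                        design=design, seed=int(s))
        for (level, k), s in zip(points, seeds)
    ]
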