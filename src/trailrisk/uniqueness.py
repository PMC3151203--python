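"""Population-uniqueness measures: exact, and Zayatz-estimated from a sample.

Population uniqueness — the fraction of individuals whose quasi-identifier
combination occurs exactly once in the population — is the re-identification
risk measure used throughout this package.  Everything needed to compute it
is the frequency spectrum: the counts ``c_j`` of equivalence classes that
contain exactly ``j`` records.

When only a simple random sample of the population is available, the
number of population uniques is estimated with the Zayatz construction:
the sample frequency spectrum serves as a plug-in prior over population
class sizes, a hypergeometric subsampling kernel gives the probability
that a population class of size ``j`` appears exactly once in the sample,
Bayes' rule converts these into P(population unique | sample unique), and
the sample-unique count is inflated by the sampling fraction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass(frozen=True)
class FrequencySpectrum:
    """Counts ``c_j`` of equivalence classes containing exactly ``j`` records."""

    counts: dict

    def __post_init__(self):
        for j, c in self.counts.items():
            if j < 1 or c < 0 or int(c) != c or int(j) != j:
                raise ValueError(f"invalid spectrum entry c_{j} = {c}")

    @property
    def n_classes(self) -> int:
        """C = number of equivalence classes."""
        return int(sum(self.counts.values()))

    @property
    def n_records(self) -> int:
        """T = total records represented."""
        return int(sum(j * c for j, c in self.counts.items()))

    def c(self, j: int) -> int:
        return int(self.counts.get(j, 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["class_size", "count"]
        )


@dataclass(frozen=True)
class SamplingDesign:
    """Simple random sample of ``n`` records from a population of ``N``."""

    N: int
    n: int

    def __post_init__(self):
        if not 1 <= self.n <= self.N:
            raise ValueError(f"need 1 <= n <= N, got n={self.n}, N={self.N}")

    @property
    def pi(self) -> float:
        """Sampling fraction n/N."""
        return self.n / self.N


@dataclass(frozen=True)
class UniquenessEstimate:
    """A uniqueness value with the method and inputs that produced it."""

    value: float
    method: str
    spectrum: FrequencySpectrum
    design: SamplingDesign | None = None

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"uniqueness {self.value} outside [0, 1]")


def frequency_spectrum(keys) -> FrequencySpectrum:
    """Frequency spectrum of a collection of hashable quasi-identifier keys."""
    if len(keys) == 0:
        raise ValueError("uniqueness is undefined for an empty key collection")
    if isinstance(keys, pd.Series):
        class_sizes = keys.value_counts().to_numpy()
        sizes, freq = np.unique(class_sizes, return_counts=True)
        counts = {int(j): int(c) for j, c in zip(sizes, freq)}
    else:
        counts = dict(Counter(Counter(keys).values()))
    return FrequencySpectrum(counts)


def exact_uniqueness(spectrum: FrequencySpectrum) -> UniquenessEstimate:
    """Proportion of records that are population-unique: c_1 / T."""
    T = spectrum.n_records
    if T == 0:
        raise ValueError("cannot compute uniqueness of an empty spectrum")
    return UniquenessEstimate(spectrum.c(1) / T, "exact", spectrum)


def _log_choose(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def p_sample_unique_given_pop_size(j, design: SamplingDesign,
                                   *, kernel: str = "hypergeometric"):
    """P(a population class of size ``j`` contributes exactly 1 sample record).

    Under simple random sampling of ``n`` from ``N`` this is the
    hypergeometric term ``j * C(N-j, n-1) / C(N, n)``, evaluated in log
    space.  ``kernel='binomial'`` substitutes the large-N approximation
    ``j * pi * (1 - pi)**(j-1)``.  Accepts a scalar or array ``j``.
    """
    j = np.asarray(j)
    if (j < 1).any() or (j > design.N).any():
        raise ValueError(f"class sizes must be in 1..N={design.N}")
    N, n = design.N, design.n
    if kernel == "binomial":
        pi = design.pi
        out = j * pi * (1.0 - pi) ** (j - 1)
    elif kernel == "hypergeometric":
        feasible = (N - j) >= (n - 1)
        js = np.where(feasible, j, 1)
        log_p = np.log(js) + _log_choose(N - js, n - 1) - _log_choose(N, n)
        out = np.where(feasible, np.exp(log_p), 0.0)
    else:
        raise ValueError("kernel must be 'hypergeometric' or 'binomial'")
    return out if out.ndim else float(out)


def zayatz_estimate(sample_spectrum: FrequencySpectrum, design: SamplingDesign,
                    *, kernel: str = "hypergeometric") -> UniquenessEstimate:
    """Estimate population uniqueness from a sample frequency spectrum.

    With sample spectrum ``c_j`` (C classes) and subsampling kernel
    ``p(j) = P(class of size j -> exactly 1 sample record)``::

        P(pop unique | sample unique) = p(1) (c_1/C) / sum_j p(j) (c_j/C)
        estimated population uniques  N1 = c_1 * P / pi
        uniqueness                    u  = N1 / N   (clamped to [0, 1])

    The sample is assumed to be a simple random sample of the population.
    A spectrum with no sample uniques yields 0.
    """
    c1 = sample_spectrum.c(1)
    if c1 == 0:
        return UniquenessEstimate(0.0, "zayatz", sample_spectrum, design)

    sizes = np.array(sorted(sample_spectrum.counts))
    cj = np.array([sample_spectrum.c(int(j)) for j in sizes], dtype=float)
    p = p_sample_unique_given_pop_size(sizes, design, kernel=kernel)
    p1 = p_sample_unique_given_pop_size(1, design, kernel=kernel)

    denom = float(np.dot(p, cj))
    p_pop_unique = (p1 * c1 / denom) if denom > 0 else 0.0
    n1_hat = c1 * p_pop_unique / design.pi
    u = min(1.0, max(0.0, n1_hat / design.N))
    return UniquenessEstimate(u, "zayatz", sample_spectrum, design)
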