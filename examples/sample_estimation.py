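"""Estimating population uniqueness from a 25% sample (Zayatz estimator).

When only a simple random sample is available, sample uniqueness
overstates population uniqueness: many sample uniques sit in larger
population classes.  The Zayatz estimator corrects for this with a
hypergeometric subsampling kernel.  Here a population with known
uniqueness is built, a 25% SRS drawn, and the estimate compared to truth.
"""

import numpy as np

import trailrisk as tr

N, pi, u_true = 50_000, 0.25, 0.30
n_unique = int(N * u_true)
# population keys: 15,000 singletons; the rest split between classes of 5
# records (which produce spurious sample uniques) and classes of 50
rest = N - n_unique
n5 = rest // 2 - (rest // 2) % 5
population = np.concatenate([
    -1 - np.arange(n_unique),
    np.arange(n5) // 5,
    n5 // 5 + np.arange(rest - n5) // 50,
])

rng = np.random.default_rng(8)
n = int(N * pi)
sample = rng.choice(population, size=n, replace=False)
_, class_sizes = np.unique(sample, return_counts=True)
sizes, freq = np.unique(class_sizes, return_counts=True)
spectrum = tr.FrequencySpectrum({int(j): int(c) for j, c in zip(sizes, freq)})

design = tr.SamplingDesign(N=N, n=n)
naive = tr.exact_uniqueness(spectrum).value
est = tr.zayatz_estimate(spectrum, design).value

print(f"true population uniqueness:      {100 * u_true:6.2f}%")
print(f"naive sample uniqueness:         {100 * naive:6.2f}%  (overstates)")
print(f"Zayatz estimate from the sample: {100 * est:6.2f}%")
# The estimator weights the c_1 sample uniques by the probability that a
# sample unique is a population unique, then inflates by 1/pi.
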