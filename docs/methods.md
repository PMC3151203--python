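# Methods

This note documents the models behind `trailrisk`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic data does and
does not establish about real registries.

## Risk model

Re-identification risk is measured as **population uniqueness**: the
proportion of individuals whose quasi-identifier combination occurs exactly
once in the population. The quasi-identifiers are date of birth, residence
postal code, and gender; longitudinal data adds the residential trail — one
postal snapshot per calendar year, taken at the beginning of the year.

Keys are **year-labelled**: the trail component of a key records *which* year
each (cropped) postal code belongs to, because the threat model assumes an
adversary who knows when a target lived where. The same assumption motivates
the sentinel codes: after quality control, years strictly before a person's
birth year become `UUUUUU` and years strictly after the death year become
`DDDDDD`, so that knowledge of a target's vital status is usable by the
adversary. A person "exists" in year Y iff birth year ≤ Y ≤ death year —
with beginning-of-year snapshots the birth year itself carries a real code
and the death year carries the last one. `build_quasi_identifiers`
accepts `include_sentinels=False` to model a less knowledgeable adversary for
whom unborn/dead years look like missing values; sentinels are stored without
a hyphen to preserve the 6-character fixed-width dialect, and real codes never
start with `U` or `D`, so cropped sentinels can never collide with cropped
real codes.

Ages are computed as `year − birth_year` (the age attained during the
snapshot year). The youth stratum is "under 20 in **every** selected trail
year" by default; the complementary "in any selected year" reading is
available via `stratify_youth_adult(..., rule="any")` since the natural-
language definition is ambiguous between the two.

## Zayatz estimation from a sample

When the data are a simple random sample of *n* from *N*, population uniques
are estimated by the Zayatz construction: the sample frequency spectrum is
the plug-in prior over population class sizes, the hypergeometric kernel
p(j) = j·C(N−j, n−1)/C(N, n) gives the probability that a population class of
size *j* appears exactly once in the sample, Bayes' rule yields
P(population unique | sample unique), and the sample-unique count is inflated
by 1/π. Hypergeometric terms are evaluated in log space via log-gamma for
stability at large N; a binomial approximation j·π(1−π)^(j−1) is available
via `kernel="binomial"` for very large populations. Estimates are clamped to
[0, 1] because sampling noise on pathological spectra can push the implied
unique count above N.

Two structural properties guard the implementation rather than any single
numeric value: at π = 1 the estimator reduces exactly to exact uniqueness,
and on synthetic populations with controlled spectra (singletons plus bulk
classes of ~50 records, the natural cell scale of 6-character postal codes)
the mean estimate over repeated 25% samples recovers the true uniqueness to
within ±0.05 for true values of 0.05, 0.3 and 0.8. The plug-in prior is known
to bias the estimate downward when the population contains many *small*
non-unique classes (sizes 2–5), since those classes masquerade as extra
sample-unique mass in the denominator; `examples/sample_estimation.py` shows
the effect. The sampler assumption is plain SRS at an explicit fraction π;
if a data set was assembled by repeated annual draws, the caller must decide
what effective π to use.

## Study-point averaging and the stopping rule

A study point's uniqueness is the mean over uniformly random k-subsets of the
window years, redrawn independently each iteration (subsets may repeat across
iterations). The stopping criterion tracks the cumulative mean: stop once
every one of the last 10 iteration-to-iteration changes is below δ = 10⁻⁴,
with at least 10 and at most 1000 iterations. At iteration *i* only *i−1*
changes exist, so the rule checks the trailing `min(window, i−1)` changes;
this makes a zero-variance registry stop exactly at the minimum iteration
count instead of one iteration later. The phrase "change over 10 iterations"
also admits a lag-10 reading, |mean_i − mean_{i−10}| < δ, available as
`StoppingRule(mode="lag")`. When k equals the window length there is only one
possible subset and a single iteration is run.

The generalization lattice enumerates 4 DOB levels × 7 postal lengths × 2
gender flags per trail length, excluding the two combinations with both DOB
and postal suppressed (a gender-only key is expressible directly but is not a
useful study point), i.e. 54 levels per trail length.

Policy acceptability uses ≤ (a study point exactly at a threshold is
acceptable); the 5%/20% thresholds follow precedents for disclosures to
external and trusted researchers respectively, and strict acceptability
implies relaxed by construction.

## Sensitivity bounds for QC removals

If a fraction *r* of records was removed by quality control and the retained
records show uniqueness *u*, the extreme cases had the removed records been
corrected and retained are closed-form: every removed record unique gives
u_max = (1−r)·u + r; none unique (and colliding with no retained unique)
gives u_min = (1−r)·u. At the default r = 0.06, an observed 20% can be as
high as 24.8% and an observed 5% as high as 10.7%.

## Synthetic registry generator

The generator emulates the structure of a provincial health-insurance
registry over an 11-year window (default 1996–2006). Its defaults are the
study conditions, not tuning knobs:

- **Postal universe.** 6-character letter-digit alternating codes drawn from
  the Canada Post letter set minus `D`/`U` (keeping real codes disjoint from
  sentinels), grouped ~75 codes per 3-character forward-sortation prefix.
  Per-code population shares are log-normal with σ = √(2·ln(mean/median)),
  calibrated to mean 48 / median 30 residents per code — the metropolitan
  profile — so cell sizes are right-skewed as in real postal geography. The
  codes with the largest shares (10% by default) are flagged rural, since
  rural postal codes cover larger populations.
- **Mobility.** Move counts are drawn from the categorical distribution
  48/21/17/8/6% for 0/1/2/3/4+ changes; the open 4+ category expands into a
  truncated geometric tail (ratio 0.5) capped at window_years − 1 change
  points. Change years are placed uniformly at random without replacement
  among the person's in-life change points — only the marginal move-count
  distribution is specified by the study conditions, so uniform timing is the
  simplest consistent completion. Destinations are drawn share-weighted from
  the universe, excluding the current code so every recorded change is a real
  change. Persons alive for only part of the window have fewer change points
  and their drawn count is truncated; calibration is therefore measured on
  persons alive for the whole window, for whom the marginal holds exactly.
- **Demography.** A piecewise-uniform age pyramid at the window start
  (masses 0.35/0.28/0.24/0.13 on ages 0–19/20–39/40–64/65–90, slightly
  youth-heavy so that roughly 30% of persons are under 20 in a mid-window
  year), 51% female, 10% of persons born during the window (uniform over
  window years), and annual death hazards by age band
  (0.0015/0.008/0.03/0.10 for <40/40–65/65–80/80+). Within-year moves are not
  modelled — residence is a beginning-of-year snapshot.
  `DemographyModel.cross_sectional()` switches off in-window vital events for
  single-snapshot studies where everyone should be alive with ages spread
  0–90.
- **Corruption.** Mutually exclusive per person via a single uniform draw:
  1% lose all postal codes; 5% receive a postal code in a year strictly
  outside their lifespan (injection targets are drawn among persons who have
  such years; a configuration warning is raised if none do). QC then removes
  exactly these defects, so realized removal rates are binomial around the
  configured rates.

What the generator does **not** emulate: household and family structure,
migration networks, real postal geography or census counts, seasonality of
births, or correlated data-entry errors. Passing tests therefore establish
that the pipeline's estimators and monotonicity properties behave correctly
on data with the right marginal structure — not that any particular real
city's uniqueness equals the synthetic values.

## Aggregate uniform-birthday estimation

Given counts per (postal code × birth year × gender), each person is assigned
a day of birth uniform over the calendar days of their birth year, exact
uniqueness on (generalized DOB, gender) is computed **within each postal
code** (the code's residents are the denominator — the literal per-code
reading; a pooled denominator can be assembled from the per-code results and
resident counts), and the assignment is repeated R = 1000 times with the
per-code mean reported. Real calendar lengths (365/366) are used rather than
a flat 365 — this keeps every generated date valid and changes collision
probabilities negligibly (a two-person same-year cell is unique with
probability 364/365 ≈ 0.99726 in a non-leap year, 365/366 in a leap year).
At the month/year level, leap-year day-of-year values are collapsed onto the
non-leap month boundaries (Feb 29 counts as February). At the year level the
draws are irrelevant and one repetition is computed. Ages convert to birth
years against an explicit reference year via `ages_to_birth_years`.

## Numerical and interface decisions

- Registries are pandas DataFrames wrapped in a light `Registry` container;
  keys are built with vectorized string operations and spectra via
  `value_counts`, so a 200,000-person single-snapshot uniqueness computation
  runs in seconds.
- Keys serialize components with a `|` separator and `year=` labels; since
  components are fixed-format (ISO dates, single-character gender, cropped
  codes), string equality coincides with component-wise equality.
- Records with *some* (not all) missing postal years pass QC (only all-missing
  and inconsistent records are removed) but raise in `encode_sentinels`,
  which refuses empty in-life years; callers who want to keep such records
  must clean them first.
- Determinism: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; identical config + seed reproduces registries
  byte-for-byte.
- Problem sizes: calibration checks run at n = 100,000 (three binomial
  standard errors distinguish the configured rates comfortably) and the
  end-to-end snapshot at n = 200,000 with ~4,200 postal codes; both complete
  in a few seconds on one core.

## Known limitations

- The Zayatz plug-in prior underestimates uniqueness when small non-unique
  population classes dominate; no superpopulation smoothing (Pitman, SUDA,
  log-linear) is provided.
- The generator's uniform move timing and share-weighted destinations are
  simplifications; real mobility is age-dependent and spatially local, which
  would concentrate trails and could raise longitudinal uniqueness.
- Sentinel-coded years participate in keys as ordinary values; mixed
  populations of living and dead persons therefore show collision structure
  within the sentinel groups that a registry restricted to living persons
  would not have.
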