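# Methods

## Model

A physician's screening performance on a metric is modelled as a binomial
proportion: k events (true-positive screens for CDR; all positive screens
for RR) in n independent examinations with a fixed per-exam event
probability p. The audit question is not "what is p̂?" but "does the data
rule out the benchmark threshold θ?", answered with a two-sided confidence
interval: adequate when the interval clears θ entirely on the favorable
side, inadequate when it misses entirely, uncertain otherwise.

The interval is the Wilson score interval with continuity correction
(Newcombe's closed form). For p̂ = k/n, q̂ = 1 − p̂, z = Φ⁻¹(1 − α/2):

    L = [2np̂ + z² − 1 − z·sqrt(z² − 2 − 1/n + 4p̂(nq̂ + 1))] / [2(n + z²)]
    U = [2np̂ + z² + 1 + z·sqrt(z² + 2 − 1/n + 4p̂(nq̂ − 1))] / [2(n + z²)]

The correction matters here because the decision rides on the interval
*endpoint* at small event counts (a CDR audit at n = 2000 rests on ~9
cancers); the corrected interval's exact coverage stays at or above nominal
where the uncorrected Wilson dips below (the `coverage` module computes this
exactly, by full binomial summation — no Monte Carlo).

### Endpoint conventions and guards

The corrected score equation |p̂ − p| − 1/(2n) = z·sqrt(p(1−p)/n) has no
valid lower root when p̂ ≤ 1/(2n); the closed form, evaluated blindly there,
returns a "lower bound" *above* p̂. We therefore pin L = 0 whenever
np̂ ≤ 1/2 (hence L = 0 exactly at p̂ = 0) and U = 1 whenever nq̂ ≤ 1/2 —
the same convention base R's `prop.test` uses. Radicands are clamped at 0
before the square root and bounds clamped to [0, 1] and to contain p̂.
Continuous (non-integer) numerators are permitted because boundary inversion
evaluates the formulas at arbitrary p̂; audit-facing code can demand integer
counts via `ProportionEstimate.require_integer`.

The normal quantile is the exact Φ⁻¹ (1.959964 at 95%); a `z=` override
(e.g. 1.96) exists for sensitivity checks and changes none of the headline
integer results.

### Classification conventions

Equality of the favorable bound with θ counts as adequate (the interval
touches the threshold from the good side). Equality of the unfavorable
bound is uncertain: "overlap" means any shared point, and no observed value
is declared confidently inadequate while its interval still touches the
acceptable region. RR is judged against its upper threshold only — a low
recall rate is harmful only through missed cancers, which the CDR benchmark
already captures.

## Boundary curves and minimum volume

The adequacy boundary at volume n solves bound(p̂, n) = θ for the favorable
bound. The bound is monotone in p̂, so we bisect on [0, 1] to an absolute
tolerance of 1e−10. Integer mode instead finds the extreme whole count k
whose bound clears θ (binary search over k; classification is monotone in k
at fixed n), yielding the sawtooth curves characteristic of rare events.
Unattainable boundaries (no rate clears θ at that n) are returned as an
explicit `None` marker, not an exception.

`minimum_volume` treats the level as continuous, brackets exponentially,
binary-searches for the smallest adequate n, then linearly re-checks a
50-volume window below the answer because the corrected bound is not
perfectly monotone in n at small volumes. The result satisfies, by
construction and by test: adequate at N_min, not adequate at N_min − 1.

Under these definitions the exact minimum volumes at the shipped reference
medians are 2777 (CDR at 4.4/1000 vs θ = 2.4/1000) and 121 (RR at 9.7% vs
θ = 16.8%). Region plots sample the boundary curves on a grid — every 10
exams for rare-event metrics (default curve range 100–10,000), every 5 for
common ones (10–2,000) — and a crossing read off such a plot lands on the
last grid point before the exact crossing: 2770 and 120. Both views are
exposed (`minimum_volume` / `boundary_crossing_volume`); the bounds at the
grid-read volumes round to the thresholds at one-decimal per-mille/percent
precision (2.39805 → 2.4; 16.80697 → 16.8), which is why volumes quoted at
that sampling resolution are self-consistent at printed precision.

### Poisson variants

For rare events the binomial count is effectively Poisson with mean λ = np.
The Poisson variant uses the score interval on λ — roots of
|k − λ| (− 0.5 if corrected) = z·sqrt(λ) — divided by n, tagged
`poisson`/`poisson_cc`. This is the closest standard construction for a
corrected Poisson rate interval; other choices (exact/Garwood,
mid-P) would shift boundaries by roughly one count, and the method tag
preserves the distinction. Tests confirm the Poisson and binomial integer
boundaries agree within one count for n ≥ 3000 at CDR-like rates, and that
the correction's effect on the bounds falls below 5% there.

## Audit pipeline

Outcome definitions: positive screen = initial BI-RADS assessment 0, 4, or
5; detected cancer = positive screen with invasive carcinoma or DCIS within
12 months of the exam; a cancer after a negative screen is an interval
cancer, never a detection. "Within 12 months" is implemented as ≤ 365 days
from the exam date (a fixed-day convention keeps tests deterministic); when
a cancer date is absent the boolean flag is authoritative, and a present
date inconsistent with the flag rejects the row. Periods are calendar
years, membership decided by the exam date. Eligibility follows the
MQSA-style floor: strictly more than `min_annual_volume` (default 480)
exams in *every* audited year. Trajectories order exams by date with a
lexicographic exam-id tie-break (reproducible regardless of file order) and
summarise cumulatively at 500, 1000, then 1000-exam checkpoints up to
min(total, 5000), appending the total as a final point when it is smaller.

## Synthetic generator

Each exam is an independent draw: cancer with probability
`cancer_prevalence`; a cancer is detected with probability `sensitivity`
(else it becomes an interval cancer behind a negative assessment);
cancer-free exams are recalled with the false-positive probability that
makes the overall recall rate equal `true_recall_rate`. Implied truths:
CDR = prevalence × sensitivity, RR = true_recall_rate. Defaults emulate a
small median-level practice — 4 readers × 1918 exams/year × 3 years,
RR 9.7%, prevalence 5/1000, sensitivity 0.88 (CDR 4.4/1000) — and
everything is reproducible from a single integer seed (same seed,
byte-identical CSV).

What the generator does *not* model: case-mix and density effects on
detection, reader-to-reader correlation, learning or drift over time,
diagnostic work-up after BI-RADS 0, and double reading. Passing tests
therefore demonstrate the statistical machinery — counting, interval
coverage at known truth, the boundary-case coin-flip at the minimum volume,
and the annual-uncertain/aggregate-adequate phenomenon — not clinical
realism of any particular practice.

## Problem sizes in the shipped checks

The test suite and acceptance script run at deliberately modest scale,
chosen as the smallest sizes at which each property is sharp: coverage
oracles use 2×10⁵–10⁶ binomial replicates against exact summation;
calibration uses 200 replicates of 10⁵ exams; the end-to-end pipeline check
uses 100 replicates of the 4-reader × 3-year practice (~23k exams each).

## Known limitations

* The three-way rule controls each physician's error rate at the stated
  confidence but makes no multiplicity adjustment across physicians, years,
  or metrics; a programme screening many readers will see some false
  "uncertain/inadequate" flags by construction.
* Coverage is computed under exact binomial sampling with a fixed p; exam
  volumes that are themselves outcome-dependent (readers who stop early)
  are outside the model.
* The inadequate/uncertain split at the unfavorable bound (strict
  inequality) is a convention; it is flagged in the shipped config
  documentation and matters only on measure-zero boundary cases.
* Poisson-variant coverage gets smoke tests only; the binomial interval is
  the decision instrument.
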