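# screenperf

Volume-aware confidence classification of physician cancer-screening
performance, with screening mammography as the worked example.

## The problem

Screening-audit programmes judge physicians on rates — the cancer detection
rate (CDR, true-positive screens per 1000 exams) and the recall rate (RR,
positive screens as a percent of exams) — against percentile benchmarks from
a national reference distribution (the BCSC: CDR 10th percentile 2.4/1000,
median 4.4/1000; RR 90th percentile 16.8%, median 9.7%). But a rate observed
over a finite interpretive volume is a noisy binomial proportion, and cancer
detection is rare: at typical annual volumes, a perfectly typical reader can
land on the wrong side of a benchmark by chance alone. Comparing point
estimates to thresholds misclassifies people.

`screenperf` instead classifies performance *with confidence*. For an
observed proportion p̂ = k/n it computes the two-sided Wilson score interval
with continuity correction (Newcombe), whose bounds solve

    |p̂ − p| − 1/(2n) = z · sqrt( p(1−p)/n ),   z = Φ⁻¹(1 − α/2),

with L pinned to 0 when p̂ ≤ 1/(2n) and U to 1 symmetrically, and classifies
against a directional threshold θ:

* **adequate** — the whole interval is on the favorable side (L ≥ θ for
  higher-is-better metrics like CDR; U ≤ θ for lower-is-better ones like RR);
* **inadequate** — the whole interval is on the unfavorable side (strict);
* **uncertain** — the interval overlaps θ: the volume is too small to decide.

Inverting the construction gives the *adequacy boundary* (least favorable
observed rate still classified adequate, as a function of volume — the
curves delimiting the three regions in the volume × rate plane) and the
*minimum volume* at which a given performance level becomes confidently
adequate. Exact finite-sample coverage of the interval procedure is computed
by exhaustive binomial summation. An audit pipeline applies all of this to
per-examination records (BI-RADS assessments, 12-month cancer outcomes), and
a seeded synthetic generator produces exam streams with known ground truth.

## Worked example

A reader detects 12 cancers in 2770 screens (4.33/1000 — just below the
reference median):

```
$ screenperf classify --metric CDR --events 12 -n 2770
{
  "category": "uncertain",
  "confidence": 0.95,
  "lower": 0.0023488986777377764,
  "metric": "CDR",
  "threshold": 0.0024,
  "upper": 0.007785749520145876
}
```

The 95% interval (2.35–7.79 per 1000) still overlaps the 2.4/1000 threshold,
so this volume cannot confirm adequacy — even though the point estimate is
1.8× the threshold. How many screens would a median-level detector (4.4/1000)
need before the benchmark is cleared with 95% confidence?

```
$ screenperf min-volume --metric CDR
{
  "attainable": true,
  "metric": "CDR",
  "minimum_volume": 2777,
  "performance_level": 0.0044,
  "search_cap": 1000000
}
```

About 2.8 thousand screens — above the US average annual volume (~1800) and
far above the US mandatory minimum (480), which is why single-year CDR audits
so often return "uncertain". (Read off a region plot sampled every 10 exams,
the crossing appears at 2770; `boundary_crossing_volume` reproduces that
readout.) The same question for recall rate at its median 9.7% against the
16.8% ceiling needs only 121 screens, because recalls are ~20× more common
than detections. At the average annual volume the boundary is well above the
median — `adequacy_boundary(1918, CDR_BENCHMARK)` returns 4.85/1000: a
one-year audit certifies only clearly above-median detectors.

Region curves, coverage diagnostics, and the full audit are also on the CLI:

```
screenperf curve --metric CDR --from 100 --to 10000 --step 10 --out curve.csv
screenperf coverage --p 0.0044 --from 50 --to 5000 --step 50 --out coverage.csv
screenperf simulate --seed 7 --out exams.csv
screenperf audit --exams exams.csv --out-dir results/
```

`audit` writes per-physician × period summaries (volume, recalls, detected
cancers, CDR, RR, and both classifications) and cumulative trajectories at
500, 1000, then 1000-exam checkpoints up to 5000.

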