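"""Three-way classification of observed performance against a benchmark.

A benchmark is a directional threshold taken from a reference distribution of
physician performance (for screening mammography: the BCSC percentiles).  A
physician *meets the benchmark with confidence* (adequate) when the whole
two-sided confidence interval for their observed rate lies on the favorable
side of the threshold; *fails it with confidence* (inadequate) when the whole
interval lies on the unfavorable side; and is *uncertain* when the interval
overlaps the threshold — the volume read is then simply too small to decide.

Shipped defaults are the BCSC mammography benchmarks: cancer detection rate
(CDR) threshold 2.4 per 1000 (10th percentile, higher is better, median
4.4/1000) and recall rate (RR) threshold 16.8% (90th percentile, lower is
better, median 9.7%).  Only an upper RR threshold is used: a low recall rate
is harmful only insofar as it depresses CDR, which the CDR benchmark already
captures.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import yaml

from .intervals import (
    BinomialInterval,
    ProportionEstimate,
    ValidationError,
    wilson_cc_interval,
)

__all__ = [
    "Direction",
    "Category",
    "Benchmark",
    "PerformanceClassification",
    "classify_performance",
    "classify_interval",
    "CDR_BENCHMARK",
    "RR_BENCHMARK",
    "default_benchmarks",
    "load_benchmarks",
]


class Direction(str, enum.Enum):
    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


class Category(str, enum.Enum):
    ADEQUATE = "adequate"
    UNCERTAIN = "uncertain"
    INADEQUATE = "inadequate"


@dataclass(frozen=True)
class Benchmark:
    """A directional performance threshold with its reference context.

    ``threshold`` is the reference-distribution percentile the confidence
    interval must clear entirely; ``reference_median`` is the distribution's
    median, used as the canonical "typical performer" level in volume
    planning.
    """

    metric_name: str
    threshold: float
    direction: Direction
    confidence: float = 0.95
    reference_median: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError(
                f"threshold must be in (0, 1), got {self.threshold}"
            )
        if not 0.0 < self.confidence < 1.0:
            raise ValidationError(
                f"confidence must be in (0, 1), got {self.confidence}"
            )
        if self.reference_median is not None:
            ok = (
                self.reference_median >= self.threshold
                if self.direction is Direction.HIGHER_IS_BETTER
                else self.reference_median <= self.threshold
            )
            if not ok:
                raise ValidationError(
                    f"reference_median {self.reference_median} is on the "
                    f"unfavorable side of threshold {self.threshold} for "
                    f"direction {self.direction.value}"
                )

    @property
    def higher_is_better(self) -> bool:
        return self.direction is Direction.HIGHER_IS_BETTER

    def favorable(self, value: float, strict: bool = True) -> bool:
        """Is ``value`` strictly on the favorable side of the threshold?"""
        if self.higher_is_better:
            return value > self.threshold if strict else value >= self.threshold
        return value < self.threshold if strict else value <= self.threshold


@dataclass(frozen=True)
class PerformanceClassification:
    """The category together with the interval and benchmark that produced it."""

    category: Category
    interval: BinomialInterval
    benchmark: Benchmark

    def as_dict(self) -> dict:
        return {
            "category": self.category.value,
            "lower": self.interval.lower,
            "upper": self.interval.upper,
            "threshold": self.benchmark.threshold,
            "metric": self.benchmark.metric_name,
            "confidence": self.interval.confidence,
        }


def classify_interval(
    interval: BinomialInterval, benchmark: Benchmark
) -> PerformanceClassification:
    """Classify an already-computed interval against a benchmark.

    Rules (theta = threshold):
      higher-is-better: adequate iff L >= theta; inadequate iff U < theta.
      lower-is-better:  adequate iff U <= theta; inadequate iff L > theta.
    Everything else is uncertain.  Equality of the *favorable* bound with
    theta counts as adequate (the interval just touches the threshold from
    the good side); equality of the unfavorable bound is uncertain, because
    the interval still shares a point with the acceptable region.
    """
    if abs(interval.confidence - benchmark.confidence) > 1e-12:
        raise ValidationError(
            f"interval confidence {interval.confidence} does not match "
            f"benchmark confidence {benchmark.confidence}"
        )
    theta = benchmark.threshold
    if benchmark.higher_is_better:
        if interval.lower >= theta:
            category = Category.ADEQUATE
        elif interval.upper < theta:
            category = Category.INADEQUATE
        else:
            category = Category.UNCERTAIN
    else:
        if interval.upper <= theta:
            category = Category.ADEQUATE
        elif interval.lower > theta:
            category = Category.INADEQUATE
        else:
            category = Category.UNCERTAIN
    return PerformanceClassification(category, interval, benchmark)


def classify_performance(
    estimate: ProportionEstimate,
    benchmark: Benchmark,
    z: float | None = None,
) -> PerformanceClassification:
    """Classify an observed rate as adequate / uncertain / inadequate.

    Computes the continuity-corrected Wilson interval at the benchmark's
    confidence level and applies :func:`classify_interval`.
    """
    interval = wilson_cc_interval(estimate, benchmark.confidence, z)
    return classify_interval(interval, benchmark)


# ---------------------------------------------------------------------------
# Shipped BCSC mammography defaults and YAML config loading
# ---------------------------------------------------------------------------

CDR_BENCHMARK = Benchmark(
    metric_name="CDR",
    threshold=0.0024,           # BCSC 10th percentile, 2.4 per 1000
    direction=Direction.HIGHER_IS_BETTER,
    confidence=0.95,
    reference_median=0.0044,    # 4.4 per 1000
)

RR_BENCHMARK = Benchmark(
    metric_name="RR",
    threshold=0.168,            # BCSC 90th percentile, 16.8%
    direction=Direction.LOWER_IS_BETTER,
    confidence=0.95,
    reference_median=0.097,     # 9.7%
)


def default_benchmarks() -> dict[str, Benchmark]:
    """The shipped BCSC screening-mammography benchmarks, keyed by metric."""
    return {"CDR": CDR_BENCHMARK, "RR": RR_BENCHMARK}


def _benchmarks_from_mapping(raw: list[dict]) -> dict[str, Benchmark]:
    out: dict[str, Benchmark] = {}
    for entry in raw:
        bench = Benchmark(
            metric_name=str(entry["metric_name"]),
            threshold=float(entry["threshold"]),
            direction=Direction(entry["direction"]),
            confidence=float(entry.get("confidence", 0.95)),
            reference_median=(
                float(entry["reference_median"])
                if entry.get("reference_median") is not None
                else None
            ),
        )
        out[bench.metric_name] = bench
    return out


def load_benchmarks(path: str | None = None) -> dict[str, Benchmark]:
    """Load benchmarks from a YAML config; with no path, the shipped defaults.

    The file holds a top-level ``benchmarks:`` list of mappings with the
    Benchmark fields (see ``screenperf/data/benchmarks.yaml``).
    """
    if path is None:
        text = (
            resources.files("screenperf").joinpath("data/benchmarks.yaml").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "benchmarks" not in raw:
        raise ValidationError("benchmark config must contain a 'benchmarks' list")
    return _benchmarks_from_mapping(raw["benchmarks"])
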