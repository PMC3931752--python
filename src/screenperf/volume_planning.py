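"""Volume-vs-performance boundary curves and minimum-volume inversion.

For a benchmark with threshold theta, the *adequacy boundary* at volume n is
the least favorable observed rate that is still classified adequate: the
p-hat whose continuity-corrected Wilson bound just clears theta.  Sweeping n
traces the curves that split the (volume, observed rate) plane into adequate,
uncertain, and inadequate regions; inverting the sweep gives the minimum
volume a physician must read before an observed rate can confidently clear
the benchmark.

Two views are provided.  The continuous view treats the observed rate as a
real number (non-integer event counts), which is what the headline
minimum-volume numbers use.  The integer view restricts to whole event
counts, producing the sawtooth curves characteristic of rare events: at small
volumes each additional required cancer moves the boundary by a visible step.
A Poisson variant replaces the binomial interval with a Poisson score
interval on the event rate, with optional 0.5-count continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classification import Benchmark
from .intervals import (
    ProportionEstimate,
    ValidationError,
    _poisson_score_bounds,
    _wilson_cc_bounds,
    z_from_confidence,
)

__all__ = [
    "VolumeCurvePoint",
    "VolumeRequirement",
    "adequacy_boundary",
    "poisson_boundary",
    "boundary_curve",
    "minimum_volume",
    "boundary_crossing_volume",
]

_BOUNDARY_TOL = 1e-10
_SCAN_WINDOW = 50  # downward guard against continuity-correction wiggles


@dataclass(frozen=True)
class VolumeCurvePoint:
    """Region boundaries at one volume.

    ``adequate_boundary`` is the least favorable observed rate classified
    adequate (smallest for higher-is-better, largest for lower-is-better);
    ``inadequate_boundary`` delimits the confidently-inadequate region the
    same way.  ``None`` marks a boundary unattainable at this volume (no
    observed rate, however extreme, clears the threshold).
    """

    volume: int
    adequate_boundary: float | None
    inadequate_boundary: float | None
    mode: str  # "continuous" | "integer"
    method: str = "wilson_cc"


@dataclass(frozen=True)
class VolumeRequirement:
    """Result of the minimum-volume search.

    ``minimum_volume`` is None when no volume up to ``search_cap`` makes the
    given performance level confidently adequate.
    """

    performance_level: float
    benchmark: Benchmark
    minimum_volume: int | None
    search_cap: int

    @property
    def attainable(self) -> bool:
        return self.minimum_volume is not None


def _favorable_bound(p_hat: float, n: int, benchmark: Benchmark, z: float) -> float:
    lower, upper = _wilson_cc_bounds(p_hat, n, z)
    return float(lower) if benchmark.higher_is_better else float(upper)


def _is_adequate(p_hat: float, n: int, benchmark: Benchmark, z: float) -> bool:
    bound = _favorable_bound(p_hat, n, benchmark, z)
    theta = benchmark.threshold
    return bound >= theta if benchmark.higher_is_better else bound <= theta


def _is_inadequate(p_hat: float, n: int, benchmark: Benchmark, z: float) -> bool:
    lower, upper = _wilson_cc_bounds(p_hat, n, z)
    if benchmark.higher_is_better:
        return float(upper) < benchmark.threshold
    return float(lower) > benchmark.threshold


def _solve_boundary(predicate, n: int, benchmark: Benchmark) -> float | None:
    """Smallest (higher-is-better) or largest (lower-is-better) p-hat
    satisfying a monotone adequacy-style predicate, by root bracketing."""
    higher = benchmark.higher_is_better
    # predicate is monotone in p-hat: False below the boundary, True above
    # (higher-is-better) or True below, False above (lower-is-better).
    lo, hi = 0.0, 1.0
    if higher:
        if not predicate(hi):
            return None
        if predicate(lo):
            return lo
    else:
        if not predicate(lo):
            return None
        if predicate(hi):
            return hi
    # Bisection on the indicator; 53 halvings reach ~1e-16, stop at tol.
    while hi - lo > _BOUNDARY_TOL:
        mid = 0.5 * (lo + hi)
        on_true_side = predicate(mid)
        if higher:
            if on_true_side:
                hi = mid
            else:
                lo = mid
        else:
            if on_true_side:
                lo = mid
            else:
                hi = mid
    return hi if higher else lo


def adequacy_boundary(
    volume: int,
    benchmark: Benchmark,
    mode: str = "continuous",
    z: float | None = None,
) -> VolumeCurvePoint:
    """Boundary observed rates separating the three regions at one volume.

    Continuous mode solves bound(p-hat, n) = theta on p-hat in [0, 1] to
    absolute tolerance 1e-10 and returns the least favorable adequate rate.
    Integer mode returns the corresponding whole-count boundary k/n: the
    smallest k with a clearing lower bound (higher-is-better) or the largest
    k with a clearing upper bound (lower-is-better); classification is
    monotone in k for fixed n, so a binary search over counts suffices.
    """
    if volume < 1:
        raise ValidationError(f"volume must be >= 1, got {volume}")
    if mode not in ("continuous", "integer"):
        raise ValidationError(f"mode must be 'continuous' or 'integer', got {mode!r}")
    zval = z_from_confidence(benchmark.confidence, z)
    n = int(volume)

    adequate = _solve_boundary(
        lambda p: _is_adequate(p, n, benchmark, zval), n, benchmark
    )
    # The inadequate region is delimited by the *other* interval endpoint with
    # strict inequality; its edge is where that endpoint meets theta.  The
    # not-inadequate predicate has the same orientation in p-hat as adequacy,
    # so the same solver applies; the edge itself is classified uncertain and
    # the open region beyond it is inadequate.
    edge = _solve_boundary(
        lambda p: not _is_inadequate(p, n, benchmark, zval), n, benchmark
    )
    inadequate = None
    if edge is not None:
        probe = (
            max(edge - 1e-9, 0.0)
            if benchmark.higher_is_better
            else min(edge + 1e-9, 1.0)
        )
        if _is_inadequate(probe, n, benchmark, zval):
            inadequate = edge

    if mode == "integer":
        adequate = _integer_boundary(adequate, n, benchmark, zval, region="adequate")
        inadequate = _integer_boundary(
            inadequate, n, benchmark, zval, region="inadequate"
        )
    return VolumeCurvePoint(n, adequate, inadequate, mode)


def _integer_boundary(
    continuous: float | None,
    n: int,
    benchmark: Benchmark,
    z: float,
    region: str,
) -> float | None:
    """Snap a continuous boundary to the nearest attaining whole count."""
    if continuous is None:
        return None
    higher = benchmark.higher_is_better
    want_adequate = region == "adequate"
    # Directions: adequate region is high-k for higher-is-better metrics and
    # low-k for lower-is-better ones; the inadequate region is the mirror.
    take_ceiling = higher if want_adequate else not higher

    def qualifies(k: int) -> bool:
        if k < 0 or k > n:
            return False
        if want_adequate:
            return _is_adequate(k / n, n, benchmark, z)
        return _is_inadequate(k / n, n, benchmark, z)

    k0 = math.ceil(continuous * n) if take_ceiling else math.floor(continuous * n)
    step = 1 if take_ceiling else -1
    # The continuous boundary may sit within one count of the integer one in
    # either direction; walk outward from the snapped count.
    k = k0 - step
    while 0 <= k <= n and qualifies(k):
        k -= step
    k += step
    while 0 <= k <= n and not qualifies(k):
        k += step
    if not 0 <= k <= n:
        return None
    return k / n


def poisson_boundary(
    volume: int,
    benchmark: Benchmark,
    corrected: bool = True,
    z: float | None = None,
) -> VolumeCurvePoint:
    """Integer-count boundaries using the Poisson score interval on the rate.

    Intended for rare-event metrics (cancer detection); usable for recall
    rates as well, where the Poisson and binomial views converge even sooner
    because events are more common.
    """
    if volume < 1:
        raise ValidationError(f"volume must be >= 1, got {volume}")
    zval = z_from_confidence(benchmark.confidence, z)
    n = int(volume)
    theta = benchmark.threshold
    higher = benchmark.higher_is_better

    def bounds(k: int):
        lo, hi = _poisson_score_bounds(k, n, zval, corrected)
        return float(lo), float(hi)

    def k_adequate(k: int) -> bool:
        lo, hi = bounds(k)
        return lo >= theta if higher else hi <= theta

    def k_inadequate(k: int) -> bool:
        lo, hi = bounds(k)
        return hi < theta if higher else lo > theta

    adequate = _scan_counts(k_adequate, n, ascending=higher)
    inadequate = _scan_counts(k_inadequate, n, ascending=not higher)
    method = "poisson_cc" if corrected else "poisson"
    return VolumeCurvePoint(
        n,
        None if adequate is None else adequate / n,
        None if inadequate is None else inadequate / n,
        "integer",
        method=method,
    )


def _scan_counts(qualifies, n: int, ascending: bool) -> int | None:
    """Extreme qualifying count via binary search (predicate monotone in k)."""
    lo, hi = 0, n
    if ascending:
        if not qualifies(n):
            return None
        while lo < hi:
            mid = (lo + hi) // 2
            if qualifies(mid):
                hi = mid
            else:
                lo = mid + 1
        return lo
    if not qualifies(0):
        return None
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if qualifies(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def boundary_curve(
    volumes,
    benchmark: Benchmark,
    mode: str = "continuous",
    z: float | None = None,
) -> list[VolumeCurvePoint]:
    """Evaluate :func:`adequacy_boundary` over a grid of volumes."""
    return [adequacy_boundary(int(n), benchmark, mode, z) for n in volumes]


def default_grid(benchmark: Benchmark) -> np.ndarray:
    """Plotting grid covering the informative volume range for a metric.

    Rare-event rates (threshold below 1%) need volumes in the thousands, so
    the grid runs 100..10000 in steps of 10; common-event rates resolve at
    10..2000 in steps of 5.
    """
    if benchmark.threshold < 0.01:
        return np.arange(100, 10001, 10)
    return np.arange(10, 2001, 5)


def minimum_volume(
    performance_level: float,
    benchmark: Benchmark,
    search_cap: int = 10**6,
    z: float | None = None,
) -> VolumeRequirement:
    """Smallest volume at which an observed rate is confidently adequate.

    Treats the observed rate as continuous (the event count n*p need not be
    whole).  Exponential bracketing finds an adequate volume, binary search
    isolates the smallest one, and a short downward linear scan guards
    against local non-monotonicity introduced by the continuity correction.
    The returned volume satisfies: adequate at ``minimum_volume``, not
    adequate at ``minimum_volume - 1``.

    A level exactly at the threshold is never adequate at any finite volume
    (the interval always straddles its own centre), so the search runs to the
    cap and reports unattainable; a level on the wrong side of the threshold
    is a validation error.
    """
    performance_level = float(performance_level)
    if not 0.0 <= performance_level <= 1.0:
        raise ValidationError(
            f"performance_level must be in [0, 1], got {performance_level}"
        )
    if search_cap < 1:
        raise ValidationError(f"search_cap must be >= 1, got {search_cap}")
    theta = benchmark.threshold
    wrong_side = (
        performance_level < theta
        if benchmark.higher_is_better
        else performance_level > theta
    )
    if wrong_side:
        raise ValidationError(
            f"performance_level {performance_level} is on the unfavorable side "
            f"of threshold {theta} for direction {benchmark.direction.value}"
        )
    zval = z_from_confidence(benchmark.confidence, z)

    def adequate(n: int) -> bool:
        return _is_adequate(performance_level, n, benchmark, zval)

    # Exponential bracketing.
    n = 1
    while n <= search_cap and not adequate(n):
        n *= 2
    if n > search_cap:
        if not adequate(search_cap):
            return VolumeRequirement(performance_level, benchmark, None, search_cap)
        n = search_cap
    lo, hi = max(n // 2, 1), n
    while lo < hi:
        mid = (lo + hi) // 2
        if adequate(mid):
            hi = mid
        else:
            lo = mid + 1
    best = lo
    # Guard window: accept any adequate volume a little below the search's
    # answer in case the corrected bound wiggles non-monotonically.
    for cand in range(max(best - _SCAN_WINDOW, 1), best):
        if adequate(cand):
            best = cand
            break
    return VolumeRequirement(performance_level, benchmark, best, search_cap)


def boundary_crossing_volume(
    performance_level: float,
    benchmark: Benchmark,
    step: int | None = None,
    z: float | None = None,
) -> int | None:
    """Volume at which the sampled boundary curve reaches a performance level.

    This is the graph-readout companion to :func:`minimum_volume`: evaluate
    the adequacy boundary on a volume grid of the given step and return the
    last sampled volume at which the level has *not yet* cleared the
    threshold — the grid point where the boundary curve crosses the level,
    at sampling resolution.  With the default plotting steps (10 for
    rare-event metrics, 5 otherwise) this reproduces volumes read off the
    region plots; it sits at most one grid step below the exact
    minimum-volume solution.
    """
    if step is None:
        step = 10 if benchmark.threshold < 0.01 else 5
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    req = minimum_volume(performance_level, benchmark, z=z)
    if req.minimum_volume is None:
        return None
    # Largest multiple of `step` strictly below the exact crossing.
    return ((req.minimum_volume - 1) // step) * step
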