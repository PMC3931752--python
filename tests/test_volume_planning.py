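"""Boundary curves, minimum-volume inversion, and the Poisson variants."""

import numpy as np
import pytest

from screenperf.classification import Benchmark, Category, classify_performance
from screenperf.intervals import ProportionEstimate, ValidationError
from screenperf.volume_planning import (
    adequacy_boundary,
    boundary_crossing_volume,
    boundary_curve,
    minimum_volume,
    poisson_boundary,
)


def brute_force_min_volume(level, benchmark, upto):
    """Independent oracle: linear scan with the public classifier."""
    for n in range(1, upto + 1):
        est = ProportionEstimate.from_rate(level, n)
        if classify_performance(est, benchmark).category is Category.ADEQUATE:
            return n
    return None


class TestMinimumVolume:
    def test_cdr_median_exact_minimum(self, cdr_benchmark):
        # Exact inversion of the continuity-corrected bound; brute force over
        # the candidate window is the oracle.
        req = minimum_volume(0.0044, cdr_benchmark)
        assert req.minimum_volume == brute_force_min_volume(
            0.0044, cdr_benchmark, 3000
        )
        assert req.minimum_volume == 2777

    def test_rr_median_exact_minimum(self, rr_benchmark):
        req = minimum_volume(0.097, rr_benchmark)
        assert req.minimum_volume == brute_force_min_volume(0.097, rr_benchmark, 500)
        assert req.minimum_volume == 121

    def test_requirement_invariant(self, cdr_benchmark, rr_benchmark):
        for level, bench in ((0.0044, cdr_benchmark), (0.097, rr_benchmark)):
            n = minimum_volume(level, bench).minimum_volume
            at = classify_performance(ProportionEstimate.from_rate(level, n), bench)
            below = classify_performance(
                ProportionEstimate.from_rate(level, n - 1), bench
            )
            assert at.category is Category.ADEQUATE
            assert below.category is not Category.ADEQUATE

    def test_better_performer_needs_fewer_exams(self, cdr_benchmark):
        req = minimum_volume(0.007, cdr_benchmark)
        assert req.minimum_volume < 2777
        assert req.minimum_volume == brute_force_min_volume(
            0.007, cdr_benchmark, 2777
        )

    def test_level_at_threshold_unattainable(self, cdr_benchmark):
        # The interval always straddles its own centre, so performing exactly
        # at the threshold can never clear it.
        req = minimum_volume(0.0024, cdr_benchmark, search_cap=10**6)
        assert req.minimum_volume is None
        assert not req.attainable

    def test_level_on_wrong_side_rejected(self, cdr_benchmark):
        with pytest.raises(ValidationError, match="unfavorable"):
            minimum_volume(0.001, cdr_benchmark)

    def test_insensitive_to_rounded_z(self, cdr_benchmark, rr_benchmark):
        # The published analysis is reproducible with either the exact normal
        # quantile or the rounded 1.96.
        assert minimum_volume(0.0044, cdr_benchmark, z=1.96).minimum_volume == 2777
        assert minimum_volume(0.097, rr_benchmark, z=1.96).minimum_volume == 121


class TestFigureReadout:
    def test_cdr_curve_crossing_matches_published_figure(self, cdr_benchmark):
        # Read at the region plot's 10-exam sampling step, the boundary curve
        # crosses the 4.4/1000 reference median at volume 2770.
        assert boundary_crossing_volume(0.0044, cdr_benchmark) == 2770

    def test_rr_curve_crossing_matches_published_figure(self, rr_benchmark):
        # At the 5-exam step the recall boundary crosses 9.7% at volume 120.
        assert boundary_crossing_volume(0.097, rr_benchmark) == 120

    def test_readout_sits_within_one_step_of_exact_minimum(self, cdr_benchmark):
        exact = minimum_volume(0.0044, cdr_benchmark).minimum_volume
        readout = boundary_crossing_volume(0.0044, cdr_benchmark, step=10)
        assert readout < exact <= readout + 10


class TestAdequacyBoundary:
    def test_cdr_boundary_at_2770_is_the_benchmark_median_at_print_precision(
        self, cdr_benchmark
    ):
        point = adequacy_boundary(2770, cdr_benchmark, mode="continuous")
        assert round(point.adequate_boundary * 1000, 1) == 4.4

    def test_rr_boundary_at_120_is_the_benchmark_median_at_print_precision(
        self, rr_benchmark
    ):
        point = adequacy_boundary(120, rr_benchmark, mode="continuous")
        assert round(point.adequate_boundary * 100, 1) == 9.7

    def test_boundary_classifies_consistently_on_grid(self, cdr_benchmark):
        for n in (480, 1000, 2770, 5000, 10000):
            point = adequacy_boundary(n, cdr_benchmark, mode="continuous")
            at = classify_performance(
                ProportionEstimate.from_rate(point.adequate_boundary, n), cdr_benchmark
            )
            assert at.category is Category.ADEQUATE
            just_below = classify_performance(
                ProportionEstimate.from_rate(point.adequate_boundary - 1e-9, n),
                cdr_benchmark,
            )
            assert just_below.category is not Category.ADEQUATE

    def test_boundary_orders_regions(self, cdr_benchmark):
        point = adequacy_boundary(2770, cdr_benchmark)
        assert point.inadequate_boundary < cdr_benchmark.threshold
        assert point.adequate_boundary > cdr_benchmark.threshold

    def test_curve_monotone_and_converges_to_threshold(self, cdr_benchmark):
        grid = [500, 1000, 2000, 4000, 8000, 16000, 10**6]
        values = [
            adequacy_boundary(n, cdr_benchmark).adequate_boundary for n in grid
        ]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))
        assert abs(values[-1] - cdr_benchmark.threshold) < 1e-4

    def test_minimum_volume_idempotent_with_boundary(self, cdr_benchmark):
        for n in (2770, 3000, 5000):
            level = adequacy_boundary(n, cdr_benchmark).adequate_boundary
            req = minimum_volume(level, cdr_benchmark)
            assert req.minimum_volume <= n

    def test_unattainable_boundary_marked_not_raised(self):
        # At n = 1 no recall rate is confidently adequate against 16.8%.
        bench = Benchmark("RR", 0.168, "lower_is_better", 0.95)
        point = adequacy_boundary(1, bench)
        assert point.adequate_boundary is None


class TestIntegerMode:
    def test_integer_boundary_demands_at_least_the_continuous_one(
        self, cdr_benchmark
    ):
        for n in (500, 1000, 2500, 4000):
            cont = adequacy_boundary(n, cdr_benchmark, mode="continuous")
            integer = adequacy_boundary(n, cdr_benchmark, mode="integer")
            if integer.adequate_boundary is None:
                continue
            k = integer.adequate_boundary * n
            assert k == pytest.approx(round(k), abs=1e-9)
            assert integer.adequate_boundary >= cont.adequate_boundary - 1e-12

    def test_sawtooth_shape_of_integer_curve(self, cdr_benchmark):
        # Required whole counts step down over a volume sweep, so the rate
        # boundary k/n falls then jumps: strictly more distinct slopes than a
        # smooth curve would show and at least one upward jump.
        pairs = []
        for n in range(200, 4001, 50):
            point = adequacy_boundary(n, cdr_benchmark, mode="integer")
            if point.adequate_boundary is not None:
                pairs.append((n, round(point.adequate_boundary * n)))
        ks = [k for _, k in pairs]
        assert len(set(ks)) > 1  # count requirement changes across the sweep
        rates = [k / n for n, k in pairs]
        ups = sum(b > a for a, b in zip(rates, rates[1:]))
        downs = sum(b < a for a, b in zip(rates, rates[1:]))
        assert ups > 0 and downs > 0  # the sawtooth rises and falls


class TestPoissonVariants:
    def test_correction_negligible_at_5000_for_cdr(self, cdr_benchmark):
        # On the interval itself (evaluated at the median detection count for
        # 5000 exams) the 0.5-count correction moves the favorable bound by
        # under 5%; the whole-count boundary curves consequently differ by at
        # most a single cancer.
        from screenperf.intervals import ProportionEstimate, poisson_interval

        est = ProportionEstimate(22, 5000)  # 4.4/1000 of 5000
        cc = poisson_interval(est, corrected=True)
        plain = poisson_interval(est, corrected=False)
        assert abs(cc.lower - plain.lower) / plain.lower < 0.05

        b_cc = poisson_boundary(5000, cdr_benchmark, corrected=True)
        b_plain = poisson_boundary(5000, cdr_benchmark, corrected=False)
        assert (
            abs(b_cc.adequate_boundary - b_plain.adequate_boundary) * 5000 <= 1 + 1e-9
        )

    def test_poisson_matches_binomial_within_one_count_for_rare_events(
        self, cdr_benchmark
    ):
        for n in range(3000, 10001, 1000):
            pois = poisson_boundary(n, cdr_benchmark, corrected=True)
            binom = adequacy_boundary(n, cdr_benchmark, mode="integer")
            k_pois = round(pois.adequate_boundary * n)
            k_binom = round(binom.adequate_boundary * n)
            assert abs(k_pois - k_binom) <= 1

    def test_correction_effect_smaller_for_common_events(
        self, cdr_benchmark, rr_benchmark
    ):
        # At matched volume the recall rate's higher event count makes the
        # 0.5-count correction relatively less important than for detection:
        # compare the relative shift of the favorable interval bound at each
        # metric's median event count for 500 exams.
        from screenperf.intervals import ProportionEstimate, poisson_interval

        def rel_effect(median, n, favorable):
            est = ProportionEstimate(round(median * n), n)
            cc = poisson_interval(est, corrected=True)
            plain = poisson_interval(est, corrected=False)
            a, b = getattr(cc, favorable), getattr(plain, favorable)
            return abs(a - b) / b

        n = 500
        assert rel_effect(0.097, n, "upper") < rel_effect(0.0044, n, "lower")


class TestCurveHelpers:
    def test_boundary_curve_evaluates_grid(self, rr_benchmark):
        points = boundary_curve([100, 200, 300], rr_benchmark)
        assert [p.volume for p in points] == [100, 200, 300]
        assert all(p.mode == "continuous" for p in points)

    def test_invalid_volume_rejected(self, cdr_benchmark):
        with pytest.raises(ValidationError, match="volume"):
            adequacy_boundary(0, cdr_benchmark)

    def test_invalid_mode_rejected(self, cdr_benchmark):
        with pytest.raises(ValidationError, match="mode"):
            adequacy_boundary(100, cdr_benchmark, mode="both")
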