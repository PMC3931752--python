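"""Two-sided confidence intervals for binomial proportions and Poisson rates.

The workhorse is the Wilson score interval with continuity correction
(Newcombe's closed form), which is the interval behind every performance
classification in this package.  A plain Wilson variant quantifies the effect
of the correction, and Poisson score intervals on the event rate provide the
rare-event view used for cancer detection rates.

Proportions here may have *continuous* numerators: boundary-curve inversion
evaluates the closed forms at non-integer event counts.  Audit-facing code can
require integer counts via :meth:`ProportionEstimate.require_integer`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "ProportionEstimate",
    "BinomialInterval",
    "ValidationError",
    "wilson_cc_interval",
    "wilson_interval",
    "poisson_interval",
    "z_from_confidence",
]


class ValidationError(ValueError):
    """Raised when an input is non-finite or outside its documented domain."""


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


def z_from_confidence(confidence: float, z: float | None = None) -> float:
    """Standard-normal quantile at 1 - alpha/2 for a two-sided interval.

    ``z`` overrides the exact quantile (e.g. ``z=1.96``) for sensitivity
    checks against hand calculations that use the rounded critical value.
    """
    confidence = _check_finite("confidence", confidence)
    if not 0.0 < confidence < 1.0:
        raise ValidationError(f"confidence must be in (0, 1), got {confidence}")
    if z is not None:
        z = _check_finite("z", z)
        if z <= 0:
            raise ValidationError(f"z must be positive, got {z}")
        return z
    return float(norm.ppf(0.5 + confidence / 2.0))


@dataclass(frozen=True)
class ProportionEstimate:
    """An observed performance value: event count over interpretive volume.

    ``numerator`` may be continuous (non-integer) because the volume-planning
    boundary math evaluates interval formulas at arbitrary p-hat; records
    ingested from audit data always carry integer counts.
    """

    numerator: float
    denominator: int

    def __post_init__(self) -> None:
        num = _check_finite("numerator", self.numerator)
        if not float(self.denominator).is_integer() or self.denominator < 1:
            raise ValidationError(
                f"denominator must be a positive integer, got {self.denominator!r}"
            )
        if num < 0:
            raise ValidationError(f"numerator must be non-negative, got {num}")
        if num > self.denominator:
            raise ValidationError(
                f"numerator {num} exceeds denominator {self.denominator}"
            )
        object.__setattr__(self, "denominator", int(self.denominator))

    @classmethod
    def from_rate(cls, value: float, denominator: int) -> "ProportionEstimate":
        """Build from a proportion instead of a count (continuous numerator)."""
        value = _check_finite("value", value)
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"value must be in [0, 1], got {value}")
        return cls(numerator=value * int(denominator), denominator=int(denominator))

    @property
    def value(self) -> float:
        """The proportion p-hat = numerator / denominator."""
        return self.numerator / self.denominator

    @property
    def is_integer_count(self) -> bool:
        return float(self.numerator).is_integer()

    def require_integer(self) -> "ProportionEstimate":
        if not self.is_integer_count:
            raise ValidationError(
                f"numerator must be an integer count, got {self.numerator}"
            )
        return self


@dataclass(frozen=True)
class BinomialInterval:
    """Two-sided confidence bounds for a proportion.

    Invariants: ``0 <= lower <= upper <= 1`` and the interval contains the
    point estimate it was computed from.
    """

    lower: float
    upper: float
    confidence: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValidationError(
                f"bounds must satisfy 0 <= lower <= upper <= 1, "
                f"got [{self.lower}, {self.upper}]"
            )
        if not 0.0 < self.confidence < 1.0:
            raise ValidationError(
                f"confidence must be in (0, 1), got {self.confidence}"
            )

    def contains(self, p: float) -> bool:
        return self.lower <= p <= self.upper

    def as_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "confidence": self.confidence,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# Wilson score intervals (vectorised kernels + scalar public API)
# ---------------------------------------------------------------------------

def _wilson_cc_bounds(p, n, z):
    """Continuity-corrected Wilson score bounds, vectorised over p.

    Newcombe's closed form.  The correction shifts the score equation by
    1/(2n); when p-hat is within 1/(2n) of 0 (resp. 1) that equation has no
    valid root and the bound is pinned to 0 (resp. 1) — the same convention
    base R's prop.test uses.  The radicand is clamped at zero before the
    square root and bounds are clamped to [0, 1] and to contain p-hat.
    """
    p = np.asarray(p, dtype=float)
    n = float(n)
    q = 1.0 - p
    z2 = z * z
    denom = 2.0 * (n + z2)

    rad_l = np.maximum(z2 - 2.0 - 1.0 / n + 4.0 * p * (n * q + 1.0), 0.0)
    lower = (2.0 * n * p + z2 - 1.0 - z * np.sqrt(rad_l)) / denom
    lower = np.where(n * p <= 0.5, 0.0, lower)

    rad_u = np.maximum(z2 + 2.0 - 1.0 / n + 4.0 * p * (n * q - 1.0), 0.0)
    upper = (2.0 * n * p + z2 + 1.0 + z * np.sqrt(rad_u)) / denom
    upper = np.where(n * q <= 0.5, 1.0, upper)

    lower = np.clip(lower, 0.0, p)
    upper = np.clip(upper, p, 1.0)
    return lower, upper


def _wilson_bounds(p, n, z):
    """Plain Wilson score bounds (no continuity correction), vectorised."""
    p = np.asarray(p, dtype=float)
    n = float(n)
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = p + z2 / (2.0 * n)
    radius = z * np.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n))
    lower = np.clip((centre - radius) / denom, 0.0, p)
    upper = np.clip((centre + radius) / denom, p, 1.0)
    return lower, upper


def wilson_cc_interval(
    estimate: ProportionEstimate,
    confidence: float = 0.95,
    z: float | None = None,
) -> BinomialInterval:
    """Wilson score interval with continuity correction for a proportion.

    Parameters
    ----------
    estimate
        Observed events over volume; the numerator may be continuous.
    confidence
        Two-sided confidence level, in (0, 1).
    z
        Optional override of the normal quantile (e.g. the rounded 1.96).

    Returns
    -------
    BinomialInterval with ``method="wilson_cc"``.  Conventions: lower bound is
    exactly 0 when p-hat = 0 (and whenever n*p-hat <= 1/2, where the corrected
    score equation has no root); upper bound is exactly 1 symmetrically.
    """
    zval = z_from_confidence(confidence, z)
    lower, upper = _wilson_cc_bounds(estimate.value, estimate.denominator, zval)
    return BinomialInterval(float(lower), float(upper), confidence, "wilson_cc")


def wilson_interval(
    estimate: ProportionEstimate,
    confidence: float = 0.95,
    z: float | None = None,
) -> BinomialInterval:
    """Plain Wilson score interval; always contained in the corrected one."""
    zval = z_from_confidence(confidence, z)
    lower, upper = _wilson_bounds(estimate.value, estimate.denominator, zval)
    return BinomialInterval(float(lower), float(upper), confidence, "wilson")


# ---------------------------------------------------------------------------
# Poisson score intervals on the event rate
# ---------------------------------------------------------------------------

def _poisson_score_bounds(k, n, z, corrected):
    """Score interval for a Poisson mean lambda = n*p, returned on the p scale.

    Solves |k - lambda| (minus 0.5 when corrected) = z*sqrt(lambda) for
    lambda; the 0.5-count shift is the continuity correction for integer
    event counts.
    """
    k = np.asarray(k, dtype=float)
    n = float(n)
    z2 = z * z
    c = 0.5 if corrected else 0.0
    kl = np.maximum(k - c, 0.0)
    ku = k + c
    lam_lower = ((-z + np.sqrt(z2 + 4.0 * kl)) / 2.0) ** 2
    lam_upper = ((z + np.sqrt(z2 + 4.0 * ku)) / 2.0) ** 2
    lower = np.where(k - c <= 0.0, 0.0, lam_lower / n)
    upper = lam_upper / n
    return np.clip(lower, 0.0, 1.0), np.clip(upper, 0.0, 1.0)


def poisson_interval(
    estimate: ProportionEstimate,
    confidence: float = 0.95,
    corrected: bool = True,
    z: float | None = None,
) -> BinomialInterval:
    """Poisson score interval for a rare-event rate, on the proportion scale.

    Intended for rates like cancer detection where events are rare enough
    that the Poisson approximation to the binomial count is excellent.
    """
    zval = z_from_confidence(confidence, z)
    lower, upper = _poisson_score_bounds(
        estimate.numerator, estimate.denominator, zval, corrected
    )
    method = "poisson_cc" if corrected else "poisson"
    lo = float(np.minimum(lower, estimate.value))
    hi = float(np.maximum(upper, estimate.value))
    return BinomialInterval(lo, hi, confidence, method)


_METHODS = {
    "wilson_cc": lambda est, conf, z: wilson_cc_interval(est, conf, z),
    "wilson": lambda est, conf, z: wilson_interval(est, conf, z),
    "poisson_cc": lambda est, conf, z: poisson_interval(est, conf, True, z),
    "poisson": lambda est, conf, z: poisson_interval(est, conf, False, z),
}


def interval_by_method(
    estimate: ProportionEstimate,
    confidence: float = 0.95,
    method: str = "wilson_cc",
    z: float | None = None,
) -> BinomialInterval:
    """Dispatch on the method tag (wilson_cc | wilson | poisson_cc | poisson)."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValidationError(
            f"unknown interval method {method!r}; expected one of {sorted(_METHODS)}"
        ) from None
    return fn(estimate, confidence, z)
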