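"""Seeded generator of synthetic screening-exam streams with known truth.

Each examination is an independent draw from a Bernoulli mixture: a cancer is
present with probability ``cancer_prevalence``; a present cancer is detected
(positive assessment, cancer within 12 months) with probability
``sensitivity``, otherwise it surfaces as an interval cancer after a negative
screen.  Cancer-free exams are recalled as false positives at whatever rate
tops the recall rate up to ``true_recall_rate``.  The implied ground truths
are therefore

    CDR = cancer_prevalence * sensitivity        (true positives per exam)
    RR  = true_recall_rate                       (all positives per exam)

The defaults emulate a small US academic practice: 4 physicians reading 1918
screening exams per year for 3 years, recall rate 9.7% and detection rate
4.4 per 1000 (prevalence 5/1000, sensitivity 0.88) — the reference-median
performer.  The generator knows nothing about case mix, reader correlation,
or drift; it exists so counting, classification, and trajectory behaviour can
be tested against known parameters.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import ValidationError

__all__ = [
    "PhysicianProfile",
    "SimulationConfig",
    "simulate_exams",
    "default_config",
    "config_from_yaml",
    "write_exam_csv",
]

# Assessment draws within the positive {0,4,5} and negative {1,2,3} sets are
# cosmetic (they exercise parsing, not statistics) but kept configurable.
POSITIVE_WEIGHTS = (0.80, 0.15, 0.05)  # BI-RADS 0, 4, 5
NEGATIVE_WEIGHTS = (0.50, 0.45, 0.05)  # BI-RADS 1, 2, 3


@dataclass(frozen=True)
class PhysicianProfile:
    """Ground-truth operating point for one simulated reader."""

    physician_id: str
    true_recall_rate: float = 0.097
    cancer_prevalence: float = 0.005
    sensitivity: float = 0.88

    def __post_init__(self) -> None:
        for name in ("true_recall_rate", "cancer_prevalence", "sensitivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.true_cdr > self.true_recall_rate:
            raise ValidationError(
                f"implied CDR {self.true_cdr} exceeds recall rate "
                f"{self.true_recall_rate}"
            )
        if self.false_positive_rate > 1.0:
            raise ValidationError(
                "implied false-positive recall probability exceeds 1"
            )

    @property
    def true_cdr(self) -> float:
        return self.cancer_prevalence * self.sensitivity

    @property
    def false_positive_rate(self) -> float:
        """P(recall | no cancer), chosen so the overall recall rate is met."""
        if self.cancer_prevalence >= 1.0:
            return 0.0
        return (self.true_recall_rate - self.true_cdr) / (1.0 - self.cancer_prevalence)


@dataclass(frozen=True)
class SimulationConfig:
    physicians: tuple[PhysicianProfile, ...]
    exams_per_year: int = 1918
    years: int = 3
    start_date: dt.date = dt.date(2006, 1, 1)
    seed: int = 0
    positive_weights: tuple[float, float, float] = POSITIVE_WEIGHTS
    negative_weights: tuple[float, float, float] = NEGATIVE_WEIGHTS

    def __post_init__(self) -> None:
        if self.exams_per_year < 1 or self.years < 1:
            raise ValidationError("exams_per_year and years must be >= 1")
        for name in ("positive_weights", "negative_weights"):
            w = getattr(self, name)
            if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9 or min(w) < 0:
                raise ValidationError(f"{name} must be 3 non-negative weights summing to 1")


def default_config(seed: int = 0, n_physicians: int = 4) -> SimulationConfig:
    """The reference-median practice: median RR/CDR readers, 1918 exams/year."""
    physicians = tuple(
        PhysicianProfile(physician_id=f"MD{i + 1}") for i in range(n_physicians)
    )
    return SimulationConfig(physicians=physicians, seed=seed)


def config_from_yaml(path) -> SimulationConfig:
    """Load a SimulationConfig from YAML (see README for the schema)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    physicians = tuple(
        PhysicianProfile(
            physician_id=str(p["physician_id"]),
            true_recall_rate=float(p.get("true_recall_rate", 0.097)),
            cancer_prevalence=float(p.get("cancer_prevalence", 0.005)),
            sensitivity=float(p.get("sensitivity", 0.88)),
        )
        for p in raw["physicians"]
    )
    kwargs = {}
    if "start_date" in raw:
        kwargs["start_date"] = dt.date.fromisoformat(str(raw["start_date"]))
    for key in ("exams_per_year", "years", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    return SimulationConfig(physicians=physicians, **kwargs)


def simulate_exams(config: SimulationConfig) -> pd.DataFrame:
    """Draw a full exam stream; byte-identical output for identical configs.

    Returns the audit module's exam schema: exam_id, physician_id, exam_date,
    assessment, cancer_within_12mo, cancer_date.  Exam dates are uniform over
    the simulated period; detected and interval cancers get a cancer_date
    uniform within the 12-month window so every row satisfies the record
    consistency invariant.
    """
    rng = np.random.default_rng(config.seed)
    n_per = config.exams_per_year * config.years
    span_days = 365 * config.years
    start = np.datetime64(config.start_date, "D")
    pos_cats = np.array([0, 4, 5])
    neg_cats = np.array([1, 2, 3])

    frames = []
    for prof in config.physicians:
        cancer = rng.random(n_per) < prof.cancer_prevalence
        detected = cancer & (rng.random(n_per) < prof.sensitivity)
        false_pos = ~cancer & (rng.random(n_per) < prof.false_positive_rate)
        positive = detected | false_pos

        assessment = np.where(
            positive,
            rng.choice(pos_cats, size=n_per, p=config.positive_weights),
            rng.choice(neg_cats, size=n_per, p=config.negative_weights),
        )
        offsets = rng.integers(0, span_days, size=n_per)
        exam_date = start + offsets
        order = np.lexsort((np.arange(n_per), offsets))

        lag = rng.integers(0, 366, size=n_per)
        cancer_date = np.where(cancer, exam_date + lag, np.datetime64("NaT"))

        frame = pd.DataFrame(
            {
                "exam_id": [
                    f"{prof.physician_id}-{i:06d}" for i in range(n_per)
                ],
                "physician_id": prof.physician_id,
                "exam_date": pd.DatetimeIndex(exam_date),
                "assessment": assessment.astype("int64"),
                "cancer_within_12mo": cancer,
                "cancer_date": pd.DatetimeIndex(cancer_date),
            }
        ).iloc[order]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_exam_csv(frame: pd.DataFrame, path) -> None:
    """Emit the audit CSV schema (ISO dates, 0/1 booleans), deterministically."""
    out = frame.copy()
    out["exam_date"] = pd.DatetimeIndex(out["exam_date"]).strftime("%Y-%m-%d")
    cd = pd.DatetimeIndex(out["cancer_date"])
    out["cancer_date"] = np.where(cd.isna(), "", cd.strftime("%Y-%m-%d"))
    out["cancer_within_12mo"] = out["cancer_within_12mo"].astype(int)
    out.to_csv(path, index=False)
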