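"""Per-examination audit pipeline for screening-mammography performance.

Takes a CSV of individual screening examinations (physician, date, BI-RADS
assessment, cancer-within-12-months outcome), applies the standard outcome
definitions, and produces per-physician cancer detection rates and recall
rates — annually, aggregated across years, and cumulatively along the exam
stream — each classified against the volume-aware benchmarks.

Outcome definitions: a *positive* screen (recall) is an exam with an initial
BI-RADS assessment of 0, 4, or 5; a *detected cancer* (true positive) is a
positive screen followed by a diagnosis of invasive carcinoma or DCIS within
12 months of the exam.  A cancer after a negative screen is an interval
cancer and never counts as a detection.  The in-memory container for exam
streams is a pandas DataFrame with one row per examination.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import pandas as pd

from .classification import (
    Benchmark,
    PerformanceClassification,
    classify_performance,
    default_benchmarks,
)
from .intervals import ProportionEstimate, ValidationError

__all__ = [
    "ExamRecord",
    "LoadResult",
    "PhysicianPeriodSummary",
    "POSITIVE_ASSESSMENTS",
    "CANCER_WINDOW_DAYS",
    "load_exams",
    "records_to_frame",
    "is_positive",
    "is_detected_cancer",
    "positive_mask",
    "detected_mask",
    "summarize",
    "summarize_all",
    "eligible_physicians",
    "trajectory",
    "DEFAULT_CHECKPOINTS",
    "TRAJECTORY_CAP",
]

POSITIVE_ASSESSMENTS = frozenset({0, 4, 5})
CANCER_WINDOW_DAYS = 365  # "within 12 months", fixed-day convention
DEFAULT_CHECKPOINTS = (500, 1000, 2000, 3000, 4000, 5000)
TRAJECTORY_CAP = 5000

REQUIRED_COLUMNS = (
    "exam_id",
    "physician_id",
    "exam_date",
    "assessment",
    "cancer_within_12mo",
)

_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no"}


@dataclass(frozen=True)
class ExamRecord:
    """One screening examination."""

    exam_id: str
    physician_id: str
    exam_date: dt.date
    assessment: int
    cancer_within_12mo: bool
    cancer_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.assessment not in range(6):
            raise ValidationError(
                f"assessment must be a BI-RADS category 0-5, got {self.assessment}"
            )
        if self.cancer_date is not None:
            delta = (self.cancer_date - self.exam_date).days
            in_window = 0 <= delta <= CANCER_WINDOW_DAYS
            if in_window != self.cancer_within_12mo:
                raise ValidationError(
                    f"cancer_within_12mo={self.cancer_within_12mo} inconsistent "
                    f"with cancer_date {self.cancer_date} ({delta} days after exam)"
                )


@dataclass(frozen=True)
class LoadResult:
    """Validated exam stream plus a row-level rejection log."""

    frame: pd.DataFrame
    n_loaded: int
    n_rejected: int
    rejections: tuple[str, ...] = ()


def is_positive(record: ExamRecord) -> bool:
    """A recall: initial BI-RADS assessment 0, 4, or 5."""
    return record.assessment in POSITIVE_ASSESSMENTS


def is_detected_cancer(record: ExamRecord) -> bool:
    """A true positive: positive screen with cancer within 12 months."""
    return is_positive(record) and record.cancer_within_12mo


def positive_mask(frame: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`is_positive` over an exam frame."""
    return frame["assessment"].isin(POSITIVE_ASSESSMENTS)


def detected_mask(frame: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`is_detected_cancer` over an exam frame."""
    return positive_mask(frame) & frame["cancer_within_12mo"]


def records_to_frame(records) -> pd.DataFrame:
    """Build the canonical exam DataFrame from ExamRecord objects."""
    return pd.DataFrame(
        {
            "exam_id": [r.exam_id for r in records],
            "physician_id": [r.physician_id for r in records],
            "exam_date": pd.to_datetime([r.exam_date for r in records]),
            "assessment": pd.array([r.assessment for r in records], dtype="int64"),
            "cancer_within_12mo": [r.cancer_within_12mo for r in records],
            "cancer_date": pd.to_datetime([r.cancer_date for r in records]),
        }
    )


def _parse_bool(raw) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def load_exams(path) -> LoadResult:
    """Read and validate an exam CSV.

    Required columns: exam_id, physician_id, exam_date (ISO 8601),
    assessment (BI-RADS 0-5), cancer_within_12mo (0/1/true/false); optional
    cancer_date.  A missing required column is a hard error; a malformed row
    (bad date, assessment outside 0-5, inconsistent cancer_date) is rejected
    with a row-numbered message and the rest of the file is kept.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"exam CSV is missing required columns: {missing}")
    has_cancer_date = "cancer_date" in raw.columns

    rows = []
    rejections: list[str] = []
    for idx, row in enumerate(raw.itertuples(index=False), start=2):  # 1 = header
        try:
            exam_date = dt.date.fromisoformat(str(row.exam_date).strip())
            assessment = int(str(row.assessment).strip())
            cancer = _parse_bool(row.cancer_within_12mo)
            cancer_date = None
            if has_cancer_date:
                cd_raw = str(row.cancer_date).strip()
                if cd_raw:
                    cancer_date = dt.date.fromisoformat(cd_raw)
            record = ExamRecord(
                exam_id=str(row.exam_id),
                physician_id=str(row.physician_id),
                exam_date=exam_date,
                assessment=assessment,
                cancer_within_12mo=cancer,
                cancer_date=cancer_date,
            )
        except (ValueError, ValidationError) as exc:
            rejections.append(f"row {idx}: {exc}")
            continue
        rows.append(record)

    frame = records_to_frame(rows)
    return LoadResult(
        frame=frame,
        n_loaded=len(rows),
        n_rejected=len(rejections),
        rejections=tuple(rejections),
    )


@dataclass(frozen=True)
class PhysicianPeriodSummary:
    """Counts, rates, and classifications for one physician and period.

    ``period`` is a calendar-year label ("2006") or "aggregate".  Invariants:
    detected_cancers <= recalls <= volume, hence cdr <= rr.
    """

    physician_id: str
    period: str
    volume: int
    recalls: int
    detected_cancers: int
    cdr: ProportionEstimate
    rr: ProportionEstimate
    cdr_class: PerformanceClassification | None = None
    rr_class: PerformanceClassification | None = None

    def __post_init__(self) -> None:
        if not self.detected_cancers <= self.recalls <= self.volume:
            raise ValidationError(
                f"counts must satisfy detected <= recalls <= volume, got "
                f"{self.detected_cancers} / {self.recalls} / {self.volume}"
            )

    def as_dict(self) -> dict:
        out = {
            "physician_id": self.physician_id,
            "period": self.period,
            "volume": self.volume,
            "recalls": self.recalls,
            "detected_cancers": self.detected_cancers,
            "cdr": self.cdr.value,
            "rr": self.rr.value,
        }
        for name, cls in (("cdr", self.cdr_class), ("rr", self.rr_class)):
            if cls is not None:
                out[f"{name}_category"] = cls.category.value
                out[f"{name}_lower"] = cls.interval.lower
                out[f"{name}_upper"] = cls.interval.upper
        return out


def _summary_from_frame(
    frame: pd.DataFrame,
    physician_id: str,
    period: str,
    benchmarks: dict[str, Benchmark] | None,
) -> PhysicianPeriodSummary:
    volume = len(frame)
    if volume == 0:
        raise ValidationError(
            f"empty period: physician {physician_id!r} has no exams in {period!r}"
        )
    recalls = int(positive_mask(frame).sum())
    detected = int(detected_mask(frame).sum())
    cdr = ProportionEstimate(detected, volume)
    rr = ProportionEstimate(recalls, volume)
    cdr_class = rr_class = None
    if benchmarks is not None:
        if "CDR" in benchmarks:
            cdr_class = classify_performance(cdr, benchmarks["CDR"])
        if "RR" in benchmarks:
            rr_class = classify_performance(rr, benchmarks["RR"])
    return PhysicianPeriodSummary(
        physician_id=physician_id,
        period=period,
        volume=volume,
        recalls=recalls,
        detected_cancers=detected,
        cdr=cdr,
        rr=rr,
        cdr_class=cdr_class,
        rr_class=rr_class,
    )


def summarize(
    frame: pd.DataFrame,
    physician_id: str,
    period: str | int = "aggregate",
    benchmarks: dict[str, Benchmark] | None = None,
) -> PhysicianPeriodSummary:
    """CDR / RR summary for one physician over one period.

    ``period`` is a calendar year (exam membership decided by the exam date)
    or "aggregate" for all of the physician's exams.  Benchmarks default to
    the shipped BCSC set; pass ``benchmarks={}`` to skip classification.
    """
    if benchmarks is None:
        benchmarks = default_benchmarks()
    sub = frame[frame["physician_id"] == physician_id]
    if str(period) != "aggregate":
        year = int(period)
        sub = sub[pd.DatetimeIndex(sub["exam_date"]).year == year]
    return _summary_from_frame(sub, physician_id, str(period), benchmarks or None)


def summarize_all(
    frame: pd.DataFrame,
    benchmarks: dict[str, Benchmark] | None = None,
) -> list[PhysicianPeriodSummary]:
    """One summary per physician per calendar year, plus the aggregate."""
    if benchmarks is None:
        benchmarks = default_benchmarks()
    out: list[PhysicianPeriodSummary] = []
    years = sorted(pd.DatetimeIndex(frame["exam_date"]).year.unique())
    for pid in sorted(frame["physician_id"].unique()):
        for year in years:
            sub = frame[
                (frame["physician_id"] == pid)
                & (pd.DatetimeIndex(frame["exam_date"]).year == year)
            ]
            if len(sub):
                out.append(_summary_from_frame(sub, pid, str(year), benchmarks))
        out.append(summarize(frame, pid, "aggregate", benchmarks))
    return out


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tidy frame (one row per physician x period) for CSV output."""
    return pd.DataFrame([s.as_dict() for s in summaries])


def eligible_physicians(
    frame: pd.DataFrame,
    min_annual_volume: int = 480,
    years=None,
) -> list[str]:
    """Physicians reading strictly more than the volume floor in every year.

    Mirrors the MQSA-style inclusion rule (>480 mammograms per year, each
    year of the audit window).  ``years`` must list the calendar years to
    check; an empty list is a validation error because "every year of
    nothing" is vacuously true and almost certainly a caller bug.
    """
    if years is None or len(list(years)) == 0:
        raise ValidationError("years must be a non-empty list of calendar years")
    years = [int(y) for y in years]
    year_of = pd.DatetimeIndex(frame["exam_date"]).year
    counts = (
        pd.DataFrame({"physician_id": frame["physician_id"], "year": year_of})
        .groupby(["physician_id", "year"])
        .size()
    )
    keep = []
    for pid in sorted(frame["physician_id"].unique()):
        if all(counts.get((pid, y), 0) > min_annual_volume for y in years):
            keep.append(pid)
    return keep


def trajectory(
    frame: pd.DataFrame,
    physician_id: str,
    benchmarks: dict[str, Benchmark] | None = None,
    checkpoints=DEFAULT_CHECKPOINTS,
    cap: int = TRAJECTORY_CAP,
) -> list[PhysicianPeriodSummary]:
    """Cumulative summaries along a physician's exam stream.

    Exams are ordered by exam_date (ties broken by exam_id, lexicographic —
    a deterministic order, not file order) and summarised at each cumulative
    checkpoint up to min(total volume, cap); if the total itself falls below
    the cap it is appended as a final point, so the last entry always equals
    the full-stream summary.  A physician with fewer exams than the first
    checkpoint yields an empty trajectory with a warning.
    """
    if benchmarks is None:
        benchmarks = default_benchmarks()
    sub = (
        frame[frame["physician_id"] == physician_id]
        .sort_values(["exam_date", "exam_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    total = len(sub)
    limit = min(total, cap)
    points = [c for c in sorted(checkpoints) if c <= limit]
    if points and limit not in points:
        points.append(limit)
    if not points:
        warnings.warn(
            f"physician {physician_id!r} has only {total} exams, fewer than the "
            f"first checkpoint {min(checkpoints)}; empty trajectory",
            stacklevel=2,
        )
        return []
    out = []
    for point in points:
        out.append(
            _summary_from_frame(
                sub.iloc[:point], physician_id, f"cumulative:{point}", benchmarks
            )
        )
    return out
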