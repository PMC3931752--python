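import datetime as dt

import pandas as pd
import pytest

from screenperf.audit import ExamRecord, records_to_frame
from screenperf.classification import CDR_BENCHMARK, RR_BENCHMARK


@pytest.fixture
def cdr_benchmark():
    return CDR_BENCHMARK


@pytest.fixture
def rr_benchmark():
    return RR_BENCHMARK


@pytest.fixture
def hand_count_frame() -> pd.DataFrame:
    """Ten exams for one reader: 3 recalls (BI-RADS 0, 4, 5), one detected
    cancer on the BI-RADS-4 exam -> volume 10, recalls 3, detected 1."""
    assessments = [1, 2, 0, 4, 1, 1, 1, 5, 1, 1]
    records = [
        ExamRecord(
            exam_id=f"E{i:03d}",
            physician_id="MD1",
            exam_date=dt.date(2006, 1, 1) + dt.timedelta(days=i),
            assessment=a,
            cancer_within_12mo=(a == 4),
        )
        for i, a in enumerate(assessments)
    ]
    return records_to_frame(records)


def write_exam_rows(path, rows, header=None):
    """Write a small exam CSV from raw string rows (for loader edge cases)."""
    if header is None:
        header = "exam_id,physician_id,exam_date,assessment,cancer_within_12mo,cancer_date"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path
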