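"""Temporal early-detection analysis of longitudinal CXR series.

For each patient with a dated series of pre-diagnosis chest radiographs and
per-source detection flags (radiology reader, AI model), the quantity of
interest is the *time from detection to diagnosis*: days between the
earliest flagged radiograph and the diagnosis date — larger means earlier
detection. "AI-assisted reading" is simulated as the per-record set union
(OR) of the two sources, so its detection time is the elementwise maximum.
Patients never flagged before diagnosis contribute 0 days.

Group comparisons use the Wilcoxon signed-rank test on the paired
per-patient times; cohort summaries use median and interquartile range; the
per-patient benefit of AI assistance (combined minus reader days) is
exported in waterfall order.
"""

from __future__ import annotations

import datetime as dt
import itertools
import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CxrRecord",
    "PatientTimeline",
    "EarlyDetectionResult",
    "OverlapCounts",
    "earliest_detection_days",
    "analyze_timeline",
    "overlap_counts",
    "median_iqr",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "waterfall_benefit",
    "read_timelines",
    "write_timelines",
]

_SOURCES = ("reader", "ai", "combined")


@dataclass(frozen=True)
class CxrRecord:
    """One dated radiograph with per-source detection flags."""

    date: dt.date
    detected_by_reader: bool
    detected_by_ai: bool


@dataclass(frozen=True)
class PatientTimeline:
    """A patient's pre-diagnosis CXR series, sorted ascending by date."""

    patient_id: str
    diagnosis_date: dt.date
    records: tuple[CxrRecord, ...]

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        if not recs:
            raise ValueError(f"patient {self.patient_id!r}: empty timeline")
        if any(b.date < a.date for a, b in zip(recs, recs[1:])):
            raise ValueError(f"patient {self.patient_id!r}: records not sorted by date")
        if any(r.date > self.diagnosis_date for r in recs):
            raise ValueError(
                f"patient {self.patient_id!r}: record after diagnosis date"
            )
        object.__setattr__(self, "records", recs)


@dataclass(frozen=True)
class EarlyDetectionResult:
    """Per-patient days from earliest detection to diagnosis, per source.

    0 encodes "not detected early". ``days_combined`` is always the
    elementwise maximum of the two sources, because the union flags a record
    whenever either source does.
    """

    patient_id: str
    days_reader: int
    days_ai: int
    days_combined: int

    def __post_init__(self) -> None:
        if min(self.days_reader, self.days_ai, self.days_combined) < 0:
            raise ValueError("detection-to-diagnosis days must be non-negative")
        if self.days_combined != max(self.days_reader, self.days_ai):
            raise ValueError("days_combined must equal max(days_reader, days_ai)")


@dataclass(frozen=True)
class OverlapCounts:
    """Patient counts by which source(s) detected the nodule early."""

    n_total: int
    n_ai: int
    n_reader: int
    n_both: int

    @property
    def n_ai_only(self) -> int:
        return self.n_ai - self.n_both

    @property
    def n_reader_only(self) -> int:
        return self.n_reader - self.n_both

    @property
    def n_neither(self) -> int:
        return self.n_total - self.n_both - self.n_ai_only - self.n_reader_only

    def __post_init__(self) -> None:
        if min(self.n_ai_only, self.n_reader_only, self.n_neither, self.n_both) < 0:
            raise ValueError("inconsistent overlap counts")


def _flagged(rec: CxrRecord, source: str) -> bool:
    if source == "reader":
        return rec.detected_by_reader
    if source == "ai":
        return rec.detected_by_ai
    if source == "combined":
        return rec.detected_by_reader or rec.detected_by_ai
    raise ValueError(f"unknown source {source!r}; expected one of {_SOURCES}")


def earliest_detection_days(tl: PatientTimeline, source: str) -> int:
    """Days from the earliest radiograph flagged by ``source`` to diagnosis.

    The combined source flags a record when either the reader or the AI
    does. Returns 0 when no record is flagged ("not detected early").
    """
    for rec in tl.records:  # records sorted ascending, first flag is earliest
        if _flagged(rec, source):
            return (tl.diagnosis_date - rec.date).days
    return 0


def analyze_timeline(tl: PatientTimeline) -> EarlyDetectionResult:
    """Detection-to-diagnosis days for reader, AI and their union."""
    return EarlyDetectionResult(
        patient_id=tl.patient_id,
        days_reader=earliest_detection_days(tl, "reader"),
        days_ai=earliest_detection_days(tl, "ai"),
        days_combined=earliest_detection_days(tl, "combined"),
    )


def overlap_counts(results: Iterable[EarlyDetectionResult]) -> OverlapCounts:
    """Count patients detected early by AI, reader, both, either-only, neither.

    A patient counts as detected by a source when its detection-to-diagnosis
    days are strictly positive.
    """
    rs = list(results)
    n_ai = sum(r.days_ai > 0 for r in rs)
    n_reader = sum(r.days_reader > 0 for r in rs)
    n_both = sum(r.days_ai > 0 and r.days_reader > 0 for r in rs)
    return OverlapCounts(n_total=len(rs), n_ai=n_ai, n_reader=n_reader, n_both=n_both)


def median_iqr(days: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation of order statistics."""
    arr = np.asarray(days, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("median undefined for empty list")
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min(positive-rank sum, negative-rank sum)
    p_value: float
    n_effective: int
    exact: bool
    all_zero: bool = False


def _signed_rank_w(diffs: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Positive/negative rank sums and the midrank vector of |d|."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))  # midranks for ties
    w_pos = float(ranks[diffs > 0].sum())
    w_neg = float(ranks[diffs < 0].sum())
    return w_pos, w_neg, ranks


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    exact_threshold: int = 15,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences ``a - b`` equal to zero are dropped (the classical Wilcoxon
    convention); absolute differences are ranked with midranks for ties; the
    statistic is ``W = min(W+, W-)``. The p-value is exact — full
    enumeration of the 2^n equiprobable sign assignments of the rank
    vector — when the effective sample size is at most ``exact_threshold``;
    above that a normal approximation with tie correction and a 0.5
    continuity correction is used. When every difference is zero the test
    degenerates: W = 0, p = 1, flagged via ``all_zero``.
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("paired samples must be equal-length 1-D, length >= 1")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0,
                              exact=True, all_zero=True)

    w_pos, w_neg, ranks = _signed_rank_w(d)
    w = min(w_pos, w_neg)

    if n <= exact_threshold:
        # exact null: every sign vector equally likely; two-sided p counts
        # assignments at least as extreme on either tail of W+
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        sums = signs @ ranks  # W+ for every assignment
        lo, hi = min(w_pos, w_neg), max(w_pos, w_neg)
        tol = 1e-9
        p = (np.count_nonzero(sums <= lo + tol) + np.count_nonzero(sums >= hi - tol)) / 2.0**n
        return WilcoxonResult(statistic=w, p_value=min(1.0, p), n_effective=n, exact=True)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(statistic=w, p_value=1.0, n_effective=n, exact=False)
    z = (w - mean + 0.5) / math.sqrt(var)  # continuity correction toward the mean
    from scipy.stats import norm

    p = min(1.0, 2.0 * norm.cdf(z))
    return WilcoxonResult(statistic=w, p_value=p, n_effective=n, exact=False)


def waterfall_benefit(
    results: Iterable[EarlyDetectionResult],
) -> tuple[list[tuple[str, int]], int]:
    """Per-patient benefit of AI assistance, in waterfall (descending) order.

    Benefit = combined days - reader days: the extra days of early detection
    the union with the AI adds over the reader alone. Returns the sorted
    list and the count of strictly positive benefits.
    """
    entries = [(r.patient_id, r.days_combined - r.days_reader) for r in results]
    entries.sort(key=lambda e: (-e[1], e[0]))
    n_positive = sum(1 for _, b in entries if b > 0)
    return entries, n_positive


_TL_COLUMNS = ["patient_id", "cxr_date", "diagnosis_date", "detected_by_reader", "detected_by_ai"]


def read_timelines(path: str | os.PathLike) -> list[PatientTimeline]:
    """Read patient timelines from CSV (ISO dates, 0/1 flags)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(_TL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"timeline CSV missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        diag = set(grp["diagnosis_date"])
        if len(diag) != 1:
            raise ValueError(f"patient {pid!r}: inconsistent diagnosis dates")
        grp = grp.sort_values("cxr_date")
        recs = tuple(
            CxrRecord(
                date=dt.date.fromisoformat(str(r.cxr_date)),
                detected_by_reader=bool(int(r.detected_by_reader)),
                detected_by_ai=bool(int(r.detected_by_ai)),
            )
            for r in grp.itertuples(index=False)
        )
        out.append(
            PatientTimeline(
                patient_id=str(pid),
                diagnosis_date=dt.date.fromisoformat(str(diag.pop())),
                records=recs,
            )
        )
    return out


def write_timelines(timelines: Iterable[PatientTimeline], path: str | os.PathLike) -> None:
    """Write patient timelines to CSV (ISO dates, 0/1 flags)."""
    rows = [
        {
            "patient_id": tl.patient_id,
            "cxr_date": r.date.isoformat(),
            "diagnosis_date": tl.diagnosis_date.isoformat(),
            "detected_by_reader": int(r.detected_by_reader),
            "detected_by_ai": int(r.detected_by_ai),
        }
        for tl in timelines
        for r in tl.records
    ]
    pd.DataFrame(rows, columns=_TL_COLUMNS).to_csv(path, index=False)
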