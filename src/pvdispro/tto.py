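"""Time-to-onset (TTO) computation and summaries.

TTO is the whole-day interval from the drug start date (START_DT) to the
event onset date (EVENT_DT). Records are excluded, in this order of
precedence, when a date is missing, when the event precedes the drug start,
when a date string is implausible or non-parsable, or when the interval is
extreme enough to suggest a data-entry error (default cut: 3,650 days).
Valid intervals are summarised by median and interquartile range and binned
into 0-7 / 7-28 / 28-60 / >=60 days, with the shared endpoints resolved as
[0,7], (7,28], (28,60], (60, inf) — same-day onset falls in the first bin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cleaning import Cohort, Report
from .faers_io import DatePrecision, DrugLexicon, RawDate, RoleCode

DEFAULT_MAX_DAYS = 3650

# (label, low, high]; first bin closed at 0
DEFAULT_BINS: tuple[tuple[str, float, float], ...] = (
    ("0-7", 0.0, 7.0),
    ("7-28", 7.0, 28.0),
    ("28-60", 28.0, 60.0),
    (">=60", 60.0, float("inf")),
)


class TTOStatus(enum.Enum):
    VALID = "valid"
    MISSING_DATE = "missing_date"
    NEGATIVE_INTERVAL = "negative_interval"
    INVALID_DATE = "invalid_date"
    EXTREME_INTERVAL = "extreme_interval"


@dataclass(frozen=True)
class TTORecord:
    primaryid: str
    start: RawDate
    event: RawDate
    status: TTOStatus
    days: Optional[int] = None


def compute_tto(
    start: RawDate,
    event: RawDate,
    max_days: int = DEFAULT_MAX_DAYS,
    primaryid: str = "",
) -> TTORecord:
    """Classify one (start, event) date pair and compute days when valid.

    Exclusion precedence: missing date, then event-before-start, then
    invalid/partial date, then extreme interval. Partial (month/year) dates
    count as non-parsable to day resolution, hence invalid_date.
    """
    def rec(status: TTOStatus, days: Optional[int] = None) -> TTORecord:
        return TTORecord(primaryid=primaryid, start=start, event=event,
                         status=status, days=days)

    if start.is_missing or event.is_missing:
        return rec(TTOStatus.MISSING_DATE)
    if start.is_day and event.is_day:
        days = (event.value - start.value).days
        if days < 0:
            return rec(TTOStatus.NEGATIVE_INTERVAL)
        if days > max_days:
            return rec(TTOStatus.EXTREME_INTERVAL)
        return rec(TTOStatus.VALID, days=days)
    return rec(TTOStatus.INVALID_DATE)


def cohort_tto_records(
    reports: Sequence[Report],
    cohort: Cohort,
    lexicon: Optional[DrugLexicon] = None,
    max_days: int = DEFAULT_MAX_DAYS,
) -> list[TTORecord]:
    """One TTO record per cohort report.

    The start date is the earliest day-precision START_DT among the report's
    matching PS drug rows (all PS rows when no lexicon is given); if none of
    them has a full date, the first row's date is used so the record carries
    the right exclusion status.
    """
    out = []
    for report in reports:
        if report.primaryid not in cohort.report_ids:
            continue
        rows = [
            d for d in report.drugs
            if d.role_code is RoleCode.PS
            and (lexicon is None or lexicon.matches(d.drug_name, d.active_ingredient))
        ]
        if not rows:
            continue
        dated = [d for d in rows if d.start_dt.is_day]
        start = (
            min(dated, key=lambda d: d.start_dt.value).start_dt
            if dated
            else rows[0].start_dt
        )
        out.append(compute_tto(start, report.event_dt, max_days, report.primaryid))
    return out


@dataclass
class TTOSummary:
    n_valid: int
    n_unknown: int
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    bin_counts: dict[str, int] = None  # type: ignore[assignment]
    bin_shares: dict[str, float] = None  # type: ignore[assignment]


def summarize_tto(
    records: Sequence[TTORecord],
    bins: Sequence[tuple[str, float, float]] = DEFAULT_BINS,
) -> TTOSummary:
    """Median/IQR and bin counts over the valid records.

    Quartiles use linear interpolation between order statistics. Bins are
    exhaustive and exclusive over the nonnegative integers.
    """
    days = np.array([r.days for r in records if r.status is TTOStatus.VALID])
    n_unknown = sum(r.status is not TTOStatus.VALID for r in records)
    counts = {label: 0 for label, _, _ in bins}
    if days.size == 0:
        return TTOSummary(n_valid=0, n_unknown=n_unknown,
                          bin_counts=counts, bin_shares={k: 0.0 for k in counts})
    for d in days:
        for label, low, high in bins:
            closed_low = low == bins[0][1]  # first bin includes its lower edge
            if (d >= low if closed_low else d > low) and d <= high:
                counts[label] += 1
                break
    q1, med, q3 = np.percentile(days, [25, 50, 75])
    return TTOSummary(
        n_valid=int(days.size),
        n_unknown=n_unknown,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        bin_counts=counts,
        bin_shares={k: v / days.size for k, v in counts.items()},
    )


def write_tto_csv(records: Sequence[TTORecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = ["primaryid,days,status"]
    for r in records:
        lines.append(f"{r.primaryid},{'' if r.days is None else r.days},{r.status.value}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_tto_summary_csv(summary: TTOSummary, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = ["field,value"]
    lines.append(f"n_valid,{summary.n_valid}")
    lines.append(f"n_unknown,{summary.n_unknown}")
    for name in ("median", "q1", "q3"):
        v = getattr(summary, name)
        lines.append(f"{name},{'' if v is None else v}")
    for label, count in summary.bin_counts.items():
        lines.append(f"bin[{label}],{count}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
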