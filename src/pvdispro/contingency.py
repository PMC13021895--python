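"""2x2 contingency tables for drug-event disproportionality.

Every (cohort drug, event) pair is laid out against the rest of the cleaned
database:

====================  ==================  ======================
                      event reported      event not reported
====================  ==================  ======================
cohort reports        a                   b
all other reports     c                   d
====================  ==================  ======================

The counting unit is the report (case), never the reaction row: a report
contributes at most 1 to ``a`` for a PT however many times the PT repeats
in it, and at most 1 to a SOC if any of its PTs maps there. PT-level tables
with ``a`` below ``min_count`` (default 3) are dropped before statistics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .cleaning import Cohort, Report
from .faers_io import SocMapping


class EventLevel(enum.Enum):
    PT = "PT"
    SOC = "SOC"


DEFAULT_MIN_COUNT = 3


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")
        if self.n == 0:
            raise ValueError("empty contingency table (N=0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cohort_size(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c


@dataclass
class EventTableSet:
    """All 2x2 tables for one drug at one MedDRA level.

    ``n_unmapped_pts`` counts distinct PTs that had no SOC assignment when
    level=SOC (those reports' PTs are simply absent from SOC tables).
    """

    drug_label: str
    level: EventLevel
    tables: dict[str, ContingencyTable]
    min_count: int = DEFAULT_MIN_COUNT
    n_unmapped_pts: int = 0

    def __len__(self) -> int:
        return len(self.tables)

    def __getitem__(self, event: str) -> ContingencyTable:
        return self.tables[event]

    def __contains__(self, event: str) -> bool:
        return event in self.tables


def _events_of(report: Report, level: EventLevel, soc_mapping: Optional[SocMapping],
               unmapped: set[str]) -> frozenset[str]:
    if level is EventLevel.PT:
        return report.events
    assert soc_mapping is not None
    socs: set[str] = set()
    for pt in report.events:
        mapped = soc_mapping.lookup(pt)
        if mapped:
            socs.update(mapped)
        else:
            unmapped.add(pt)
    return frozenset(socs)


def build_tables(
    reports: Sequence[Report],
    cohort: Cohort,
    level: Union[EventLevel, str] = EventLevel.PT,
    soc_mapping: Optional[SocMapping] = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> EventTableSet:
    """Build the 2x2 table for every event observed in the cohort.

    ``reports`` is the full cleaned database; ``cohort.report_ids`` must be a
    subset of its primaryids. The background (c, d) is every non-cohort
    report. At PT level, events with a < min_count are dropped; at SOC level
    no count filter is applied.
    """
    level = EventLevel(level) if not isinstance(level, EventLevel) else level
    if level is EventLevel.SOC and soc_mapping is None:
        raise ValueError("SOC-level tables need a soc_mapping")
    ids = {r.primaryid for r in reports}
    if not cohort.report_ids <= ids:
        missing = sorted(cohort.report_ids - ids)[:5]
        raise ValueError(
            f"cohort {cohort.label!r} contains reports outside the cleaned set "
            f"(e.g. {missing})"
        )

    n_total = len(reports)
    n_cohort = len(cohort.report_ids)
    in_cohort_with: dict[str, int] = {}
    total_with: dict[str, int] = {}
    unmapped: set[str] = set()
    for report in reports:
        events = _events_of(report, level, soc_mapping, unmapped)
        is_cohort = report.primaryid in cohort.report_ids
        for event in events:
            total_with[event] = total_with.get(event, 0) + 1
            if is_cohort:
                in_cohort_with[event] = in_cohort_with.get(event, 0) + 1

    effective_min = min_count if level is EventLevel.PT else 0
    tables: dict[str, ContingencyTable] = {}
    for event, a in sorted(in_cohort_with.items()):
        if a < effective_min:
            continue
        c = total_with[event] - a
        tables[event] = ContingencyTable(
            a=a, b=n_cohort - a, c=c, d=n_total - n_cohort - c
        )
    return EventTableSet(
        drug_label=cohort.label,
        level=level,
        tables=tables,
        min_count=effective_min,
        n_unmapped_pts=len(unmapped),
    )


def summarize_counts(table_set: EventTableSet) -> list[dict]:
    """Project each table to (event, a, cohort size, event total, N)."""
    return [
        {
            "event": event,
            "a": t.a,
            "cohort_size": t.cohort_size,
            "event_total": t.event_total,
            "N": t.n,
        }
        for event, t in table_set.tables.items()
    ]


def write_tables_csv(table_set: EventTableSet, path: Union[str, Path]) -> Path:
    """Emit event,a,b,c,d as UTF-8 CSV with header."""
    path = Path(path)
    lines = ["event,a,b,c,d"]
    for event, t in table_set.tables.items():
        escaped = '"' + event.replace('"', '""') + '"' if "," in event else event
        lines.append(f"{escaped},{t.a},{t.b},{t.c},{t.d}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
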