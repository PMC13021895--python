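"""Report-level cleaning for spontaneous-report databases.

A FAERS case (CASEID) accrues multiple versions (PRIMARYIDs) as follow-up
reports arrive; analyses must keep exactly one version per case. The rules
implemented here, in order:

1. deduplicate — per CASEID keep the record with the latest FDA receipt
   date, breaking ties by the largest PRIMARYID;
2. remove_deleted — drop cases the FDA has marked for deletion;
3. assemble_reports — join DEMO/DRUG/REAC/OUTC rows into one Report per
   surviving PRIMARYID;
4. chronology_filter — drop reports whose drug start date falls strictly
   after the event onset date (both at day precision) or whose FDA receipt
   date is missing/invalid.

Cohorts are then built by restricting to reports where the drug of interest
carries the Primary Suspect (PS) role code.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .faers_io import (
    DatePrecision,
    DeletedRecord,
    DemoRecord,
    DrugLexicon,
    DrugRecord,
    OutcomeRecord,
    RawDate,
    ReactionRecord,
    RoleCode,
    Sex,
)

logger = logging.getLogger("pvdispro")

# chronology_filter / assembly drop reasons
REASON_CHRONOLOGY = "chronology"
REASON_BAD_FDA_DT = "missing_fda_dt"
REASON_NO_EVENTS = "no_events"


@dataclass
class Report:
    """One cleaned case: demographics plus its drug and event rows."""

    primaryid: str
    caseid: str
    fda_dt: RawDate
    event_dt: RawDate
    sex: Sex = Sex.UNKNOWN
    age_years: Optional[float] = None
    country: str = ""
    reporter_code: str = ""
    weight_kg: Optional[float] = None
    events: frozenset[str] = frozenset()
    drugs: list[DrugRecord] = field(default_factory=list)
    routes: frozenset[str] = frozenset()
    outcomes: frozenset[str] = frozenset()


@dataclass
class Cohort:
    label: str
    report_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.report_ids)


@dataclass
class StepCounts:
    """Bookkeeping for one cleaning step: in = kept + dropped."""

    step: str
    n_in: int
    n_kept: int
    reasons: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return self.n_in - self.n_kept


def _primaryid_sort_key(primaryid: str) -> str:
    # Numeric ids compare numerically via zero-padding; non-numeric ids are
    # logged and compared the same way (zero-padded string), per the tie rule.
    pid = primaryid.strip()
    if not pid.isdigit():
        logger.warning("non-numeric primaryid %r in dedup tie-break", primaryid)
    return pid.zfill(32)


def deduplicate(records: Sequence[DemoRecord]) -> list[DemoRecord]:
    """One DEMO record per CASEID: latest FDA_DT wins, then largest PRIMARYID.

    Idempotent; output preserves first-appearance order of the kept records.
    """
    best: dict[str, tuple] = {}
    keep: dict[str, DemoRecord] = {}
    for rec in records:
        key = (
            rec.fda_dt.value if rec.fda_dt.is_day else None,
            _primaryid_sort_key(rec.primaryid),
        )
        # None sorts below any date: records without a day-precision FDA_DT
        # lose to any dated version of the same case.
        current = best.get(rec.caseid)
        if current is None or _dedup_gt(key, current):
            best[rec.caseid] = key
            keep[rec.caseid] = rec
    order = {id(rec): i for i, rec in enumerate(records)}
    return sorted(keep.values(), key=lambda r: order[id(r)])


def _dedup_gt(key: tuple, other: tuple) -> bool:
    date_a, pid_a = key
    date_b, pid_b = other
    if (date_a is None) != (date_b is None):
        return date_b is None
    if date_a != date_b:
        return date_a > date_b
    return pid_a > pid_b


def remove_deleted(
    records: Sequence[DemoRecord],
    deleted_caseids: Iterable[str] | Iterable[DeletedRecord],
) -> list[DemoRecord]:
    """Drop every record whose CASEID appears in the deletion list."""
    deleted = {
        d.caseid if isinstance(d, DeletedRecord) else str(d) for d in deleted_caseids
    }
    return [rec for rec in records if rec.caseid not in deleted]


def assemble_reports(
    demo: Sequence[DemoRecord],
    drugs: Sequence[DrugRecord] = (),
    reactions: Sequence[ReactionRecord] = (),
    outcomes: Sequence[OutcomeRecord] = (),
) -> list[Report]:
    """Join cleaned DEMO records with their DRUG/REAC/OUTC rows.

    Reports keep their DEMO order. Reports without any reaction row are kept
    here (events empty) and rejected later by the analyzability check in
    :func:`clean_pipeline`, so callers can see them in drop accounting.
    """
    drug_by_id: dict[str, list[DrugRecord]] = {}
    for d in drugs:
        drug_by_id.setdefault(d.primaryid, []).append(d)
    events_by_id: dict[str, set[str]] = {}
    for r in reactions:
        pt = r.pt.strip()
        if pt:
            events_by_id.setdefault(r.primaryid, set()).add(pt)
    outc_by_id: dict[str, set[str]] = {}
    for o in outcomes:
        code = o.outcome_code.strip()
        if code:
            outc_by_id.setdefault(o.primaryid, set()).add(code)

    reports = []
    for rec in demo:
        drug_rows = drug_by_id.get(rec.primaryid, [])
        reports.append(
            Report(
                primaryid=rec.primaryid,
                caseid=rec.caseid,
                fda_dt=rec.fda_dt,
                event_dt=rec.event_dt,
                sex=rec.sex,
                age_years=rec.age_years,
                country=rec.country,
                reporter_code=rec.reporter_code,
                weight_kg=rec.weight_kg,
                events=frozenset(events_by_id.get(rec.primaryid, ())),
                drugs=drug_rows,
                routes=frozenset(d.route.strip() for d in drug_rows if d.route.strip()),
                outcomes=frozenset(outc_by_id.get(rec.primaryid, ())),
            )
        )
    return reports


def chronology_filter(
    reports: Sequence[Report],
) -> tuple[list[Report], list[tuple[Report, str]]]:
    """Drop chronologically impossible reports and reports without a valid
    FDA receipt date.

    A report is dropped iff (a) some drug start date is strictly after the
    event onset date with both at day precision, or (b) FDA_DT is not a full
    valid date. Partial dates never trigger the chronology rule — deciding
    "after" needs day precision on both sides.
    """
    kept: list[Report] = []
    dropped: list[tuple[Report, str]] = []
    for report in reports:
        if not report.fda_dt.is_day:
            dropped.append((report, REASON_BAD_FDA_DT))
            continue
        if _chronology_violation(report):
            dropped.append((report, REASON_CHRONOLOGY))
            continue
        kept.append(report)
    return kept, dropped


def _chronology_violation(report: Report) -> bool:
    if report.event_dt.precision is not DatePrecision.DAY:
        return False
    for drug in report.drugs:
        if drug.start_dt.is_day and drug.start_dt.value > report.event_dt.value:
            return True
    return False


def build_cohort(
    reports: Sequence[Report],
    lexicon: DrugLexicon,
    *,
    strict_single_suspect: bool = False,
) -> Cohort:
    """Reports where a lexicon drug carries the Primary Suspect role.

    With ``strict_single_suspect`` the report must also name no other
    suspect drug (PS or SS) outside the lexicon.
    """
    if not lexicon.synonyms:
        raise ValueError(f"lexicon {lexicon.target_label!r} has no synonyms")
    ids = []
    for report in reports:
        ps_match = any(
            d.role_code is RoleCode.PS
            and lexicon.matches(d.drug_name, d.active_ingredient)
            for d in report.drugs
        )
        if not ps_match:
            continue
        if strict_single_suspect:
            other_suspect = any(
                d.role_code in (RoleCode.PS, RoleCode.SS)
                and not lexicon.matches(d.drug_name, d.active_ingredient)
                for d in report.drugs
            )
            if other_suspect:
                continue
        ids.append(report.primaryid)
    return Cohort(label=lexicon.target_label, report_ids=frozenset(ids))


@dataclass
class CleaningResult:
    reports: list[Report]
    steps: list[StepCounts]

    def manifest(self) -> dict:
        return {
            "steps": [
                {
                    "step": s.step,
                    "in": s.n_in,
                    "kept": s.n_kept,
                    "dropped": s.n_dropped,
                    "reasons": dict(s.reasons),
                }
                for s in self.steps
            ],
            "n_reports": len(self.reports),
        }


def clean_pipeline(
    demo: Sequence[DemoRecord],
    drugs: Sequence[DrugRecord] = (),
    reactions: Sequence[ReactionRecord] = (),
    outcomes: Sequence[OutcomeRecord] = (),
    deleted: Iterable[str] | Iterable[DeletedRecord] = (),
) -> CleaningResult:
    """Run the full cleaning sequence with per-step accounting.

    Order: deduplicate -> remove_deleted -> assemble -> drop event-less
    reports -> chronology filter.
    """
    steps: list[StepCounts] = []

    deduped = deduplicate(demo)
    steps.append(
        StepCounts(
            "deduplicate",
            len(demo),
            len(deduped),
            Counter({"duplicate_version": len(demo) - len(deduped)}),
        )
    )

    surviving = remove_deleted(deduped, deleted)
    steps.append(
        StepCounts(
            "remove_deleted",
            len(deduped),
            len(surviving),
            Counter({"deleted_case": len(deduped) - len(surviving)}),
        )
    )

    assembled = assemble_reports(surviving, drugs, reactions, outcomes)
    analyzable = [r for r in assembled if r.events]
    steps.append(
        StepCounts(
            "require_events",
            len(assembled),
            len(analyzable),
            Counter({REASON_NO_EVENTS: len(assembled) - len(analyzable)}),
        )
    )

    kept, dropped = chronology_filter(analyzable)
    steps.append(
        StepCounts(
            "chronology_filter",
            len(analyzable),
            len(kept),
            Counter(reason for _, reason in dropped),
        )
    )

    return CleaningResult(reports=kept, steps=steps)
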