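"""Demographic summaries and sex/age subgroup signal analyses.

Subgroup analyses restrict BOTH the cohort and the background database to
the stratum before any table is built — the standard subgroup
disproportionality convention — then apply the ordinary contingency and
statistics machinery unchanged, including the minimum-count filter. An
``any``/``any`` stratum therefore reproduces the global analysis exactly,
and cell counts over a partition of strata (e.g. F + M + unknown) sum to
the unstratified cells.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .cleaning import Cohort, Report
from .contingency import DEFAULT_MIN_COUNT, EventLevel, EventTableSet, build_tables
from .dispro_stats import (
    DEFAULT_PRIORS,
    DEFAULT_THRESHOLDS,
    BcpnnPriors,
    SignalStatistics,
    Thresholds,
    signal_table,
)
from .faers_io import Sex, SocMapping

DEFAULT_AGE_CUT = 60.0


class AgeGroup(enum.Enum):
    UNDER = "under60"
    OVER_OR_EQUAL = "over_or_equal_60"
    UNKNOWN = "unknown"
    ANY = "any"


class SexGroup(enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"
    ANY = "any"


@dataclass(frozen=True)
class StratumSpec:
    """A sex/age subgroup. ``any`` leaves that axis unrestricted."""

    sex: SexGroup = SexGroup.ANY
    age_group: AgeGroup = AgeGroup.ANY
    age_cut: float = DEFAULT_AGE_CUT

    def contains(self, report: Report) -> bool:
        if self.sex is not SexGroup.ANY:
            sex = {Sex.F: SexGroup.F, Sex.M: SexGroup.M}.get(
                report.sex, SexGroup.UNKNOWN
            )
            if sex is not self.sex:
                return False
        if self.age_group is not AgeGroup.ANY:
            if age_group_of(report.age_years, self.age_cut) is not self.age_group:
                return False
        return True

    def label(self) -> str:
        return f"{self.sex.value}_{self.age_group.value}"


def age_group_of(age_years: Optional[float], cut: float = DEFAULT_AGE_CUT) -> AgeGroup:
    """Partition an age into under/over-or-equal/unknown at the cut (years)."""
    if age_years is None or not np.isfinite(age_years):
        return AgeGroup.UNKNOWN
    return AgeGroup.UNDER if age_years < cut else AgeGroup.OVER_OR_EQUAL


# FAERS code -> display label maps for the demographic summary.
REPORTER_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "OT": "Other health-professional",
    "PH": "Pharmacist",
    "LW": "Lawyer",
    "RN": "Registered nurse",
    "HP": "Health professional",
    "": "Unknown",
}
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention to prevent permanent impairment/damage",
    "OT": "Other serious",
}


@dataclass
class DemographicsSummary:
    """Counts, percentages and quantiles describing one cohort."""

    n: int
    sex_counts: dict[str, int] = field(default_factory=dict)
    age_group_counts: dict[str, int] = field(default_factory=dict)
    reporter_counts: dict[str, int] = field(default_factory=dict)
    outcome_counts: dict[str, int] = field(default_factory=dict)
    country_counts: dict[str, int] = field(default_factory=dict)
    route_counts: dict[str, int] = field(default_factory=dict)
    year_counts: dict[int, int] = field(default_factory=dict)
    age_median: Optional[float] = None
    age_q1: Optional[float] = None
    age_q3: Optional[float] = None
    weight_median: Optional[float] = None
    weight_q1: Optional[float] = None
    weight_q3: Optional[float] = None

    def percentages(self, counts: dict) -> dict:
        if self.n == 0:
            return {k: 0.0 for k in counts}
        return {k: 100.0 * v / self.n for k, v in counts.items()}


def _quartiles(values: list[float]) -> tuple[Optional[float], ...]:
    if not values:
        return None, None, None
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def summarize_demographics(
    reports: Sequence[Report],
    cohort: Optional[Cohort] = None,
    age_cut: float = DEFAULT_AGE_CUT,
) -> DemographicsSummary:
    """Tabulate sex, age group, reporter, outcome, country, route and report
    year over a cohort; medians and IQRs over non-missing age and weight.

    ``cohort=None`` summarizes all reports. Sex/age-group percentages are
    shares of the cohort; a report can contribute to several outcome or
    route categories, so those percentages may exceed 100 in sum.
    """
    if cohort is not None:
        reports = [r for r in reports if r.primaryid in cohort.report_ids]
    summary = DemographicsSummary(n=len(reports))
    sex_c: Counter = Counter()
    age_c: Counter = Counter()
    rep_c: Counter = Counter()
    out_c: Counter = Counter()
    country_c: Counter = Counter()
    route_c: Counter = Counter()
    year_c: Counter = Counter()
    ages, weights = [], []
    for r in reports:
        sex_c[r.sex.value if r.sex is not Sex.UNKNOWN else "Unknown"] += 1
        age_c[age_group_of(r.age_years, age_cut).value] += 1
        rep_c[REPORTER_LABELS.get(r.reporter_code.upper(), r.reporter_code or "Unknown")] += 1
        for code in r.outcomes:
            out_c[OUTCOME_LABELS.get(code.upper(), code)] += 1
        country_c[r.country or "Unknown"] += 1
        for route in r.routes:
            route_c[route] += 1
        if r.fda_dt.year is not None:
            year_c[r.fda_dt.year] += 1
        if r.age_years is not None:
            ages.append(r.age_years)
        if r.weight_kg is not None:
            weights.append(r.weight_kg)
    summary.sex_counts = dict(sex_c)
    summary.age_group_counts = dict(age_c)
    summary.reporter_counts = dict(rep_c)
    summary.outcome_counts = dict(out_c)
    summary.country_counts = dict(country_c)
    summary.route_counts = dict(route_c)
    summary.year_counts = dict(sorted(year_c.items()))
    summary.age_median, summary.age_q1, summary.age_q3 = _quartiles(ages)
    summary.weight_median, summary.weight_q1, summary.weight_q3 = _quartiles(weights)
    return summary


def run_subgroup(
    reports: Sequence[Report],
    cohort: Cohort,
    stratum: StratumSpec,
    level: Union[EventLevel, str] = EventLevel.PT,
    soc_mapping: Optional[SocMapping] = None,
    min_count: int = DEFAULT_MIN_COUNT,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    priors: BcpnnPriors = DEFAULT_PRIORS,
    restrict_background: bool = True,
) -> tuple[EventTableSet, dict[str, SignalStatistics]]:
    """Signal analysis inside one sex/age stratum.

    Both cohort and background are restricted to the stratum (set
    ``restrict_background=False`` to keep the full database as comparator).
    Returns the stratum's table set and its signal statistics; an empty
    stratum cohort yields empty outputs.
    """
    in_stratum = [r for r in reports if stratum.contains(r)]
    stratum_ids = {r.primaryid for r in in_stratum}
    sub_cohort = Cohort(
        label=cohort.label, report_ids=cohort.report_ids & frozenset(stratum_ids)
    )
    background = in_stratum if restrict_background else list(reports)
    table_set = build_tables(background, sub_cohort, level, soc_mapping, min_count)
    return table_set, signal_table(table_set, thresholds, priors)
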