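"""Synthetic FAERS-style databases with known ground truth.

The generator emulates the structure the cleaning and signal modules
consume — DEMO/DRUG/REAC/OUTC tables plus a deleted-case list — with
planted drug-event associations of known rate ratio, duplicate case
versions, deleted cases, missing and partial dates, and configurable
demographics. Every draw flows from one :class:`numpy.random.Generator`
seeded from the config, so identical configs produce byte-identical files.

Event model: each report carries exactly one Primary Suspect drug drawn
from the prevalence mixture; each PT is an independent Bernoulli coin with
probability ``min(1, RR(drug, pt) * p0(pt))``. All-zero event rows are
redrawn (capped retries, then a single forced background event), i.e.
events are distributed conditionally on at least one event per report —
the :class:`TruthTable` accounts for that conditioning when it derives the
induced odds ratio a recovery test should compare against.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cleaning import CleaningResult, clean_pipeline
from .contingency import ContingencyTable
from .dispro_stats import SignalStatistics
from .faers_io import (
    AgeUnit,
    DeletedRecord,
    DemoRecord,
    DrugRecord,
    OutcomeRecord,
    RawDate,
    ReactionRecord,
    RoleCode,
    Sex,
    SocMapping,
    TableKind,
    normalize_name,
    parse_date,
    write_table,
)

_EPOCH = _dt.date(2004, 7, 1)
_LAST_START = _dt.date(2024, 6, 30)

_MAX_REDRAW_ROUNDS = 50


@dataclass(frozen=True)
class PlantedEffect:
    """A planted association: reports of ``drug`` carry ``pt`` with its
    background probability multiplied by ``rr`` (capped at 1). ``sex``
    restricts the effect to one sex, for effect-modification scenarios."""

    drug: str
    pt: str
    rr: float
    sex: Optional[Sex] = None


@dataclass(frozen=True)
class AgeComponent:
    low: float
    high: float
    weight: float


@dataclass
class SyntheticConfig:
    """Full generative specification of a synthetic reporting database.

    Defaults describe the reference study conditions used throughout the
    test-bench: 50,000 reports, one cohort drug at 10% prevalence, 200 PTs
    at background reporting probability 0.01 spread over 10 SOCs, sex and
    age mixtures matching a typical antibiotic cohort, a short geometric
    time-to-onset (median ~2 days), 5% duplicate case versions, 1% deleted
    cases, ~20% missing event dates.
    """

    seed: int = 0
    n_reports: int = 50_000
    drugs: tuple[tuple[str, float], ...] = (("DRUG_A", 0.10),)
    n_background_drugs: int = 10
    n_pts: int = 200
    n_socs: int = 10
    background_pt_prob: float = 0.01
    effects: tuple[PlantedEffect, ...] = ()
    duplicate_rate: float = 0.05
    deleted_rate: float = 0.01
    missing_event_dt_rate: float = 0.20
    partial_date_rate: float = 0.05
    pt_repeat_rate: float = 0.0
    sex_split: tuple[float, float, float] = (0.55, 0.37, 0.08)  # F, M, unknown
    age_components: tuple[AgeComponent, ...] = (
        AgeComponent(0.0, 60.0, 0.47),
        AgeComponent(60.0, 90.0, 0.30),
    )  # remaining mass -> age unknown
    tto_mean_days: float = 3.0
    reporting_delay_mean_days: float = 30.0

    def __post_init__(self) -> None:
        prev = sum(p for _, p in self.drugs)
        if not 0 <= prev <= 1:
            raise ValueError("drug prevalences must sum to at most 1")
        for name, value in (
            ("duplicate_rate", self.duplicate_rate),
            ("deleted_rate", self.deleted_rate),
            ("missing_event_dt_rate", self.missing_event_dt_rate),
            ("partial_date_rate", self.partial_date_rate),
            ("pt_repeat_rate", self.pt_repeat_rate),
        ):
            if not 0 <= value < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.background_pt_prob <= 1:
            raise ValueError("background_pt_prob must be in (0, 1]")
        if self.n_pts <= 0 or self.n_socs <= 0:
            raise ValueError("need at least one PT and one SOC")
        for eff in self.effects:
            if eff.rr < 0:
                raise ValueError(f"negative rate ratio for {eff.drug}/{eff.pt}")
        known = {label for label, _ in self.drugs}
        for eff in self.effects:
            if eff.drug not in known:
                raise ValueError(f"effect on unknown drug {eff.drug!r}")
        if abs(sum(self.sex_split) - 1.0) > 1e-9:
            raise ValueError("sex_split must sum to 1")
        if sum(c.weight for c in self.age_components) > 1 + 1e-9:
            raise ValueError("age component weights must sum to at most 1")

    # -- derived vocabulary -------------------------------------------------

    @property
    def pt_names(self) -> list[str]:
        return [f"PT_{i:03d}" for i in range(1, self.n_pts + 1)]

    @property
    def soc_names(self) -> list[str]:
        return [f"SOC_{i:02d}" for i in range(1, self.n_socs + 1)]

    def soc_of(self, pt_index: int) -> str:
        return self.soc_names[pt_index % self.n_socs]

    @property
    def drug_labels(self) -> list[str]:
        bg = [f"BG_DRUG_{i:02d}" for i in range(1, self.n_background_drugs + 1)]
        return [label for label, _ in self.drugs] + bg

    @property
    def drug_probs(self) -> np.ndarray:
        prev = [p for _, p in self.drugs]
        rest = 1.0 - sum(prev)
        if self.n_background_drugs == 0:
            if rest > 1e-9:
                raise ValueError("prevalences < 1 but no background drugs")
            return np.asarray(prev)
        return np.asarray(prev + [rest / self.n_background_drugs] * self.n_background_drugs)

    def pt_probs(self) -> np.ndarray:
        return np.full(self.n_pts, self.background_pt_prob)

    def soc_mapping(self) -> SocMapping:
        return SocMapping(
            entries={
                normalize_name(pt): frozenset({self.soc_of(i)})
                for i, pt in enumerate(self.pt_names)
            }
        )


@dataclass
class TruthTable:
    """Ground truth for a generated database.

    ``rr`` is the planted rate ratio (1 everywhere except configured
    effects). ``expected_a`` is the unconditional n * prevalence *
    min(1, RR * p0) cell expectation; ``induced_odds_ratio`` is the exact
    odds ratio the at-least-one-event conditioning induces between the
    cohort and the pooled background, which is what a consistent ROR
    estimate converges to.
    """

    config: SyntheticConfig

    def rr(self, drug: str, pt: str) -> float:
        total = 1.0
        for eff in self.config.effects:
            if eff.drug == drug and eff.pt == pt and eff.sex is None:
                total *= eff.rr
        return total

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (drug, pt)
            for drug, _ in self.config.drugs
            for pt in self.config.pt_names
        ]

    def expected_a(self, drug: str, pt: str) -> float:
        prev = dict(self.config.drugs)[drug]
        p0 = self.config.background_pt_prob
        return self.config.n_reports * prev * min(1.0, self.rr(drug, pt) * p0)

    # conditional per-(drug, sex) event marginals
    def _marginals(self) -> dict[str, np.ndarray]:
        cfg = self.config
        p0 = cfg.pt_probs()
        pt_index = {pt: i for i, pt in enumerate(cfg.pt_names)}
        sexes = [Sex.F, Sex.M, Sex.UNKNOWN]
        out: dict[str, np.ndarray] = {}
        for label in cfg.drug_labels:
            marg = np.zeros(cfg.n_pts)
            for sex, w in zip(sexes, cfg.sex_split):
                p = p0.copy()
                for eff in cfg.effects:
                    if eff.drug == label and (eff.sex is None or eff.sex is sex):
                        j = pt_index[eff.pt]
                        p[j] = min(1.0, p[j] * eff.rr)
                q = np.prod(1.0 - p)
                marg += w * p / (1.0 - q)
            out[label] = marg
        return out

    def induced_odds_ratio(self, drug: str, pt: str) -> float:
        cfg = self.config
        marg = self._marginals()
        j = cfg.pt_names.index(pt)
        w = cfg.drug_probs
        labels = cfg.drug_labels
        i_drug = labels.index(drug)
        m1 = marg[drug][j]
        w_bg = np.delete(w, i_drug)
        m0 = sum(
            w_d * marg[label][j]
            for w_d, label in zip(w_bg, [l for l in labels if l != drug])
        ) / w_bg.sum()
        return (m1 / (1 - m1)) / (m0 / (1 - m0))


def _dates_to_text(days: np.ndarray) -> np.ndarray:
    base = np.datetime64(_EPOCH.isoformat(), "D")
    as_dt = base + days.astype("timedelta64[D]")
    return np.char.replace(np.datetime_as_string(as_dt, unit="D"), "-", "")


_OUTCOME_CODES = ["OT", "HO", "LT", "DE", "DS", "RI", "CA"]
_OUTCOME_PROBS = [0.48, 0.38, 0.08, 0.03, 0.02, 0.006, 0.004]
_ROUTES = ["Oral", "Other", "Intravenous", "Transplacental"]
_ROUTE_PROBS = [0.50, 0.44, 0.05, 0.01]
_COUNTRIES = ["FR", "US", "GB", "IT", "CA", "ES", "DE", "PT"]
_COUNTRY_PROBS = [0.26, 0.23, 0.17, 0.11, 0.06, 0.03, 0.03, 0.11]
_REPORTERS = ["CN", "MD", "OT", "PH", ""]
_REPORTER_PROBS = [0.30, 0.28, 0.20, 0.19, 0.03]


@dataclass
class SyntheticDataset:
    """Arrays for one generated database plus typed-record/file views.

    Index 0..n-1 are original reports; ``dup_src`` lists the originals that
    received a duplicate case version (clones share the CASEID, carry a new
    PRIMARYID and — for half of them — a later FDA date, the other half an
    identical FDA date to exercise the PRIMARYID tie-break).
    """

    config: SyntheticConfig
    truth: TruthTable
    events: np.ndarray  # bool (n, n_pts)
    drug_idx: np.ndarray  # int (n,)
    sex_idx: np.ndarray  # 0=F 1=M 2=unknown
    age_years: np.ndarray  # float, nan = unknown
    weight_kg: np.ndarray  # float, nan = unknown
    start_days: np.ndarray  # int days since epoch
    tto_days: np.ndarray  # int
    fda_days: np.ndarray  # int
    event_missing: np.ndarray  # bool
    start_partial: np.ndarray  # bool (start date reduced to month precision)
    outcome_idx: np.ndarray
    route_idx: np.ndarray
    country_idx: np.ndarray
    reporter_idx: np.ndarray
    deleted: np.ndarray  # bool over originals
    dup_src: np.ndarray  # int indices of cloned originals
    dup_same_fda: np.ndarray  # bool per clone

    # -- identifiers --------------------------------------------------------

    def caseid(self, i: int) -> str:
        return str(10_000_000 + i)

    def primaryid(self, i: int, version: int = 1) -> str:
        return f"{10_000_000 + i}{version}"

    # -- text fields --------------------------------------------------------

    def _start_text(self, i: int) -> str:
        text = _dates_to_text(self.start_days[[i]])[0]
        return text[:6] if self.start_partial[i] else text

    def _event_text(self, i: int) -> str:
        if self.event_missing[i]:
            return ""
        return _dates_to_text(np.array([self.start_days[i] + self.tto_days[i]]))[0]

    def _fda_text(self, i: int, clone: bool = False, same_fda: bool = False) -> str:
        day = self.fda_days[i] + (0 if (not clone or same_fda) else 1)
        return _dates_to_text(np.array([day]))[0]

    # -- record views -------------------------------------------------------

    def _demo_one(self, i: int, version: int, clone: bool, same_fda: bool) -> DemoRecord:
        sex = (Sex.F, Sex.M, Sex.UNKNOWN)[self.sex_idx[i]]
        age = self.age_years[i]
        has_age = not math.isnan(age)
        wt = self.weight_kg[i]
        return DemoRecord(
            primaryid=self.primaryid(i, version),
            caseid=self.caseid(i),
            fda_dt=parse_date(self._fda_text(i, clone, same_fda)),
            event_dt=parse_date(self._event_text(i)),
            sex=sex,
            age_value=round(float(age), 1) if has_age else None,
            age_unit=AgeUnit.YEARS if has_age else AgeUnit.UNKNOWN,
            reporter_code=_REPORTERS[self.reporter_idx[i]],
            country=_COUNTRIES[self.country_idx[i]],
            weight_kg=round(float(wt), 1) if not math.isnan(wt) else None,
        )

    def demo_records(self) -> list[DemoRecord]:
        records = [self._demo_one(i, 1, False, False) for i in range(len(self.drug_idx))]
        for k, i in enumerate(self.dup_src):
            records.append(self._demo_one(int(i), 2, True, bool(self.dup_same_fda[k])))
        return records

    def _ids_with_clones(self) -> list[tuple[int, int]]:
        pairs = [(i, 1) for i in range(len(self.drug_idx))]
        pairs += [(int(i), 2) for i in self.dup_src]
        return pairs

    def drug_records(self) -> list[DrugRecord]:
        labels = self.config.drug_labels
        return [
            DrugRecord(
                primaryid=self.primaryid(i, v),
                drug_name=labels[self.drug_idx[i]],
                active_ingredient=labels[self.drug_idx[i]],
                role_code=RoleCode.PS,
                route=_ROUTES[self.route_idx[i]],
                start_dt=parse_date(self._start_text(i)),
            )
            for i, v in self._ids_with_clones()
        ]

    def reaction_records(self) -> list[ReactionRecord]:
        pts = self.config.pt_names
        rng = np.random.default_rng(self.config.seed + 104729)  # repeat-row draws only
        repeat = self.config.pt_repeat_rate
        records = []
        for i, v in self._ids_with_clones():
            pid = self.primaryid(i, v)
            for j in np.flatnonzero(self.events[i]):
                records.append(ReactionRecord(primaryid=pid, pt=pts[j]))
                if repeat and rng.random() < repeat:
                    records.append(ReactionRecord(primaryid=pid, pt=pts[j]))
        return records

    def outcome_records(self) -> list[OutcomeRecord]:
        return [
            OutcomeRecord(
                primaryid=self.primaryid(i, v),
                outcome_code=_OUTCOME_CODES[self.outcome_idx[i]],
            )
            for i, v in self._ids_with_clones()
        ]

    def deleted_records(self) -> list[DeletedRecord]:
        return [DeletedRecord(caseid=self.caseid(int(i)))
                for i in np.flatnonzero(self.deleted)]

    def record_tables(self) -> dict[str, list]:
        return {
            "DEMO": self.demo_records(),
            "DRUG": self.drug_records(),
            "REAC": self.reaction_records(),
            "OUTC": self.outcome_records(),
            "DELETED": self.deleted_records(),
        }

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Write the ``$``-delimited table files the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, records in self.record_tables().items():
            paths[name] = write_table(
                records, outdir / f"{name}.txt", TableKind(name)
            )
        return paths

    def write_truth_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        lines = ["drug,pt,rr,expected_a"]
        for drug, pt in self.truth.pairs():
            lines.append(
                f"{drug},{pt},{self.truth.rr(drug, pt)!r},"
                f"{self.truth.expected_a(drug, pt)!r}"
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    def clean(self) -> CleaningResult:
        """Run the cleaning pipeline over the typed-record views."""
        return clean_pipeline(
            self.demo_records(),
            self.drug_records(),
            self.reaction_records(),
            self.outcome_records(),
            self.deleted_records(),
        )

    # -- fast analytic counting path ---------------------------------------

    def pair_table(self, drug: str, pt: str) -> ContingencyTable:
        """The post-cleaning 2x2 table for one pair, computed from arrays.

        Duplicate clones share CASEID and content, so deduplication leaves
        the original counts; deletion removes whole cases. Verified against
        the full record pipeline in the test suite.
        """
        keep = ~self.deleted
        j = self.config.pt_names.index(pt)
        cohort = self.drug_idx == self.config.drug_labels.index(drug)
        has = self.events[:, j]
        a = int(np.sum(keep & cohort & has))
        b = int(np.sum(keep & cohort & ~has))
        c = int(np.sum(keep & ~cohort & has))
        d = int(np.sum(keep & ~cohort & ~has))
        return ContingencyTable(a=a, b=b, c=c, d=d)

    def tables_for_drug(self, drug: str, min_count: int = 0) -> dict[str, ContingencyTable]:
        """Post-cleaning 2x2 tables for every PT at once (vectorised
        :meth:`pair_table`); PTs with a < min_count are omitted."""
        keep = ~self.deleted
        cohort = keep & (self.drug_idx == self.config.drug_labels.index(drug))
        background = keep & ~cohort
        a = self.events[cohort].sum(axis=0)
        c = self.events[background].sum(axis=0)
        n_cohort = int(cohort.sum())
        n_bg = int(background.sum())
        out = {}
        for j, pt in enumerate(self.config.pt_names):
            if a[j] < min_count:
                continue
            out[pt] = ContingencyTable(
                a=int(a[j]), b=n_cohort - int(a[j]),
                c=int(c[j]), d=n_bg - int(c[j]),
            )
        return out


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full synthetic database; deterministic given the config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    p0 = config.pt_probs()
    if n > 0 and not config.effects and float(p0.sum()) == 0:
        raise ValueError("infeasible config: all event probabilities zero")

    drug_idx = rng.choice(len(config.drug_labels), size=n, p=config.drug_probs)
    sex_idx = rng.choice(3, size=n, p=list(config.sex_split))

    # per-effect applicability masks
    pt_index = {pt: i for i, pt in enumerate(config.pt_names)}
    sex_code = {Sex.F: 0, Sex.M: 1, Sex.UNKNOWN: 2}
    masks = []
    for eff in config.effects:
        mask = drug_idx == config.drug_labels.index(eff.drug)
        if eff.sex is not None:
            mask = mask & (sex_idx == sex_code[eff.sex])
        masks.append((mask, pt_index[eff.pt], min(1.0, eff.rr * p0[pt_index[eff.pt]])))

    def draw_events(rows: np.ndarray) -> np.ndarray:
        k = rows.size
        probs = np.tile(p0, (k, 1))
        for mask, j, p_eff in masks:
            sel = mask[rows]
            probs[sel, j] = p_eff
        return rng.random((k, config.n_pts)) < probs

    events = np.zeros((n, config.n_pts), dtype=bool)
    if n:
        events[:] = draw_events(np.arange(n))
        for _ in range(_MAX_REDRAW_ROUNDS):
            zero = np.flatnonzero(~events.any(axis=1))
            if zero.size == 0:
                break
            events[zero] = draw_events(zero)
        zero = np.flatnonzero(~events.any(axis=1))
        if zero.size:  # force one background event, sampled by weight
            total = float(p0.sum())
            if total == 0:
                raise ValueError("infeasible config: all event probabilities zero")
            forced = rng.choice(config.n_pts, size=zero.size, p=p0 / total)
            events[zero, forced] = True

    # demographics
    weights = [c.weight for c in config.age_components]
    unknown_mass = 1.0 - sum(weights)
    comp = rng.choice(len(weights) + 1, size=n, p=weights + [unknown_mass])
    age = np.full(n, np.nan)
    for ci, c in enumerate(config.age_components):
        rows = comp == ci
        age[rows] = rng.uniform(c.low, c.high, size=int(rows.sum()))
    weight = np.where(
        rng.random(n) < 0.5, rng.normal(70.0, 15.0, size=n).clip(30, 160), np.nan
    )

    # dates (integer days since epoch)
    horizon = (_LAST_START - _EPOCH).days
    start_days = rng.integers(0, horizon + 1, size=n)
    p_tto = 1.0 / (config.tto_mean_days + 1.0)
    tto_days = rng.geometric(p_tto, size=n) - 1
    delay = rng.geometric(1.0 / config.reporting_delay_mean_days, size=n)
    fda_days = start_days + tto_days + delay
    event_missing = rng.random(n) < config.missing_event_dt_rate
    start_partial = rng.random(n) < config.partial_date_rate

    outcome_idx = rng.choice(len(_OUTCOME_CODES), size=n, p=_OUTCOME_PROBS)
    route_idx = rng.choice(len(_ROUTES), size=n, p=_ROUTE_PROBS)
    country_idx = rng.choice(len(_COUNTRIES), size=n, p=_COUNTRY_PROBS)
    reporter_idx = rng.choice(len(_REPORTERS), size=n, p=_REPORTER_PROBS)

    deleted = rng.random(n) < config.deleted_rate
    dup_src = np.flatnonzero(rng.random(n) < config.duplicate_rate)
    dup_same_fda = rng.random(dup_src.size) < 0.5

    return SyntheticDataset(
        config=config,
        truth=TruthTable(config=config),
        events=events,
        drug_idx=drug_idx,
        sex_idx=sex_idx,
        age_years=age,
        weight_kg=weight,
        start_days=start_days,
        tto_days=tto_days,
        fda_days=fda_days,
        event_missing=event_missing,
        start_partial=start_partial,
        outcome_idx=outcome_idx,
        route_idx=route_idx,
        country_idx=country_idx,
        reporter_idx=reporter_idx,
        deleted=deleted,
        dup_src=dup_src,
        dup_same_fda=dup_same_fda,
    )


@dataclass
class RecoveryResult:
    sensitivity: Optional[float]
    false_positive_rate: Optional[float]
    n_positive_pairs: int
    n_null_pairs: int
    decisions: list[dict] = field(default_factory=list)


def evaluate_recovery(
    stats_by_drug: dict[str, dict[str, SignalStatistics]],
    truth: TruthTable,
    min_expected: float = 3.0,
) -> RecoveryResult:
    """Score signal decisions against the generator's ground truth.

    Sensitivity is computed over planted RR>1 pairs whose expected cell
    count is at least ``min_expected``; the false-positive rate over RR=1
    pairs. Pairs absent from a signal table (below min_count) count as not
    flagged. With no positive pairs, sensitivity is None.
    """
    decisions = []
    tp = fp = n_pos = n_null = 0
    for drug, pt in truth.pairs():
        if drug not in stats_by_drug:
            continue
        rr = truth.rr(drug, pt)
        flagged = bool(
            pt in stats_by_drug[drug] and stats_by_drug[drug][pt].signal
        )
        expected = truth.expected_a(drug, pt)
        decisions.append(
            {"drug": drug, "pt": pt, "rr": rr, "expected_a": expected,
             "flagged": flagged}
        )
        if rr > 1 and expected >= min_expected:
            n_pos += 1
            tp += flagged
        elif rr == 1:
            n_null += 1
            fp += flagged
    return RecoveryResult(
        sensitivity=tp / n_pos if n_pos else None,
        false_positive_rate=fp / n_null if n_null else None,
        n_positive_pairs=n_pos,
        n_null_pairs=n_null,
        decisions=decisions,
    )
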