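"""Readers and writers for FAERS-style quarterly ASCII tables.

FAERS distributes each quarter as ``$``-delimited text files with a header
row (DEMO, DRUG, REAC, OUTC, THER, INDI plus a list of deleted cases).
Column names drift across quarters, so every reader binds columns by
header name (case-insensitively), never by position. Files are decoded as
latin-1 with replacement, matching the encoding the FDA actually ships.

Dates in FAERS are digit strings of varying completeness: ``YYYYMMDD``,
``YYYYMM`` or ``YYYY``. :func:`parse_date` classifies each string into a
:class:`RawDate` with an explicit precision instead of guessing, because
downstream rules (chronology exclusion, time-to-onset) are only allowed to
fire on full-precision dates.
"""

from __future__ import annotations

import csv
import datetime as _dt
import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

logger = logging.getLogger("pvdispro")

DELIMITER = "$"
ENCODING = "latin-1"


class DatePrecision(enum.Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"
    MISSING = "missing"
    INVALID = "invalid"


@dataclass(frozen=True)
class RawDate:
    """A FAERS date string together with its parsed precision.

    ``value`` is a :class:`datetime.date` only when ``precision`` is DAY;
    ``year``/``month`` carry whatever partial information the string held.
    """

    text: str
    precision: DatePrecision
    value: Optional[_dt.date] = None
    year: Optional[int] = None
    month: Optional[int] = None

    @property
    def is_day(self) -> bool:
        return self.precision is DatePrecision.DAY

    @property
    def is_missing(self) -> bool:
        return self.precision is DatePrecision.MISSING

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.text!r}({self.precision.value})"


MISSING_DATE = RawDate(text="", precision=DatePrecision.MISSING)

_DIGITS = re.compile(r"^\d+$")


def parse_date(text: Optional[str]) -> RawDate:
    """Classify a FAERS date string; never raises on malformed input.

    8 digits forming a valid calendar date -> day precision; 6 digits with a
    valid month -> month; 4 digits -> year; empty/whitespace -> missing;
    anything else (including Feb 30) -> invalid.
    """
    if text is None:
        return MISSING_DATE
    stripped = text.strip()
    if not stripped:
        return RawDate(text=text, precision=DatePrecision.MISSING)
    if not _DIGITS.match(stripped):
        return RawDate(text=text, precision=DatePrecision.INVALID)
    n = len(stripped)
    if n == 8:
        try:
            value = _dt.date(int(stripped[:4]), int(stripped[4:6]), int(stripped[6:8]))
        except ValueError:
            return RawDate(text=text, precision=DatePrecision.INVALID)
        return RawDate(
            text=text,
            precision=DatePrecision.DAY,
            value=value,
            year=value.year,
            month=value.month,
        )
    if n == 6:
        year, month = int(stripped[:4]), int(stripped[4:6])
        if not 1 <= month <= 12:
            return RawDate(text=text, precision=DatePrecision.INVALID)
        return RawDate(text=text, precision=DatePrecision.MONTH, year=year, month=month)
    if n == 4:
        return RawDate(text=text, precision=DatePrecision.YEAR, year=int(stripped))
    return RawDate(text=text, precision=DatePrecision.INVALID)


class Sex(enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


class AgeUnit(enum.Enum):
    YEARS = "YR"
    MONTHS = "MON"
    WEEKS = "WK"
    DAYS = "DY"
    DECADES = "DEC"
    UNKNOWN = "unknown"


class RoleCode(enum.Enum):
    PS = "PS"
    SS = "SS"
    C = "C"
    I = "I"
    UNKNOWN = "unknown"


# conversion to years
_AGE_FACTORS = {
    AgeUnit.YEARS: 1.0,
    AgeUnit.DECADES: 10.0,
    AgeUnit.MONTHS: 1.0 / 12.0,
    AgeUnit.WEEKS: 1.0 / 52.0,
    AgeUnit.DAYS: 1.0 / 365.25,
}


def age_in_years(value: Optional[float], unit: AgeUnit) -> Optional[float]:
    """Normalize an (age value, FAERS age code) pair to years; unknown unit -> None."""
    if value is None or unit is AgeUnit.UNKNOWN:
        return None
    return value * _AGE_FACTORS[unit]


@dataclass
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: RawDate = MISSING_DATE
    event_dt: RawDate = MISSING_DATE
    sex: Sex = Sex.UNKNOWN
    age_value: Optional[float] = None
    age_unit: AgeUnit = AgeUnit.UNKNOWN
    reporter_code: str = ""
    country: str = ""
    weight_kg: Optional[float] = None

    @property
    def age_years(self) -> Optional[float]:
        return age_in_years(self.age_value, self.age_unit)


@dataclass
class DrugRecord:
    primaryid: str
    drug_name: str = ""
    active_ingredient: str = ""
    role_code: RoleCode = RoleCode.UNKNOWN
    route: str = ""
    start_dt: RawDate = MISSING_DATE


@dataclass
class ReactionRecord:
    primaryid: str
    pt: str


@dataclass
class OutcomeRecord:
    primaryid: str
    outcome_code: str


@dataclass
class TherapyRecord:
    primaryid: str
    start_dt: RawDate = MISSING_DATE
    end_dt: RawDate = MISSING_DATE


@dataclass
class IndicationRecord:
    primaryid: str
    indi_pt: str = ""


@dataclass
class DeletedRecord:
    caseid: str


Record = Union[
    DemoRecord,
    DrugRecord,
    ReactionRecord,
    OutcomeRecord,
    TherapyRecord,
    IndicationRecord,
    DeletedRecord,
]


class TableKind(enum.Enum):
    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    OUTC = "OUTC"
    THER = "THER"
    INDI = "INDI"
    DELETED = "DELETED"


class MissingColumnError(ValueError):
    """A mandatory column is absent from a table header."""


def _norm_header(name: str) -> str:
    return name.strip().lower()


def _get(row: dict, *names: str, default: str = "") -> str:
    for name in names:
        if name in row and row[name] is not None:
            return row[name].strip()
    return default


def _to_float(text: str) -> Optional[float]:
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def _parse_sex(text: str) -> Sex:
    t = text.strip().upper()
    if t == "F":
        return Sex.F
    if t == "M":
        return Sex.M
    return Sex.UNKNOWN


def _parse_age_unit(text: str) -> AgeUnit:
    t = text.strip().upper()
    for unit in AgeUnit:
        if t == unit.value:
            return unit
    return AgeUnit.UNKNOWN


def _parse_role(text: str) -> RoleCode:
    t = text.strip().upper()
    for role in (RoleCode.PS, RoleCode.SS, RoleCode.C, RoleCode.I):
        if t == role.value:
            return role
    return RoleCode.UNKNOWN


# Column synonyms seen across FAERS quarters (e.g. ISR-era names).
_MANDATORY = {
    TableKind.DEMO: ("primaryid", "caseid"),
    TableKind.DRUG: ("primaryid",),
    TableKind.REAC: ("primaryid",),
    TableKind.OUTC: ("primaryid",),
    TableKind.THER: ("primaryid",),
    TableKind.INDI: ("primaryid",),
    TableKind.DELETED: (),
}


def _build_demo(row: dict) -> DemoRecord:
    return DemoRecord(
        primaryid=_get(row, "primaryid"),
        caseid=_get(row, "caseid"),
        fda_dt=parse_date(_get(row, "fda_dt")),
        event_dt=parse_date(_get(row, "event_dt")),
        sex=_parse_sex(_get(row, "sex", "gndr_cod")),
        age_value=_to_float(_get(row, "age")),
        age_unit=_parse_age_unit(_get(row, "age_cod")),
        reporter_code=_get(row, "occp_cod"),
        country=_get(row, "occr_country", "reporter_country"),
        weight_kg=_to_float(_get(row, "wt")),
    )


def _build_drug(row: dict) -> DrugRecord:
    return DrugRecord(
        primaryid=_get(row, "primaryid"),
        drug_name=_get(row, "drugname"),
        active_ingredient=_get(row, "prod_ai"),
        role_code=_parse_role(_get(row, "role_cod")),
        route=_get(row, "route"),
        start_dt=parse_date(_get(row, "start_dt")),
    )


def _build_reac(row: dict) -> ReactionRecord:
    return ReactionRecord(primaryid=_get(row, "primaryid"), pt=_get(row, "pt"))


def _build_outc(row: dict) -> OutcomeRecord:
    return OutcomeRecord(
        primaryid=_get(row, "primaryid"), outcome_code=_get(row, "outc_cod", "outc_code")
    )


def _build_ther(row: dict) -> TherapyRecord:
    return TherapyRecord(
        primaryid=_get(row, "primaryid"),
        start_dt=parse_date(_get(row, "start_dt")),
        end_dt=parse_date(_get(row, "end_dt")),
    )


def _build_indi(row: dict) -> IndicationRecord:
    return IndicationRecord(
        primaryid=_get(row, "primaryid"), indi_pt=_get(row, "indi_pt")
    )


def _build_deleted(row: dict) -> DeletedRecord:
    return DeletedRecord(caseid=_get(row, "caseid"))


_BUILDERS = {
    TableKind.DEMO: _build_demo,
    TableKind.DRUG: _build_drug,
    TableKind.REAC: _build_reac,
    TableKind.OUTC: _build_outc,
    TableKind.THER: _build_ther,
    TableKind.INDI: _build_indi,
    TableKind.DELETED: _build_deleted,
}


def read_table(
    path: Union[str, Path],
    kind: Union[TableKind, str],
    *,
    delimiter: str = DELIMITER,
    encoding: str = ENCODING,
) -> list:
    """Read one FAERS ASCII table into typed records.

    The header row defines column binding (case-insensitive). Unknown extra
    columns are ignored. Mandatory columns (primaryid; caseid for DEMO)
    missing from the header raise :class:`MissingColumnError`. Malformed data
    lines are skipped with a logged count; records are returned in file order.
    """
    kind = TableKind(kind) if not isinstance(kind, TableKind) else kind
    path = Path(path)
    build = _BUILDERS[kind]
    records: list = []
    skipped = 0
    with path.open("r", encoding=encoding, errors="replace", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row")
        columns = [_norm_header(c) for c in header]
        for col in _MANDATORY[kind]:
            if col not in columns:
                raise MissingColumnError(
                    f"{path}: mandatory column {col!r} missing from {kind.value} header"
                )
        if kind is TableKind.DELETED and "caseid" not in columns:
            raise MissingColumnError(f"{path}: DELETED table needs a caseid column")
        for lineno, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if len(fields) > len(columns):
                skipped += 1
                continue
            row = dict(zip(columns, fields))
            record = build(row)
            key = getattr(record, "primaryid", None) or getattr(record, "caseid", None)
            if not key:
                skipped += 1
                continue
            records.append(record)
    if skipped:
        logger.warning("%s: skipped %d unreadable line(s)", path, skipped)
    return records


# Writers emit the canonical modern column set; read_table(write_table(x))
# round-trips every parsed field.
_WRITE_COLUMNS = {
    TableKind.DEMO: [
        "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod",
        "occp_cod", "occr_country", "wt",
    ],
    TableKind.DRUG: ["primaryid", "drugname", "prod_ai", "role_cod", "route", "start_dt"],
    TableKind.REAC: ["primaryid", "pt"],
    TableKind.OUTC: ["primaryid", "outc_cod"],
    TableKind.THER: ["primaryid", "start_dt", "end_dt"],
    TableKind.INDI: ["primaryid", "indi_pt"],
    TableKind.DELETED: ["caseid"],
}


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _record_row(record: Record, kind: TableKind) -> list[str]:
    if kind is TableKind.DEMO:
        r: DemoRecord = record  # type: ignore[assignment]
        return [
            r.primaryid, r.caseid, r.fda_dt.text, r.event_dt.text,
            "" if r.sex is Sex.UNKNOWN else r.sex.value,
            _fmt_num(r.age_value),
            "" if r.age_unit is AgeUnit.UNKNOWN else r.age_unit.value,
            r.reporter_code, r.country, _fmt_num(r.weight_kg),
        ]
    if kind is TableKind.DRUG:
        d: DrugRecord = record  # type: ignore[assignment]
        return [
            d.primaryid, d.drug_name, d.active_ingredient,
            "" if d.role_code is RoleCode.UNKNOWN else d.role_code.value,
            d.route, d.start_dt.text,
        ]
    if kind is TableKind.REAC:
        return [record.primaryid, record.pt]  # type: ignore[union-attr]
    if kind is TableKind.OUTC:
        return [record.primaryid, record.outcome_code]  # type: ignore[union-attr]
    if kind is TableKind.THER:
        return [record.primaryid, record.start_dt.text, record.end_dt.text]  # type: ignore[union-attr]
    if kind is TableKind.INDI:
        return [record.primaryid, record.indi_pt]  # type: ignore[union-attr]
    return [record.caseid]  # type: ignore[union-attr]


def write_table(
    records: Iterable[Record],
    path: Union[str, Path],
    kind: Union[TableKind, str],
    *,
    delimiter: str = DELIMITER,
    encoding: str = ENCODING,
) -> Path:
    """Write records back to a ``$``-delimited ASCII table with header."""
    kind = TableKind(kind) if not isinstance(kind, TableKind) else kind
    path = Path(path)
    with path.open("w", encoding=encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(_WRITE_COLUMNS[kind])
        for record in records:
            writer.writerow(_record_row(record, kind))
    return path


# ---------------------------------------------------------------------------
# Drug lexicon and PT -> SOC mapping
# ---------------------------------------------------------------------------

_PUNCT = re.compile(r"[^a-z0-9 ]+")
_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold, strip punctuation to spaces and collapse whitespace."""
    lowered = name.strip().lower()
    lowered = _PUNCT.sub(" ", lowered)
    return _WS.sub(" ", lowered).strip()


@dataclass
class DrugLexicon:
    """Synonyms (and explicit exclusions) defining one drug cohort.

    Matching is exact on normalized names — auditable, no substring
    surprises — run against both DRUGNAME and PROD_AI. Exclusions let a
    combination product (e.g. "amoxicillin and clavulanate potassium") be
    kept out of the monotherapy cohort even though its name would otherwise
    be added as a synonym.
    """

    target_label: str
    synonyms: set[str] = field(default_factory=set)
    exclusions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.synonyms = {normalize_name(s) for s in self.synonyms if s.strip()}
        self.exclusions = {normalize_name(s) for s in self.exclusions if s.strip()}
        overlap = self.synonyms & self.exclusions
        if overlap:
            raise ValueError(f"lexicon {self.target_label!r}: names listed as both "
                             f"synonym and exclusion: {sorted(overlap)}")

    def matches(self, drug_name: str, active_ingredient: str = "") -> bool:
        names = {normalize_name(drug_name), normalize_name(active_ingredient)}
        names.discard("")
        if names & self.exclusions:
            return False
        return bool(names & self.synonyms)


def read_lexicon(path: Union[str, Path]) -> DrugLexicon:
    """Read a sectioned synonym file.

    Format: an optional ``[target] label`` line, then ``[synonyms]`` /
    ``[exclusions]`` section headers with one name per line; ``#`` comments
    and blank lines ignored.
    """
    path = Path(path)
    label = path.stem
    synonyms: set[str] = set()
    exclusions: set[str] = set()
    section = "synonyms"
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        low = line.lower()
        if low.startswith("[target]"):
            label = line[len("[target]"):].strip() or label
            continue
        if low == "[synonyms]":
            section = "synonyms"
            continue
        if low == "[exclusions]":
            section = "exclusions"
            continue
        (synonyms if section == "synonyms" else exclusions).add(line)
    return DrugLexicon(target_label=label, synonyms=synonyms, exclusions=exclusions)


@dataclass
class SocMapping:
    """Case-insensitive PT -> {SOC} lookup. A PT may map to several SOCs."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def lookup(self, pt: str) -> frozenset[str]:
        """SOCs for a PT; empty frozenset means unmapped (never an error)."""
        return self.entries.get(normalize_name(pt), frozenset())

    def __contains__(self, pt: str) -> bool:
        return normalize_name(pt) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_soc_mapping(path: Union[str, Path]) -> SocMapping:
    """Read a tab-separated PT<TAB>SOC file; duplicate PT rows merge SOC sets."""
    path = Path(path)
    accum: dict[str, set[str]] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2 or not parts[1].strip():
            raise ValueError(f"{path}:{lineno}: PT row with empty SOC")
        pt, soc = normalize_name(parts[0]), parts[1].strip()
        if not pt:
            raise ValueError(f"{path}:{lineno}: empty PT")
        accum.setdefault(pt, set()).add(soc)
    return SocMapping(entries={pt: frozenset(socs) for pt, socs in accum.items()})
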