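"""Reading, writing and assembling FAERS-dialect report tables.

A FAERS quarterly extract is a set of "$"-separated ASCII tables sharing
a report key (``primaryid``, grouped into cases by ``caseid`` with a
``caseversion`` for follow-ups): DEMO (demographics, one row per report
version), DRUG (one row per drug mention), REAC (one row per MedDRA
preferred term), OUTC (seriousness outcomes), INDI (indications) and
THER (therapy dates per drug).  This module loads those tables into a
:class:`RawTableSet`, round-trips them losslessly, and assembles them
into the report-level :class:`Report` data model used by the rest of the
pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .dates import PartialDate, parse_partial_date

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "FAERS_ASCII",
    "RawTableSet",
    "SchemaError",
    "DrugRecord",
    "EventRecord",
    "Report",
    "TABLE_NAMES",
    "age_to_class",
    "age_years_from_code",
    "read_table_set",
    "write_table_set",
    "assemble_reports",
    "write_report_store",
    "AGE_CLASSES",
]

TABLE_NAMES = ("demo", "drug", "reac", "outc", "indi", "ther")

#: report-key column present in every table
KEY = "primaryid"

_SCHEMAS: Dict[str, Sequence[str]] = {
    "demo": (
        "primaryid",
        "caseid",
        "caseversion",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "reporter_country",
        "fda_dt",
    ),
    "drug": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "caseid", "pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "indi": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
}


@dataclass(frozen=True)
class Dialect:
    """Delimiter + per-table column layout of a report-table set."""

    sep: str = "$"
    schemas: Mapping[str, Sequence[str]] = field(default_factory=lambda: dict(_SCHEMAS))

    def columns(self, table: str) -> Sequence[str]:
        return self.schemas[table]


#: the FAERS ASCII convention: "$"-separated, no quoting
FAERS_ASCII = Dialect()

#: comma-separated variant accepted for hand-written fixtures
CSV_DIALECT = Dialect(sep=",")


class SchemaError(ValueError):
    """A table file does not match the declared dialect schema."""


@dataclass
class RawTableSet:
    """The six report tables of one extract, plus a load report."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    source_quarter: str = ""
    load_report: Dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def orphan_counts(self) -> Dict[str, int]:
        """Rows in child tables whose key is absent from DEMO."""
        keys = set(self.demo[KEY])
        return {
            name: int((~self.table(name)[KEY].isin(keys)).sum())
            for name in TABLE_NAMES
            if name != "demo"
        }


def _read_one(path: Path, table: str, dialect: Dialect) -> pd.DataFrame:
    expected = list(dialect.columns(table))
    try:
        df = pd.read_csv(
            path,
            sep=dialect.sep,
            dtype=str,
            keep_default_na=False,
            engine="python",
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise SchemaError(f"{path}: cannot parse as {dialect.sep!r}-delimited: {exc}") from exc
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: unknown column layout for table {table!r}: "
            f"got {list(df.columns)}, expected {expected} "
            f"(first data line: {df.iloc[0].tolist() if len(df) else 'empty'})"
        )
    return df


def read_table_set(
    paths: Mapping[str, str | Path],
    dialect: Dialect = FAERS_ASCII,
    source_quarter: str = "",
) -> RawTableSet:
    """Load one extract from per-table file paths.

    Rows lacking the report key are dropped and counted in
    ``load_report`` as ``dropped_missing_key_<table>``.
    """
    missing = [t for t in TABLE_NAMES if t not in paths]
    if missing:
        raise ValueError(f"missing table paths: {missing}")
    frames: Dict[str, pd.DataFrame] = {}
    load_report: Dict[str, int] = {}
    for name in TABLE_NAMES:
        df = _read_one(Path(paths[name]), name, dialect)
        bad = df[KEY].astype(str).str.strip() == ""
        if bad.any():
            load_report[f"dropped_missing_key_{name}"] = int(bad.sum())
            df = df.loc[~bad].reset_index(drop=True)
        frames[name] = df
    return RawTableSet(**frames, source_quarter=source_quarter, load_report=load_report)


def write_table_set(
    tables: RawTableSet,
    directory: str | Path,
    dialect: Dialect = FAERS_ASCII,
    prefix: str = "",
) -> Dict[str, Path]:
    """Write the six tables back out; inverse of :func:`read_table_set`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}
    for name in TABLE_NAMES:
        path = directory / f"{prefix}{name}.txt"
        tables.table(name).to_csv(path, sep=dialect.sep, index=False)
        out[name] = path
    return out


# ---------------------------------------------------------------------------
# report-level data model
# ---------------------------------------------------------------------------

AGE_CLASSES = ("<=25", "26-50", "51-75", ">=76", "unknown")

ROLE_CODES = {
    "PS": "primary suspect",
    "SS": "secondary suspect",
    "C": "concomitant",
    "I": "interacting",
}

OUTCOME_CODES = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "RI": "required intervention",
    "CA": "congenital anomaly",
    "OT": "other serious",
}

#: occupation codes counted as health-professional reporters
_HCP_CODES = {"MD", "PH", "RN", "OT", "HP"}
_NON_HCP_CODES = {"CN", "LW"}

#: multipliers from FAERS age-unit codes to years
_AGE_UNIT_YEARS = {
    "YR": 1.0,
    "": 1.0,  # blank unit: FAERS convention is years
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


def age_years_from_code(age: object, age_cod: object) -> Optional[float]:
    """Normalize a (value, unit-code) age pair to years; else missing."""
    s = str(age).strip() if age is not None else ""
    if not s:
        return None
    try:
        value = float(s)
    except ValueError:
        return None
    unit = str(age_cod).strip().upper() if age_cod is not None else ""
    factor = _AGE_UNIT_YEARS.get(unit)
    if factor is None or value < 0:
        return None
    return value * factor


def age_to_class(age_years: Optional[float]) -> str:
    """Map age in years to the four study age classes (or unknown).

    Bins follow the literal labels <=25 / 26-50 / 51-75 / >=76 with
    inclusive printed bounds; fractional ages fall in the bin of the
    surrounding integer range.
    """
    if age_years is None or not (0 <= age_years <= 150):
        return "unknown"
    if age_years <= 25:
        return "<=25"
    if age_years <= 50:
        return "26-50"
    if age_years <= 75:
        return "51-75"
    return ">=76"


def _sex_label(code: object) -> str:
    c = str(code).strip().upper()
    return {"F": "female", "M": "male"}.get(c, "unknown")


def _reporter_label(code: object) -> str:
    c = str(code).strip().upper()
    if c in _HCP_CODES:
        return "health professional"
    if c in _NON_HCP_CODES:
        return "nonhealth professional"
    return "unknown"


@dataclass
class DrugRecord:
    """One drug mention within a report."""

    verbatim_name: str
    role: str
    inn: Optional[str] = None
    atc_codes: frozenset = frozenset()
    therapy_start: Optional[PartialDate] = None
    therapy_end: Optional[PartialDate] = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES.values():
            raise ValueError(f"unknown drug role {self.role!r}")


@dataclass
class EventRecord:
    """One MedDRA-coded adverse event within a report."""

    preferred_term: str
    onset_date: Optional[PartialDate] = None

    def __post_init__(self) -> None:
        if not self.preferred_term.strip():
            raise ValueError("preferred_term must be nonempty")


@dataclass
class Report:
    """One safety-report version with its linked drug and event lines."""

    report_id: str
    case_id: str
    version_seq: int
    age_years: Optional[float]
    sex: str
    reporter_type: str
    country: str
    reporting_year: Optional[int]
    outcome: frozenset
    drugs: List[DrugRecord] = field(default_factory=list)
    events: List[EventRecord] = field(default_factory=list)

    @property
    def serious(self) -> bool:
        """A report is serious iff at least one outcome was recorded."""
        return len(self.outcome) > 0

    @property
    def age_class(self) -> str:
        return age_to_class(self.age_years)

    def earliest_onset(self, full_precision_only: bool = False) -> Optional[PartialDate]:
        dates = [e.onset_date for e in self.events if e.onset_date is not None]
        if full_precision_only:
            dates = [d for d in dates if d.is_full]
        return min(dates) if dates else None


def assemble_reports(tables: RawTableSet) -> List[Report]:
    """Group the raw tables into one :class:`Report` per report key.

    Duplicate DEMO rows for the same key keep the first row (conflicts
    are logged).  Therapy dates are joined to drug lines on the drug
    sequence number; the report-level event date is attached to every
    event line (REAC carries no per-event date in this dialect).
    """
    demo = tables.demo
    dup = demo.duplicated(KEY, keep="first")
    if dup.any():
        logger.warning("%d conflicting DEMO rows dropped (kept first per key)", dup.sum())
        demo = demo.loc[~dup]

    ther_idx: Dict[tuple, pd.Series] = {}
    for _, row in tables.ther.iterrows():
        ther_idx.setdefault((row[KEY], str(row["dsg_drug_seq"])), row)

    drugs_by_key: Dict[str, List[DrugRecord]] = {}
    for _, row in tables.drug.iterrows():
        role = ROLE_CODES.get(str(row["role_cod"]).strip().upper())
        if role is None:
            logger.warning("unknown role code %r; treated as concomitant", row["role_cod"])
            role = "concomitant"
        ther = ther_idx.get((row[KEY], str(row["drug_seq"])))
        drugs_by_key.setdefault(row[KEY], []).append(
            DrugRecord(
                verbatim_name=str(row["drugname"]),
                role=role,
                therapy_start=parse_partial_date(ther["start_dt"]) if ther is not None else None,
                therapy_end=parse_partial_date(ther["end_dt"]) if ther is not None else None,
            )
        )

    events_by_key: Dict[str, List[str]] = {}
    for _, row in tables.reac.iterrows():
        pt = str(row["pt"]).strip()
        if pt:
            events_by_key.setdefault(row[KEY], []).append(pt)

    outcome_by_key: Dict[str, set] = {}
    for _, row in tables.outc.iterrows():
        label = OUTCOME_CODES.get(str(row["outc_cod"]).strip().upper())
        if label:
            outcome_by_key.setdefault(row[KEY], set()).add(label)

    reports: List[Report] = []
    for _, row in demo.iterrows():
        key = row[KEY]
        onset = parse_partial_date(row["event_dt"])
        fda = parse_partial_date(row["fda_dt"])
        try:
            version = int(str(row["caseversion"]).strip() or 1)
        except ValueError:
            version = 1
        country = str(row["reporter_country"]).strip() or "unknown"
        reports.append(
            Report(
                report_id=str(key),
                case_id=str(row["caseid"]),
                version_seq=version,
                age_years=age_years_from_code(row["age"], row["age_cod"]),
                sex=_sex_label(row["sex"]),
                reporter_type=_reporter_label(row["occp_cod"]),
                country=country,
                reporting_year=fda.year if fda is not None else None,
                outcome=frozenset(outcome_by_key.get(key, set())),
                drugs=drugs_by_key.get(key, []),
                events=[EventRecord(pt, onset) for pt in events_by_key.get(key, [])],
            )
        )
    return reports


def write_report_store(reports: Iterable[Report], directory: str | Path, sep: str = "\t") -> Dict[str, Path]:
    """Write the normalized store: one delimited file per entity.

    ``reports.tsv`` has one row per report, ``drugs.tsv`` and
    ``events.tsv`` one row per drug/event line keyed by report_id.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rep_rows, drug_rows, ev_rows = [], [], []
    for r in reports:
        rep_rows.append(
            {
                "report_id": r.report_id,
                "case_id": r.case_id,
                "version_seq": r.version_seq,
                "age_years": "" if r.age_years is None else r.age_years,
                "age_class": r.age_class,
                "sex": r.sex,
                "reporter_type": r.reporter_type,
                "country": r.country,
                "reporting_year": "" if r.reporting_year is None else r.reporting_year,
                "serious": int(r.serious),
                "outcome": ";".join(sorted(r.outcome)),
            }
        )
        for d in r.drugs:
            drug_rows.append(
                {
                    "report_id": r.report_id,
                    "verbatim_name": d.verbatim_name,
                    "inn": d.inn or "",
                    "atc_codes": ";".join(sorted(d.atc_codes)),
                    "role": d.role,
                    "therapy_start": d.therapy_start.isoformat() if d.therapy_start else "",
                    "therapy_end": d.therapy_end.isoformat() if d.therapy_end else "",
                }
            )
        for e in r.events:
            ev_rows.append(
                {
                    "report_id": r.report_id,
                    "preferred_term": e.preferred_term,
                    "onset_date": e.onset_date.isoformat() if e.onset_date else "",
                }
            )
    paths = {}
    for name, rows in (("reports", rep_rows), ("drugs", drug_rows), ("events", ev_rows)):
        path = directory / f"{name}.tsv"
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
        paths[name] = path
    return paths
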