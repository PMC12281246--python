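"""Reading FAERS-style quarterly ASCII tables and assembling per-case safety reports.

A FAERS quarter is four ``$``-separated ASCII tables — DEMO (one row per
report version, with demographics), DRUG (one row per drug entry), REAC
(one row per adverse-event preferred term, PT) and INDI (one row per drug
indication PT).  ``primaryid`` identifies a report *version*; ``caseid``
identifies the underlying case, which may accumulate several versions as
follow-up information arrives.  The functions here parse the tables,
join them into :class:`CaseReport` records and collapse versions to one
report per case (latest version wins).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "INDI")

#: column carrying the event / indication PT code in each table
PT_COLUMN = {"REAC": "pt", "INDI": "indi_pt"}

SEX_CODES = {"F": "female", "M": "male"}
HEALTH_PROFESSIONAL_CODES = {"MD", "PH", "OT", "HP"}
NON_HEALTH_PROFESSIONAL_CODES = {"CN", "LW"}
ROLE_CODES = ("PS", "SS", "C", "I")
REGIONS = ("Europe", "NorthAmerica", "Asia", "Oceania", "SouthAmerica", "Africa")

#: per-unit factor converting a FAERS (age, age_cod) pair to years;
#: DEC encodes decades of life, not a decimal year count
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
}


class FaersFormatError(ValueError):
    """A quarter file is structurally unusable (missing file or key columns)."""


@dataclass(frozen=True)
class Dialect:
    """Field-separator convention of the quarter files.

    FAERS ASCII uses a bare ``$`` with no quoting; tab is convenient for
    hand-written fixtures.
    """

    sep: str = "$"

    def __post_init__(self) -> None:
        if len(self.sep) != 1:
            raise ValueError("separator must be a single character")


@dataclass(frozen=True)
class RawRecord:
    """One data row of one quarter table, keyed by report version and case."""

    table_name: str
    primary_id: str
    case_id: str
    payload: dict[str, str]

    def __post_init__(self) -> None:
        if self.table_name not in TABLE_NAMES:
            raise ValueError(f"unknown table {self.table_name!r}")
        if not self.primary_id or not self.case_id:
            raise ValueError("primary_id and case_id must be non-empty")


@dataclass(frozen=True)
class RejectedRow:
    """A data row whose field count disagrees with the header."""

    table_name: str
    line_number: int
    n_fields: int
    n_expected: int
    raw: str


@dataclass
class ParseResult:
    records: list[RawRecord]
    rejects: list[RejectedRow]

    def table(self, name: str) -> list[RawRecord]:
        return [r for r in self.records if r.table_name == name]


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report: verbatim name, FAERS role code, mapped ATC."""

    raw_name: str
    role: str
    atc_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"role must be one of {ROLE_CODES}, got {self.role!r}")
        if self.atc_code is not None and not re.fullmatch(r"[A-Z]\d\d[A-Z]{2}\d\d", self.atc_code):
            raise ValueError(f"malformed ATC code {self.atc_code!r}")


@dataclass(frozen=True)
class CaseReport:
    """One safety report (a single version of a case) after table joins.

    ``event_pts`` and ``indication_pts`` hold MedDRA PT codes as strings.
    A report with no adverse event or no drug entry is invalid and is
    filtered out during assembly, not constructed.
    """

    case_id: str
    primary_id: str
    receipt_sequence: int
    sex: str
    age_years: Optional[float]
    reporter: str
    region: str
    drugs: tuple[DrugEntry, ...]
    event_pts: frozenset[str]
    indication_pts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.event_pts:
            raise ValueError("a report with no adverse event is invalid")
        if not self.drugs:
            raise ValueError("a report with no drug entry is invalid")
        if self.age_years is not None and not (0 <= self.age_years < 150):
            raise ValueError(f"implausible age {self.age_years!r}")


@dataclass
class AssemblyResult:
    cases: list[CaseReport]
    n_demo_rows: int
    n_no_event: int  # DEMO rows excluded because the REAC join was empty
    n_no_drug: int  # DEMO rows excluded because the DRUG join was empty
    n_orphan_rows: int  # DRUG/REAC/INDI rows whose primary_id has no DEMO row


def _read_table(path: str | Path, table_name: str, dialect: Dialect) -> ParseResult:
    path = Path(path)
    if not path.exists():
        raise FaersFormatError(f"{table_name} file not found: {path}")
    records: list[RawRecord] = []
    rejects: list[RejectedRow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.sep, quoting=csv.QUOTE_NONE)
        try:
            header = next(reader)
        except StopIteration:
            raise FaersFormatError(f"{table_name} file {path} is empty") from None
        header = [h.strip().lower() for h in header]
        for key in ("primaryid", "caseid"):
            if key not in header:
                raise FaersFormatError(f"{table_name} header lacks required column {key!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                rejects.append(
                    RejectedRow(table_name, lineno, len(row), len(header), dialect.sep.join(row))
                )
                continue
            payload = dict(zip(header, row))
            pid, cid = payload["primaryid"].strip(), payload["caseid"].strip()
            if not pid or not cid:
                rejects.append(RejectedRow(table_name, lineno, len(row), len(header), dialect.sep.join(row)))
                continue
            records.append(RawRecord(table_name, pid, cid, payload))
    if rejects:
        logger.warning("%s: %d malformed row(s) routed to rejects", table_name, len(rejects))
    return ParseResult(records, rejects)


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    indi_path: str | Path,
    dialect: Dialect | None = None,
) -> ParseResult:
    """Parse the four quarter tables into tagged raw records.

    Rows whose field count disagrees with the header are collected in
    ``ParseResult.rejects`` (parsing continues); a missing file or a header
    lacking ``primaryid``/``caseid`` raises :class:`FaersFormatError`.
    """
    dialect = dialect or Dialect()
    records: list[RawRecord] = []
    rejects: list[RejectedRow] = []
    for path, name in zip((demo_path, drug_path, reac_path, indi_path), TABLE_NAMES):
        part = _read_table(path, name, dialect)
        records.extend(part.records)
        rejects.extend(part.rejects)
    return ParseResult(records, rejects)


def parse_age(value: str, unit: str) -> Optional[float]:
    """Convert a FAERS (age, age_cod) pair to years; unparseable → ``None``.

    An empty unit is treated as years.  Results outside [0, 150) are
    discarded as recording errors.
    """
    value = (value or "").strip()
    if not value:
        return None
    try:
        x = float(value)
    except ValueError:
        return None
    factor = AGE_UNIT_TO_YEARS.get((unit or "").strip().upper() or "YR")
    if factor is None:
        return None
    years = x * factor
    if not (0 <= years < 150):
        return None
    return years


def decode_sex(code: str) -> str:
    return SEX_CODES.get((code or "").strip().upper(), "unknown")


def decode_reporter(occp_cod: str) -> str:
    code = (occp_cod or "").strip().upper()
    if code in HEALTH_PROFESSIONAL_CODES:
        return "health_professional"
    if code in NON_HEALTH_PROFESSIONAL_CODES:
        return "non_health_professional"
    return "unknown"


def decode_region(country: str, country_regions: Mapping[str, str]) -> str:
    return country_regions.get((country or "").strip().upper(), "unknown")


def assemble_cases(
    records: Iterable[RawRecord],
    country_regions: Mapping[str, str] | None = None,
    normalize_drug: Callable[[str], Optional[str]] | None = None,
) -> AssemblyResult:
    """Join DEMO/DRUG/REAC/INDI rows on ``primaryid`` into one report each.

    One :class:`CaseReport` is produced per DEMO row that has at least one
    REAC and one DRUG row; the excluded remainder is counted, and DRUG /
    REAC / INDI rows with no DEMO row are counted as orphans.
    ``normalize_drug`` (typically :func:`pvscreen.vocabulary.normalize_drug`
    bound to a dictionary) maps verbatim drug names to ATC codes.
    """
    if country_regions is None:
        from .vocabulary import default_country_regions

        country_regions = default_country_regions()

    demo: dict[str, RawRecord] = {}
    drugs: dict[str, list[DrugEntry]] = {}
    events: dict[str, set[str]] = {}
    indications: dict[str, set[str]] = {}
    n_demo = n_orphans = 0

    records = list(records)
    demo_ids = {r.primary_id for r in records if r.table_name == "DEMO"}
    if not demo_ids:
        raise FaersFormatError("no DEMO rows: nothing to assemble")

    for rec in records:
        pid = rec.primary_id
        if rec.table_name == "DEMO":
            n_demo += 1
            demo[pid] = rec
            continue
        if pid not in demo_ids:
            n_orphans += 1
            continue
        if rec.table_name == "DRUG":
            role = rec.payload.get("role_cod", "").strip().upper()
            if role not in ROLE_CODES:
                role = "C"
            name = rec.payload.get("drugname", "").strip()
            atc = normalize_drug(name) if normalize_drug else None
            drugs.setdefault(pid, []).append(DrugEntry(name, role, atc))
        elif rec.table_name in PT_COLUMN:
            pt = rec.payload.get(PT_COLUMN[rec.table_name], "").strip()
            if pt:
                target = events if rec.table_name == "REAC" else indications
                target.setdefault(pid, set()).add(pt)

    cases: list[CaseReport] = []
    n_no_event = n_no_drug = 0
    for pid, rec in demo.items():
        if pid not in events:
            n_no_event += 1
            continue
        if pid not in drugs:
            n_no_drug += 1
            continue
        p = rec.payload
        try:
            seq = int(float(p.get("caseversion", "") or 0))
        except ValueError:
            seq = 0
        cases.append(
            CaseReport(
                case_id=rec.case_id,
                primary_id=pid,
                receipt_sequence=seq,
                sex=decode_sex(p.get("sex", "")),
                age_years=parse_age(p.get("age", ""), p.get("age_cod", "")),
                reporter=decode_reporter(p.get("occp_cod", "")),
                region=decode_region(p.get("occr_country", ""), country_regions),
                drugs=tuple(drugs[pid]),
                event_pts=frozenset(events[pid]),
                indication_pts=frozenset(indications.get(pid, set())),
            )
        )
    if n_no_event or n_no_drug or n_orphans:
        logger.info(
            "assembly: %d no-event, %d no-drug DEMO rows excluded; %d orphan rows",
            n_no_event, n_no_drug, n_orphans,
        )
    return AssemblyResult(cases, n_demo, n_no_event, n_no_drug, n_orphans)


def deduplicate(cases: Sequence[CaseReport]) -> list[CaseReport]:
    """Keep the latest report version per case.

    Within a ``case_id`` the report with the highest ``receipt_sequence``
    wins; ties break on the lexicographically highest ``primary_id``.
    Output is sorted by ``case_id``, so the operation is deterministic and
    idempotent.
    """
    best: dict[str, CaseReport] = {}
    for case in cases:
        cur = best.get(case.case_id)
        if cur is None or (case.receipt_sequence, case.primary_id) > (cur.receipt_sequence, cur.primary_id):
            best[case.case_id] = case
    out = [best[k] for k in sorted(best)]
    removed = len(cases) - len(out)
    if removed:
        logger.info("deduplication removed %d superseded report version(s)", removed)
    return out


# ---------------------------------------------------------------------------
# canonical case table (TSV, one row per case, ';'-joined list columns)

_LIST_SEP = ";"
_CASE_COLUMNS = [
    "case_id", "primary_id", "receipt_sequence", "sex", "age_years", "reporter",
    "region", "drug_names", "drug_roles", "drug_atcs", "event_pts", "indication_pts",
]


def write_cases(cases: Sequence[CaseReport], path: str | Path) -> None:
    rows = []
    for c in cases:
        rows.append({
            "case_id": c.case_id,
            "primary_id": c.primary_id,
            "receipt_sequence": c.receipt_sequence,
            "sex": c.sex,
            "age_years": "" if c.age_years is None else repr(c.age_years),
            "reporter": c.reporter,
            "region": c.region,
            "drug_names": _LIST_SEP.join(d.raw_name for d in c.drugs),
            "drug_roles": _LIST_SEP.join(d.role for d in c.drugs),
            "drug_atcs": _LIST_SEP.join(d.atc_code or "" for d in c.drugs),
            "event_pts": _LIST_SEP.join(sorted(c.event_pts)),
            "indication_pts": _LIST_SEP.join(sorted(c.indication_pts)),
        })
    pd.DataFrame(rows, columns=_CASE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cases(path: str | Path) -> list[CaseReport]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cases = []
    for row in df.itertuples(index=False):
        names = row.drug_names.split(_LIST_SEP) if row.drug_names else []
        roles = row.drug_roles.split(_LIST_SEP) if row.drug_roles else []
        atcs = row.drug_atcs.split(_LIST_SEP) if row.drug_atcs else []
        cases.append(
            CaseReport(
                case_id=row.case_id,
                primary_id=row.primary_id,
                receipt_sequence=int(row.receipt_sequence),
                sex=row.sex,
                age_years=float(row.age_years) if row.age_years else None,
                reporter=row.reporter,
                region=row.region,
                drugs=tuple(
                    DrugEntry(n, r, a or None) for n, r, a in zip(names, roles, atcs)
                ),
                event_pts=frozenset(row.event_pts.split(_LIST_SEP)) if row.event_pts else frozenset(),
                indication_pts=frozenset(row.indication_pts.split(_LIST_SEP)) if row.indication_pts else frozenset(),
            )
        )
    return cases
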