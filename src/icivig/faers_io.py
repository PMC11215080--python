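"""Reading FAERS-style quarterly ASCII tables and the package fixture format.

FAERS quarters ship as '$'-delimited text with a header row (DEMO, DRUG, REAC,
OUTC, THER, INDI). Column names changed around 2014, so each logical field is
resolved through an alias table. The fixture format is JSON Lines: one
self-contained report object per line, ordered by PRIMARYID, which round-trips
exactly and is convenient for tests and small cohorts.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cohort import CaseReport, DrugRecord, ReactionRecord, OUTCOME_CODES, ROLE_CODES

logger = logging.getLogger(__name__)

AGE_UNITS_PER_YEAR = {
    "YR": 1.0,
    "DEC": 0.1,       # decades: multiply by 10
    "MON": 12.0,
    "WK": 52.18,
    "DY": 365.25,
    "HR": 8766.0,
}

# Logical field -> accepted header names (pre- and post-2014 dialects).
_ALIASES: dict[str, tuple[str, ...]] = {
    "primaryid": ("primaryid", "isr"),
    "caseid": ("caseid", "case"),
    "fda_dt": ("fda_dt",),
    "age": ("age",),
    "age_cod": ("age_cod",),
    "sex": ("sex", "gndr_cod"),
    "occr_country": ("occr_country", "reporter_country"),
    "occp_cod": ("occp_cod",),
    "drugname": ("drugname", "drug_name"),
    "role_cod": ("role_cod",),
    "drug_seq": ("drug_seq", "dsg_drug_seq"),
    "pt": ("pt",),
    "event_dt": ("event_dt",),
    "outc_cod": ("outc_cod", "outc_code"),
    "start_dt": ("start_dt",),
    "indi_pt": ("indi_pt",),
}


class FaersFormatError(ValueError):
    """Fatal structural problem in a FAERS table (missing file or column)."""


@dataclass(slots=True)
class RawReportRow:
    primary_id: str
    case_id: str
    fda_receipt_date: datetime.date | None
    date_imprecise: bool = False
    age_value: float | None = None
    age_unit: str | None = None
    sex: str | None = None
    country: str | None = None
    reporter_type: str | None = None

    @property
    def age_years(self) -> float | None:
        if self.age_value is None:
            return None
        unit = self.age_unit or "YR"
        per_year = AGE_UNITS_PER_YEAR.get(unit)
        if per_year is None:
            return None
        return self.age_value / per_year


@dataclass(slots=True)
class OutcomeRecord:
    primary_id: str
    outcome_code: str


@dataclass(slots=True)
class IndicationRecord:
    primary_id: str
    indication_term: str


@dataclass
class FaersTables:
    """Parsed raw tables plus per-table skip accounting."""

    demo: list[RawReportRow] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReactionRecord] = field(default_factory=list)
    outc: list[OutcomeRecord] = field(default_factory=list)
    ther: list[dict] = field(default_factory=list)
    indi: list[IndicationRecord] = field(default_factory=list)
    skipped: dict[str, int] = field(default_factory=dict)
    total_lines: dict[str, int] = field(default_factory=dict)


def parse_faers_date(raw: str | None) -> tuple[datetime.date | None, bool]:
    """Parse YYYYMMDD; partial dates complete to the first day/month.

    Returns (date, imprecise). Unparseable input gives (None, False).
    """
    if raw is None:
        return None, False
    raw = raw.strip()
    if not raw.isdigit():
        return None, False
    try:
        if len(raw) == 8:
            return datetime.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8])), False
        if len(raw) == 6:
            return datetime.date(int(raw[:4]), int(raw[4:6]), 1), True
        if len(raw) == 4:
            return datetime.date(int(raw), 1, 1), True
    except ValueError:
        return None, False
    return None, False


def _read_delimited(path: str | Path, table: str) -> tuple[list[str], list[list[str]]]:
    p = Path(path)
    if not p.exists():
        raise FaersFormatError(f"{table} table not found: {p}")
    with open(p, "r", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FaersFormatError(f"{table} table is empty (no header): {p}")
    header = [h.strip().lower() for h in lines[0].split("$")]
    rows = [line.split("$") for line in lines[1:] if line.strip()]
    return header, rows


def _column_map(header: list[str], table: str, required: Sequence[str]) -> dict[str, int]:
    cols: dict[str, int] = {}
    for logical, names in _ALIASES.items():
        for name in names:
            if name in header:
                cols[logical] = header.index(name)
                break
    for logical in required:
        if logical not in cols:
            raise FaersFormatError(
                f"{table} header lacks required field '{logical}' "
                f"(accepted names: {', '.join(_ALIASES[logical])})"
            )
    return cols


def _get(row: list[str], cols: Mapping[str, int], logical: str) -> str | None:
    idx = cols.get(logical)
    if idx is None or idx >= len(row):
        return None
    value = row[idx].strip()
    return value or None


def read_faers_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path | None = None,
    ther_path: str | Path | None = None,
    indi_path: str | Path | None = None,
) -> FaersTables:
    """Read the quarterly ASCII tables into raw records.

    Malformed lines (bad vocabulary codes, unparseable mandatory fields) are
    skipped and counted per table, never fatal; a missing file or a header
    lacking a required field is fatal.
    """
    out = FaersTables()

    header, rows = _read_delimited(demo_path, "DEMO")
    cols = _column_map(header, "DEMO", ["primaryid", "caseid", "fda_dt"])
    out.total_lines["DEMO"] = len(rows)
    skipped = 0
    for row in rows:
        pid = _get(row, cols, "primaryid")
        cid = _get(row, cols, "caseid")
        if not pid or not cid:
            skipped += 1
            continue
        fda_dt, imprecise = parse_faers_date(_get(row, cols, "fda_dt"))
        age_raw = _get(row, cols, "age")
        try:
            age_value = float(age_raw) if age_raw is not None else None
        except ValueError:
            age_value = None
        age_unit = _get(row, cols, "age_cod")
        if age_unit is not None and age_unit.upper() not in AGE_UNITS_PER_YEAR:
            age_value, age_unit = None, None
        out.demo.append(
            RawReportRow(
                primary_id=pid,
                case_id=cid,
                fda_receipt_date=fda_dt,
                date_imprecise=imprecise,
                age_value=age_value,
                age_unit=age_unit.upper() if age_unit else None,
                sex=_get(row, cols, "sex"),
                country=_get(row, cols, "occr_country"),
                reporter_type=_get(row, cols, "occp_cod"),
            )
        )
    out.skipped["DEMO"] = skipped

    header, rows = _read_delimited(drug_path, "DRUG")
    cols = _column_map(header, "DRUG", ["primaryid", "drugname", "role_cod"])
    out.total_lines["DRUG"] = len(rows)
    skipped = 0
    drug_seq: dict[tuple[str, str], DrugRecord] = {}
    for row in rows:
        pid = _get(row, cols, "primaryid")
        name = _get(row, cols, "drugname")
        role = (_get(row, cols, "role_cod") or "").upper()
        if not pid or not name or role not in ROLE_CODES:
            skipped += 1
            continue
        rec = DrugRecord(primary_id=pid, drug_name_raw=name, role_code=role)
        out.drug.append(rec)
        seq = _get(row, cols, "drug_seq")
        if seq is not None:
            drug_seq[(pid, seq)] = rec
    out.skipped["DRUG"] = skipped

    header, rows = _read_delimited(reac_path, "REAC")
    cols = _column_map(header, "REAC", ["primaryid", "pt"])
    out.total_lines["REAC"] = len(rows)
    skipped = 0
    for row in rows:
        pid = _get(row, cols, "primaryid")
        pt = _get(row, cols, "pt")
        if not pid or not pt:
            skipped += 1
            continue
        onset, imprecise = parse_faers_date(_get(row, cols, "event_dt"))
        out.reac.append(
            ReactionRecord(
                primary_id=pid, pt=pt, event_onset_date=onset, onset_imprecise=imprecise
            )
        )
    out.skipped["REAC"] = skipped

    if outc_path is not None:
        header, rows = _read_delimited(outc_path, "OUTC")
        cols = _column_map(header, "OUTC", ["primaryid", "outc_cod"])
        out.total_lines["OUTC"] = len(rows)
        skipped = 0
        for row in rows:
            pid = _get(row, cols, "primaryid")
            code = (_get(row, cols, "outc_cod") or "").upper()
            if not pid or code not in OUTCOME_CODES:
                skipped += 1
                continue
            out.outc.append(OutcomeRecord(primary_id=pid, outcome_code=code))
        out.skipped["OUTC"] = skipped

    if ther_path is not None:
        header, rows = _read_delimited(ther_path, "THER")
        cols = _column_map(header, "THER", ["primaryid", "start_dt"])
        out.total_lines["THER"] = len(rows)
        skipped = 0
        for row in rows:
            pid = _get(row, cols, "primaryid")
            start, imprecise = parse_faers_date(_get(row, cols, "start_dt"))
            if not pid or start is None:
                skipped += 1
                continue
            seq = _get(row, cols, "drug_seq")
            out.ther.append(
                {"primary_id": pid, "drug_seq": seq, "start_date": start,
                 "imprecise": imprecise}
            )
            rec = drug_seq.get((pid, seq)) if seq is not None else None
            if rec is not None and rec.therapy_start_date is None:
                rec.therapy_start_date = start
                rec.start_imprecise = imprecise
        out.skipped["THER"] = skipped

    if indi_path is not None:
        header, rows = _read_delimited(indi_path, "INDI")
        cols = _column_map(header, "INDI", ["primaryid", "indi_pt"])
        out.total_lines["INDI"] = len(rows)
        skipped = 0
        for row in rows:
            pid = _get(row, cols, "primaryid")
            term = _get(row, cols, "indi_pt")
            if not pid or not term:
                skipped += 1
                continue
            out.indi.append(IndicationRecord(primary_id=pid, indication_term=term))
        out.skipped["INDI"] = skipped

    for table, n in out.skipped.items():
        if n:
            logger.info("read_faers_tables: %s skipped %d malformed line(s)", table, n)
    return out


def assemble_reports(tables: FaersTables) -> list[CaseReport]:
    """Join the raw tables by PRIMARYID into self-contained case reports.

    Demographic rows without a parseable FDA receipt date cannot enter the
    study-window logic and are dropped (counted in ``skipped['DEMO_NO_DATE']``).
    """
    reports: dict[str, CaseReport] = {}
    no_date = 0
    for row in tables.demo:
        if row.fda_receipt_date is None:
            no_date += 1
            continue
        reports[row.primary_id] = CaseReport(
            primary_id=row.primary_id,
            case_id=row.case_id,
            fda_receipt_date=row.fda_receipt_date,
            age_years=row.age_years,
            sex=row.sex,
            country=row.country,
            reporter_type=row.reporter_type,
        )
    tables.skipped["DEMO_NO_DATE"] = no_date
    for rec in tables.drug:
        rep = reports.get(rec.primary_id)
        if rep is not None:
            rep.drugs.append(rec)
    for rec in tables.reac:
        rep = reports.get(rec.primary_id)
        if rep is not None:
            rep.reactions.append(rec)
    for rec in tables.outc:
        rep = reports.get(rec.primary_id)
        if rep is not None:
            rep.outcomes.append(rec.outcome_code)
    for rec in tables.indi:
        rep = reports.get(rec.primary_id)
        if rep is not None:
            rep.indications.append(rec.indication_term)
    return sorted(reports.values(), key=lambda r: r.primary_id)


# ---------------------------------------------------------------------------
# Fixture format (JSON Lines, one report per line)
# ---------------------------------------------------------------------------


def _date_out(d: datetime.date | None) -> str | None:
    return d.isoformat() if d is not None else None


def _date_in(s: str | None) -> datetime.date | None:
    return datetime.date.fromisoformat(s) if s is not None else None


def _report_to_obj(r: CaseReport) -> dict:
    return {
        "primary_id": r.primary_id,
        "case_id": r.case_id,
        "fda_receipt_date": _date_out(r.fda_receipt_date),
        "age_years": r.age_years,
        "sex": r.sex,
        "country": r.country,
        "reporter_type": r.reporter_type,
        "drugs": [
            {
                "drug_name_raw": d.drug_name_raw,
                "role_code": d.role_code,
                "therapy_start_date": _date_out(d.therapy_start_date),
                "start_imprecise": d.start_imprecise,
            }
            for d in r.drugs
        ],
        "reactions": [
            {
                "pt": rx.pt,
                "event_onset_date": _date_out(rx.event_onset_date),
                "onset_imprecise": rx.onset_imprecise,
            }
            for rx in r.reactions
        ],
        "outcomes": list(r.outcomes),
        "indications": list(r.indications),
    }


def _report_from_obj(obj: dict, index: int) -> CaseReport:
    try:
        pid = obj["primary_id"]
        report = CaseReport(
            primary_id=pid,
            case_id=obj["case_id"],
            fda_receipt_date=_date_in(obj["fda_receipt_date"]),
            age_years=obj.get("age_years"),
            sex=obj.get("sex"),
            country=obj.get("country"),
            reporter_type=obj.get("reporter_type"),
            drugs=[
                DrugRecord(
                    primary_id=pid,
                    drug_name_raw=d["drug_name_raw"],
                    role_code=d["role_code"],
                    therapy_start_date=_date_in(d.get("therapy_start_date")),
                    start_imprecise=bool(d.get("start_imprecise", False)),
                )
                for d in obj.get("drugs", [])
            ],
            reactions=[
                ReactionRecord(
                    primary_id=pid,
                    pt=rx["pt"],
                    event_onset_date=_date_in(rx.get("event_onset_date")),
                    onset_imprecise=bool(rx.get("onset_imprecise", False)),
                )
                for rx in obj.get("reactions", [])
            ],
            outcomes=list(obj.get("outcomes", [])),
            indications=list(obj.get("indications", [])),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"fixture record {index}: schema violation ({exc})") from exc
    if report.fda_receipt_date is None:
        raise ValueError(f"fixture record {index}: missing fda_receipt_date")
    return report


def write_fixture(reports: Iterable[CaseReport], path: str | Path) -> None:
    reports = sorted(reports, key=lambda r: r.primary_id)
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(json.dumps(_report_to_obj(r), sort_keys=True) + "\n")


def read_fixture(path: str | Path) -> list[CaseReport]:
    """Read a JSON-Lines fixture; deterministic ordering by PRIMARYID."""
    reports: list[CaseReport] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            report = _report_from_obj(json.loads(line), i)
            if report.primary_id in seen:
                raise ValueError(
                    f"fixture record {i}: duplicate primary_id '{report.primary_id}'"
                )
            seen.add(report.primary_id)
            reports.append(report)
    reports.sort(key=lambda r: r.primary_id)
    return reports


def write_signal_report(results: Mapping[str, object], path: str | Path) -> None:
    """Write one row per treatment strategy, mirroring the signal-table layout.

    Columns: strategy, N, ROR (95% CI), PRR (chi2), IC (IC025), EBGM (EBGM05),
    joint flag. Values rounded to one decimal; undefined statistics print NA.
    """
    if not results:
        raise ValueError("write_signal_report: no results to write")

    def fmt(x, nd=1):
        return "NA" if x is None else f"{x:.{nd}f}"

    lines = ["strategy\tN\tROR (95% CI)\tPRR (chi2)\tIC (IC025)\tEBGM (EBGM05)\tjoint"]
    for label, res in results.items():
        ror_ci = (
            "NA"
            if res.ror is None
            else f"{res.ror:.1f} ({res.ror_ci95[0]:.1f}, {res.ror_ci95[1]:.1f})"
        )
        lines.append(
            "\t".join(
                [
                    label,
                    str(res.n_cases),
                    ror_ci,
                    f"{fmt(res.prr)} ({fmt(res.chi2)})",
                    f"{fmt(res.ic)} ({fmt(res.ic025)})",
                    f"{fmt(res.ebgm)} ({fmt(res.ebgm05)})",
                    "yes" if res.joint_positive else "no",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
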