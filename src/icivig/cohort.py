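"""Cohort construction: deduplication, filtering, and report classification.

A spontaneous-report database carries several versions of the same case and a
mix of precise and partial information. This module turns raw reports into the
analysis cohort: one record per case, adults only, restricted to the study
window, with each report labelled by its immune-checkpoint-inhibitor (ICI)
treatment strategy and its indication organ.
"""

from __future__ import annotations

import datetime
import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._dictionaries import (
    AGENT_CLASS,
    AGENT_ORDER,
    DRUG_SYNONYMS,
    ORGAN_KEYWORDS,
)

logger = logging.getLogger(__name__)

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = ("PS", "SS", "C", "I")
SUSPECT_ROLES = ("PS", "SS")

#: FAERS outcome vocabulary.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

DEFAULT_WINDOW = (datetime.date(2012, 1, 1), datetime.date(2022, 12, 31))
DEFAULT_PT = "Immune thrombocytopenia"


@dataclass(slots=True)
class DrugRecord:
    primary_id: str
    drug_name_raw: str
    role_code: str
    therapy_start_date: datetime.date | None = None
    start_imprecise: bool = False


@dataclass(slots=True)
class ReactionRecord:
    primary_id: str
    pt: str
    event_onset_date: datetime.date | None = None
    onset_imprecise: bool = False


@dataclass(slots=True)
class CaseReport:
    """One spontaneous report after table joining (one row per PRIMARYID)."""

    primary_id: str
    case_id: str
    fda_receipt_date: datetime.date
    age_years: float | None = None
    sex: str | None = None
    country: str | None = None
    reporter_type: str | None = None
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)

    @property
    def received_year(self) -> int:
        return self.fda_receipt_date.year

    @property
    def first_ici_start_date(self) -> datetime.date | None:
        """Earliest therapy start among suspect-role ICI drugs."""
        dates = [
            d.therapy_start_date
            for d in self.drugs
            if d.role_code in SUSPECT_ROLES
            and classify_ici(d.drug_name_raw) is not None
            and d.therapy_start_date is not None
        ]
        return min(dates) if dates else None


class Strategy(str, enum.Enum):
    ANTI_PD1 = "ANTI_PD1"
    ANTI_PDL1 = "ANTI_PDL1"
    ANTI_CTLA4 = "ANTI_CTLA4"
    COMBO = "COMBO"
    NONE = "NONE"


@dataclass(frozen=True, slots=True)
class StrategyLabel:
    value: Strategy
    drug_level: str | None = None  # single agent, or "pd1agent+ctla4agent"


def _normalize_drug_name(name: str) -> str:
    cleaned = "".join(ch if ch.isalnum() or ch == " " else " " for ch in name.lower())
    return " ".join(cleaned.split())


def classify_ici(drug_name_raw: str) -> str | None:
    """Map a verbatim drug name to a generic ICI agent, or ``None``.

    Brand and generic synonyms are matched case-insensitively after stripping
    punctuation; a synonym embedded in a longer verbatim string (for example a
    name with a dose suffix) is still found token-wise.
    """
    norm = _normalize_drug_name(drug_name_raw)
    if not norm:
        return None
    hit = DRUG_SYNONYMS.get(norm)
    if hit is not None:
        return hit
    for token in norm.split():
        hit = DRUG_SYNONYMS.get(token)
        if hit is not None:
            return hit
    return None


def report_agents(report: CaseReport) -> list[str]:
    """Suspect-role ICI agents in a report, in fixed class-major order."""
    found = {
        agent
        for d in report.drugs
        if d.role_code in SUSPECT_ROLES
        for agent in (classify_ici(d.drug_name_raw),)
        if agent is not None
    }
    return [a for a in AGENT_ORDER if a in found]


def assign_strategy(report: CaseReport) -> StrategyLabel:
    """Label a report with its ICI treatment strategy.

    Only suspect-role drugs (PS/SS) define exposure. A combination means at
    least one anti-PD-1/PD-L1 agent together with at least one anti-CTLA-4
    agent; PD-1 plus PD-L1 co-exposure without CTLA-4 does not qualify and is
    excluded from strategy-level analyses.
    """
    agents = report_agents(report)
    classes = {AGENT_CLASS[a] for a in agents}
    has_pd = bool(classes & {"ANTI_PD1", "ANTI_PDL1"})
    has_ctla4 = "ANTI_CTLA4" in classes
    if has_pd and has_ctla4:
        pd_agent = next(a for a in agents if AGENT_CLASS[a] != "ANTI_CTLA4")
        ctla4_agent = next(a for a in agents if AGENT_CLASS[a] == "ANTI_CTLA4")
        return StrategyLabel(Strategy.COMBO, f"{pd_agent}+{ctla4_agent}")
    if len(classes) == 1:
        cls = classes.pop()
        drug_level = agents[0] if len(agents) == 1 else None
        return StrategyLabel(Strategy(cls), drug_level)
    if classes == {"ANTI_PD1", "ANTI_PDL1"}:
        logger.info(
            "report %s: PD-1 + PD-L1 co-exposure without CTLA-4; "
            "excluded from strategy-level analyses",
            report.primary_id,
        )
        return StrategyLabel(Strategy.NONE)
    return StrategyLabel(Strategy.NONE)


def _dedup_key(report: CaseReport) -> tuple:
    pid = report.primary_id
    pid_key = (0, int(pid), "") if pid.isdigit() else (1, 0, pid)
    return (report.fda_receipt_date, pid_key)


def deduplicate(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep one report per case: the latest FDA receipt date.

    Exact PRIMARYID duplicates are collapsed first; ties on receipt date are
    broken toward the numerically (else lexicographically) larger PRIMARYID.
    The result is ordered by PRIMARYID, so the operation is idempotent and
    independent of input order.
    """
    by_pid: dict[str, CaseReport] = {}
    n_in = 0
    for r in reports:
        n_in += 1
        by_pid.setdefault(r.primary_id, r)
    best: dict[str, CaseReport] = {}
    for r in by_pid.values():
        cur = best.get(r.case_id)
        if cur is None or _dedup_key(r) > _dedup_key(cur):
            best[r.case_id] = r
    survivors = sorted(best.values(), key=_dedup_key)
    removed = n_in - len(survivors)
    if removed:
        logger.info("deduplicate: removed %d of %d reports", removed, n_in)
    return survivors


def apply_filters(
    reports: Sequence[CaseReport],
    window: tuple[datetime.date, datetime.date] = DEFAULT_WINDOW,
    min_age: float = 18.0,
) -> list[CaseReport]:
    """Restrict to the study window and to adults.

    Reports with a known age below ``min_age`` are dropped; reports with a
    missing age are retained (the characteristics table carries an explicit
    missing-age stratum). The returned set is the full background used for
    contingency building; ICI exposure is not required here.
    """
    lo, hi = window
    kept = [
        r
        for r in reports
        if lo <= r.fda_receipt_date <= hi
        and (r.age_years is None or r.age_years >= min_age)
    ]
    if not kept:
        logger.warning("apply_filters: empty cohort after filtering")
    return kept


def select_cases(
    cohort: Sequence[CaseReport], pt: str = DEFAULT_PT
) -> dict[str, bool]:
    """Flag each report as a case iff a reaction PT equals ``pt`` exactly.

    Matching is case-insensitive but exact: 'Thrombocytopenia' is a distinct
    preferred term and does not select 'Immune thrombocytopenia' cases.
    """
    if not pt or not pt.strip():
        raise ValueError("target preferred term must be non-empty")
    target = pt.strip().casefold()
    return {
        r.primary_id: any(rx.pt.strip().casefold() == target for rx in r.reactions)
        for r in cohort
    }


def map_indication_organ(indication_term: str | None) -> str:
    """Map a free-text indication to an organ category.

    Unmatched non-empty terms become 'Unspecified'; an absent term is
    'Missing'. The keyword table is ordered so more specific site names win.
    """
    if indication_term is None or not indication_term.strip():
        return "Missing"
    term = indication_term.casefold()
    for keyword, organ in ORGAN_KEYWORDS:
        if keyword in term:
            return organ
    return "Unspecified"


def report_organ(report: CaseReport) -> str:
    """Single organ label per report: first indication that maps to a site."""
    labels = [map_indication_organ(t) for t in report.indications]
    for lab in labels:
        if lab not in ("Unspecified", "Missing"):
            return lab
    if any(lab == "Unspecified" for lab in labels):
        return "Unspecified"
    return "Missing"
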