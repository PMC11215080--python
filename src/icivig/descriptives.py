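"""Clinical-characteristics summary of the case series, fatal vs non-fatal.

A case is fatal iff the death code (DE) appears among its outcomes; the
non-fatal outcome shown for the remaining cases is the most severe remaining
code in the order life-threatening > hospitalization > disability > other.
Per-variable association with mortality is tested with an uncorrected Pearson
chi-square, with missing-value rows displayed but excluded from the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import CaseReport, Strategy, StrategyLabel, assign_strategy, report_organ
from ._dictionaries import ORGAN_CATEGORIES

logger = logging.getLogger(__name__)

AGE_CUTOFFS = (65.0, 85.0)
AGE_GROUPS = ("18-65", "65-85", ">85", "Missing")

#: Countries broken out individually; everything else is pooled.
TOP_COUNTRIES = ("JP", "US", "FR", "DE", "CA", "CN")

OUTCOME_SEVERITY = ("LT", "HO", "DS", "OT")
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "OT": "Other",
}

REPORTER_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other healthcare professional",
    "HP": "Other healthcare professional",
}

STRATEGY_LABELS = {
    Strategy.ANTI_PD1: "Anti-PD-1",
    Strategy.ANTI_PDL1: "Anti-PD-L1",
    Strategy.ANTI_CTLA4: "Anti-CTLA-4",
    Strategy.COMBO: "Combination therapy",
}


def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100*num/den, rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("proportion: denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def is_fatal(report: CaseReport) -> bool:
    return "DE" in report.outcomes


def outcome_category(report: CaseReport) -> str:
    """Mutually exclusive outcome category with death precedence."""
    if is_fatal(report):
        return "Death"
    for code in OUTCOME_SEVERITY:
        if code in report.outcomes:
            return OUTCOME_LABELS[code]
    return "Missing"


def age_group(age_years: float | None) -> str:
    if age_years is None:
        return "Missing"
    if age_years < AGE_CUTOFFS[0]:
        return "18-65"
    if age_years <= AGE_CUTOFFS[1]:
        return "65-85"
    return ">85"


def country_group(country: str | None) -> str:
    if country is None:
        return "Other country"
    return country if country in TOP_COUNTRIES else "Other country"


def reporter_group(reporter_type: str | None) -> str:
    if reporter_type is None:
        return "Missing"
    return REPORTER_LABELS.get(reporter_type.upper(), "Missing")


def sex_group(sex: str | None) -> str:
    if sex in ("M", "F"):
        return {"M": "Male", "F": "Female"}[sex]
    return "Missing"


@dataclass(slots=True)
class CharacteristicsRow:
    variable: str
    category: str
    fatal: int
    nonfatal: int

    @property
    def total(self) -> int:
        return self.fatal + self.nonfatal


@dataclass
class CharacteristicsTable:
    n_fatal: int
    n_nonfatal: int
    rows: list[CharacteristicsRow] = field(default_factory=list)
    pvalues: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_fatal + self.n_nonfatal

    def variable_rows(self, variable: str) -> list[CharacteristicsRow]:
        return [r for r in self.rows if r.variable == variable]

    def row(self, variable: str, category: str) -> CharacteristicsRow:
        for r in self.rows:
            if r.variable == variable and r.category == category:
                return r
        raise KeyError((variable, category))

    def to_tsv(self, path) -> None:
        lines = ["variable\tcategory\tfatal\tfatal_pct\tnonfatal\tnonfatal_pct"
                 "\ttotal\ttotal_pct\tp_value"]
        seen: set[str] = set()
        for r in self.rows:
            pct = lambda n, d: "" if d == 0 else f"{proportion(n, d, 1):.1f}"
            p = ""
            if r.variable not in seen and r.variable in self.pvalues:
                p = f"{self.pvalues[r.variable][1]:.3g}"
            seen.add(r.variable)
            lines.append(
                f"{r.variable}\t{r.category}\t{r.fatal}\t{pct(r.fatal, self.n_fatal)}"
                f"\t{r.nonfatal}\t{pct(r.nonfatal, self.n_nonfatal)}"
                f"\t{r.total}\t{pct(r.total, self.n_total)}\t{p}"
            )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def chisq_association(
    fatal_counts: Sequence[int], nonfatal_counts: Sequence[int]
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for mortality association.

    Categories with a zero total are dropped; at least two informative
    categories are required, and a zero expected cell is an error.
    """
    pairs = [
        (f, nf) for f, nf in zip(fatal_counts, nonfatal_counts, strict=True)
        if f + nf > 0
    ]
    if len(pairs) < 2:
        raise ValueError("chisq_association: need >= 2 categories with counts")
    table = np.array(pairs).T  # 2 x k
    if (table.sum(axis=1) == 0).any():
        raise ValueError("chisq_association: a margin is zero (expected cell 0)")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected == 0).any():
        raise ValueError("chisq_association: zero expected cell")
    return float(chi2), float(p)


def _year_categories(cases: Sequence[CaseReport]) -> list[str]:
    return [str(y) for y in sorted({r.received_year for r in cases})]


def summarize(
    cohort_cases: Sequence[CaseReport],
    labels: dict[str, StrategyLabel] | None = None,
) -> CharacteristicsTable:
    """Build the clinical-characteristics table for the case series.

    Variables: gender, age group (cutoffs at 65 and 85 years), country,
    received year, treatment strategy, mutually exclusive outcomes, indication
    organ, and reporter type. Each variable's categories (missing included)
    sum to the cohort size.
    """
    if not cohort_cases:
        raise ValueError("summarize: empty case set")
    if labels is None:
        labels = {r.primary_id: assign_strategy(r) for r in cohort_cases}

    fatal = [r for r in cohort_cases if is_fatal(r)]
    nonfatal = [r for r in cohort_cases if not is_fatal(r)]
    table = CharacteristicsTable(n_fatal=len(fatal), n_nonfatal=len(nonfatal))

    def add_variable(variable: str, categories: Sequence[str], value_fn) -> None:
        f_counts = {c: 0 for c in categories}
        nf_counts = {c: 0 for c in categories}
        for r in fatal:
            f_counts[value_fn(r)] += 1
        for r in nonfatal:
            nf_counts[value_fn(r)] += 1
        for c in categories:
            if f_counts[c] or nf_counts[c] or c != "Missing":
                table.rows.append(
                    CharacteristicsRow(variable, c, f_counts[c], nf_counts[c])
                )
        informative = [c for c in categories if c != "Missing"]
        try:
            table.pvalues[variable] = chisq_association(
                [f_counts[c] for c in informative],
                [nf_counts[c] for c in informative],
            )
        except ValueError:
            logger.info("summarize: chi-square not computable for %s", variable)

    add_variable("Gender", ["Male", "Female", "Missing"], lambda r: sex_group(r.sex))
    add_variable("Age group", list(AGE_GROUPS), lambda r: age_group(r.age_years))
    add_variable(
        "Country",
        list(TOP_COUNTRIES) + ["Other country"],
        lambda r: country_group(r.country),
    )
    add_variable(
        "Received year", _year_categories(cohort_cases), lambda r: str(r.received_year)
    )
    strategy_cats = list(STRATEGY_LABELS.values()) + ["Missing"]
    add_variable(
        "Treatment strategy",
        strategy_cats,
        lambda r: STRATEGY_LABELS.get(labels[r.primary_id].value, "Missing"),
    )
    add_variable(
        "Outcomes",
        ["Death", "Life-threatening", "Hospitalization", "Disability", "Other",
         "Missing"],
        outcome_category,
    )
    add_variable("Indication organ", list(ORGAN_CATEGORIES), report_organ)
    add_variable(
        "Reporter type",
        ["Consumer", "Physician", "Pharmacist", "Other healthcare professional",
         "Missing"],
        lambda r: reporter_group(r.reporter_type),
    )
    return table
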