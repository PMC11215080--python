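"""Disproportionality statistics on 2x2 report contingency tables.

For an index exposure E and a target event Y in a spontaneous-report database,
the table counts are

    a = reports with E and Y        b = reports with E, other events
    c = reports without E, with Y   d = reports without E, other events

and N = a+b+c+d. Four classical signal-detection statistics are computed:

* ROR  = ad/(bc), with a Wald 95% CI on the log scale,
* PRR  = [a/(a+b)] / [c/(c+d)], with the Pearson chi-square
  (ad-bc)^2 N / [(a+b)(c+d)(a+c)(b+d)], no continuity correction,
* IC   = log2[ aN / ((a+c)(a+b)) ] (information component), and
* EBGM = aN / ((a+c)(a+b)), the observed/expected relative reporting ratio
  (no empirical-Bayes shrinkage), so 2**IC == EBGM identically.

The lower bounds are computed exactly as the source formulas state them:
IC025 = exp(ln IC - 1.96*s) and EBGM05 = exp(ln EBGM - 1.64*s) with
s = sqrt(1/a + 1/b + 1/c + 1/d). Note the IC025 form exponentiates the log of
the IC itself; it is unusual (a conventional BCPNN bound subtracts on the log2
scale) but is implemented verbatim and flagged in the documentation.

A signal is declared only when all four per-algorithm thresholds are met
(N >= 2 with ROR CI low > 1; N >= 2, PRR >= 2, chi2 >= 4; IC025 > 0;
EBGM05 > 2), where N in the thresholds is the case count a.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from ._dictionaries import AGENT_CLASS, AGENT_ORDER
from .cohort import CaseReport, Strategy, StrategyLabel, assign_strategy, select_cases

logger = logging.getLogger(__name__)

Z95 = 1.96
Z90_ONE_SIDED = 1.64

ALGORITHMS = ("ror", "prr", "ic", "ebgm")


class UndefinedStatistic(ValueError):
    """A statistic is undefined for this table (names the offending cell)."""


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def _require_positive(self, cells: str) -> None:
        for name in cells:
            if getattr(self, name) == 0:
                raise UndefinedStatistic(f"zero cell {name}")


def _log_se(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def compute_ror(t: ContingencyTable) -> tuple[float, tuple[float, float]]:
    """Reporting odds ratio with its Wald 95% CI; requires all cells > 0."""
    t._require_positive("abcd")
    ror = (t.a * t.d) / (t.b * t.c)
    se = _log_se(t)
    ci = (math.exp(math.log(ror) - Z95 * se), math.exp(math.log(ror) + Z95 * se))
    return ror, ci


def ror_flag(t: ContingencyTable, ror: float, ci: tuple[float, float]) -> bool:
    return t.a >= 2 and ci[0] > 1.0


def compute_prr(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and uncorrected Pearson chi-square."""
    if t.a + t.b == 0:
        raise UndefinedStatistic("zero margin a+b")
    if t.c + t.d == 0:
        raise UndefinedStatistic("zero margin c+d")
    if t.c == 0:
        raise UndefinedStatistic("zero cell c")
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if denom == 0:
        raise UndefinedStatistic("zero margin in chi-square denominator")
    chi2 = (t.a * t.d - t.b * t.c) ** 2 * t.n / denom
    return prr, chi2


def prr_flag(t: ContingencyTable, prr: float, chi2: float) -> bool:
    return t.a >= 2 and prr >= 2.0 and chi2 >= 4.0


def compute_ic(t: ContingencyTable) -> tuple[float, float | None]:
    """Information component IC = log2(observed/expected) and its lower bound.

    The printed lower-bound form exp(ln IC - 1.96 s) is only defined for
    IC > 0 (and needs all cells positive for s); otherwise IC025 is reported
    as not applicable, which makes the IC criterion fail.
    """
    if t.a == 0:
        raise UndefinedStatistic("zero cell a")
    if t.a + t.b == 0 or t.a + t.c == 0:
        raise UndefinedStatistic("zero margin for IC")
    ic = math.log2(t.a * t.n / ((t.a + t.c) * (t.a + t.b)))
    ic025: float | None = None
    if ic > 0 and min(t.a, t.b, t.c, t.d) > 0:
        ic025 = math.exp(math.log(ic) - Z95 * _log_se(t))
    return ic, ic025


def ic_flag(t: ContingencyTable, ic: float, ic025: float | None) -> bool:
    return ic025 is not None and ic025 > 0.0


def compute_ebgm(t: ContingencyTable) -> tuple[float, float | None]:
    """Relative reporting ratio aN/((a+c)(a+b)) and its one-sided lower bound.

    This is the observed/expected ratio without gamma-Poisson shrinkage;
    EBGM05 = exp(ln EBGM - 1.64 s) needs all cells positive for s.
    """
    if t.a == 0:
        raise UndefinedStatistic("zero cell a")
    if t.a + t.b == 0 or t.a + t.c == 0:
        raise UndefinedStatistic("zero margin for EBGM")
    ebgm = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    ebgm05: float | None = None
    if min(t.a, t.b, t.c, t.d) > 0:
        ebgm05 = math.exp(math.log(ebgm) - Z90_ONE_SIDED * _log_se(t))
    return ebgm, ebgm05


def ebgm_flag(t: ContingencyTable, ebgm: float, ebgm05: float | None) -> bool:
    return ebgm05 is not None and ebgm05 > 2.0


@dataclass(slots=True)
class SignalResult:
    n_cases: int
    ror: float | None = None
    ror_ci95: tuple[float, float] | None = None
    prr: float | None = None
    chi2: float | None = None
    ic: float | None = None
    ic025: float | None = None
    ebgm: float | None = None
    ebgm05: float | None = None
    flags: dict[str, bool] = None  # type: ignore[assignment]
    joint_positive: bool = False

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = {alg: False for alg in ALGORITHMS}


def evaluate_signal(t: ContingencyTable) -> SignalResult:
    """All four statistics plus the joint positivity flag for one table.

    An undefined statistic (zero cell) is recorded as not applicable with a
    false flag rather than raising, so a scan over many strategies never
    aborts on a sparse row.
    """
    res = SignalResult(n_cases=t.a)
    try:
        res.ror, res.ror_ci95 = compute_ror(t)
        res.flags["ror"] = ror_flag(t, res.ror, res.ror_ci95)
    except UndefinedStatistic:
        pass
    try:
        res.prr, res.chi2 = compute_prr(t)
        res.flags["prr"] = prr_flag(t, res.prr, res.chi2)
    except UndefinedStatistic:
        pass
    try:
        res.ic, res.ic025 = compute_ic(t)
        res.flags["ic"] = ic_flag(t, res.ic, res.ic025)
    except UndefinedStatistic:
        pass
    try:
        res.ebgm, res.ebgm05 = compute_ebgm(t)
        res.flags["ebgm"] = ebgm_flag(t, res.ebgm, res.ebgm05)
    except UndefinedStatistic:
        pass
    res.joint_positive = all(res.flags[alg] for alg in ALGORITHMS)
    return res


def build_contingency(
    background_reports: Sequence[CaseReport],
    index_predicate: Callable[[CaseReport], bool],
    event_flag: Mapping[str, bool] | Callable[[CaseReport], bool],
) -> ContingencyTable:
    """Partition the background into the four cells of a 2x2 table."""
    if not background_reports:
        raise ValueError("build_contingency: empty background")
    if callable(event_flag):
        is_event = event_flag
    else:
        is_event = lambda r: bool(event_flag.get(r.primary_id, False))  # noqa: E731
    a = b = c = d = 0
    for r in background_reports:
        if index_predicate(r):
            if is_event(r):
                a += 1
            else:
                b += 1
        else:
            if is_event(r):
                c += 1
            else:
                d += 1
    return ContingencyTable(a, b, c, d)


_STRATEGY_ROW = {
    Strategy.ANTI_PD1: "Anti-PD-1",
    Strategy.ANTI_PDL1: "Anti-PD-L1",
    Strategy.ANTI_CTLA4: "Anti-CTLA-4",
}


def scan_strategies(
    background: Sequence[CaseReport],
    pt: str = "Immune thrombocytopenia",
    labels: Mapping[str, StrategyLabel] | None = None,
    case_flags: Mapping[str, bool] | None = None,
) -> dict[str, SignalResult]:
    """One signal row per treatment strategy against the full background.

    Rows: Total (any ICI exposure), each ICI class, each single agent present,
    and each observed PD-1/PD-L1 + CTLA-4 pair. The comparator for every row
    is all other background reports. Strategy labels and case flags may be
    passed in to avoid recomputation; otherwise they are derived here.
    """
    if not background:
        raise ValueError("scan_strategies: empty background")
    if labels is None:
        labels = {r.primary_id: assign_strategy(r) for r in background}
    if case_flags is None:
        case_flags = select_cases(background, pt)

    # Tally (strategy value, drug_level, is_case) once; every row is then a
    # marginal sum, which keeps the scan linear in the background size.
    counts: dict[tuple[Strategy, str | None], list[int]] = {}
    n_cases_total = 0
    n_total = len(background)
    for r in background:
        lab = labels[r.primary_id]
        is_case = bool(case_flags.get(r.primary_id, False))
        cell = counts.setdefault((lab.value, lab.drug_level), [0, 0])
        cell[1 if is_case else 0] += 1
        if is_case:
            n_cases_total += 1

    def row(pred: Callable[[Strategy, str | None], bool]) -> SignalResult:
        a = sum(v[1] for k, v in counts.items() if pred(*k))
        ab = sum(sum(v) for k, v in counts.items() if pred(*k))
        b = ab - a
        c = n_cases_total - a
        d = n_total - ab - c
        return evaluate_signal(ContingencyTable(a, b, c, d))

    results: dict[str, SignalResult] = {}
    results["Total"] = row(lambda s, dl: s != Strategy.NONE)
    # Class rows are always emitted; an absent class yields a zero index
    # margin and therefore a row of not-applicable statistics.
    for strat, name in _STRATEGY_ROW.items():
        results[name] = row(lambda s, dl, strat=strat: s == strat)
    for agent in AGENT_ORDER:
        strat = Strategy(AGENT_CLASS[agent])
        if (strat, agent) in counts:
            results[agent.capitalize()] = row(
                lambda s, dl, strat=strat, agent=agent: s == strat and dl == agent
            )
    pairs = sorted({dl for (s, dl) in counts if s == Strategy.COMBO and dl is not None})
    for pair in pairs:
        first, second = pair.split("+")
        name = f"{first.capitalize()} + {second}"
        results[name] = row(lambda s, dl, pair=pair: s == Strategy.COMBO and dl == pair)
    return results
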