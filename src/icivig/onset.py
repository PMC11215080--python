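"""Time-to-onset (TTO) analysis: days from first ICI dose to event onset.

TTO is the difference between the event-onset date of the target reaction and
the first suspect-ICI therapy start date. Reports lacking either date, with an
imprecise (partially specified) date, or with a non-positive difference are
excluded with a logged reason, yielding the analyzable subset. With every
onset observed and no censoring, the Kaplan-Meier event-free curve reduces
exactly to one minus the empirical CDF; it is computed by the product-limit
form so the identity is a checked property rather than an assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import CaseReport, DEFAULT_PT, StrategyLabel

logger = logging.getLogger(__name__)

#: Onset bins in days, left-open / right-closed, so "within 30 days" is the
#: first bin.
TTO_BINS = ((0, 30), (30, 60), (60, 90), (90, 180), (180, None))
TTO_BIN_LABELS = ("(0,30]", "(30,60]", "(60,90]", "(90,180]", ">180")


@dataclass(slots=True)
class OnsetRecord:
    primary_id: str
    tto_days: float
    strategy: StrategyLabel | None = None
    organ: str | None = None


def compute_tto(report: CaseReport, pt: str = DEFAULT_PT) -> tuple[float | None, str]:
    """TTO in days for one report, or (None, reason) if not analyzable."""
    start = report.first_ici_start_date
    if start is None:
        return None, "no therapy date"
    if any(
        d.start_imprecise
        for d in report.drugs
        if d.therapy_start_date == start
    ):
        return None, "imprecise therapy date"
    target = pt.strip().casefold()
    events = [rx for rx in report.reactions if rx.pt.strip().casefold() == target]
    dated = [rx for rx in events if rx.event_onset_date is not None]
    if not dated:
        return None, "no event date"
    first = min(dated, key=lambda rx: rx.event_onset_date)
    if first.onset_imprecise:
        return None, "imprecise event date"
    tto = (first.event_onset_date - start).days
    if tto <= 0:
        return None, "non-positive TTO"
    return float(tto), "ok"


def bin_tto(tto_days: float) -> str:
    if tto_days <= 0:
        raise ValueError("bin_tto: TTO must be positive")
    for (lo, hi), label in zip(TTO_BINS, TTO_BIN_LABELS):
        if hi is None or lo < tto_days <= hi:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(slots=True)
class KMCurve:
    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # event-free probability just after each time
    at_risk: np.ndarray      # subjects at risk entering each time

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(tto_days: Sequence[float]) -> KMCurve:
    """Product-limit event-free curve for fully observed onset times."""
    if len(tto_days) == 0:
        raise ValueError("km_curve: empty input")
    values = np.sort(np.asarray(tto_days, dtype=float))
    times, counts = np.unique(values, return_counts=True)
    n = len(values)
    at_risk = n - np.concatenate(([0], np.cumsum(counts)[:-1]))
    survival = np.cumprod(1.0 - counts / at_risk)
    return KMCurve(times=times, survival=survival, at_risk=at_risk)


def logrank_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """k-group log-rank chi-square on fully observed onset times, df = k-1."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("logrank_test: need >= 2 non-empty groups")
    durations = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    labels = np.concatenate(
        [np.full(len(g), i) for i, g in enumerate(groups)]
    )
    res = multivariate_logrank_test(durations, labels, np.ones_like(durations))
    return float(res.test_statistic), float(res.p_value)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; identical samples give p = 1."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis: need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        logger.warning("kruskal_wallis: all values identical; H=0, p=1")
        return 0.0, 1.0
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(h), float(p)


def median_iqr(tto_days: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation (type-7 convention)."""
    if len(tto_days) == 0:
        raise ValueError("median_iqr: empty input")
    arr = np.asarray(tto_days, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


def onset_records(
    cases: Sequence[CaseReport],
    labels: dict[str, StrategyLabel] | None = None,
    organs: dict[str, str] | None = None,
    pt: str = DEFAULT_PT,
) -> tuple[list[OnsetRecord], dict[str, str]]:
    """Analyzable onset records plus the per-report exclusion reasons."""
    records: list[OnsetRecord] = []
    excluded: dict[str, str] = {}
    for r in cases:
        tto, reason = compute_tto(r, pt)
        if tto is None:
            excluded[r.primary_id] = reason
            continue
        records.append(
            OnsetRecord(
                primary_id=r.primary_id,
                tto_days=tto,
                strategy=labels.get(r.primary_id) if labels else None,
                organ=organs.get(r.primary_id) if organs else None,
            )
        )
    return records, excluded
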