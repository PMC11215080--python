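"""Synthetic FAERS-like cohorts and expression matrices with known truths.

Two kinds of synthetic data are produced:

* stochastic cohorts (``gen_cohort``) with configurable exposure prevalences,
  a baseline event probability and per-strategy planted reporting-ratio
  multipliers, used for null-calibration and coverage studies of the signal
  statistics; and
* a deterministic 345-report case series (``gen_paper_fixture``) whose
  marginal counts reproduce the published clinical-characteristics table of
  ICI-induced immune thrombocytopenia exactly (gender, age group, received
  year, treatment strategy, outcomes, indication organ, reporter type), whose
  analyzable time-to-onset subset has 147 records with 64 onsets within 30
  days and 88 within 60, and whose known ages and onset times reproduce the
  published medians and interquartile ranges (age 69, IQR 60-76; onset 42
  days, IQR 17-135) under the type-7 quantile convention.

Every stochastic generator is a pure function of its config, seed included.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CaseReport, DrugRecord, ReactionRecord

ITP_PT = "Immune thrombocytopenia"

#: Default exposure prevalences per strategy key (single agent or a
#: "pd1agent+ctla4agent" pair). The mix emulates the relative reporting
#: volumes of the eight agents in a spontaneous-report database where ICI
#: reports are a few percent of all reports.
DEFAULT_EXPOSURE: dict[str, float] = {
    "nivolumab": 0.010,
    "pembrolizumab": 0.010,
    "cemiplimab": 0.0005,
    "atezolizumab": 0.003,
    "avelumab": 0.0008,
    "durvalumab": 0.0015,
    "ipilimumab": 0.002,
    "nivolumab+ipilimumab": 0.004,
    "pembrolizumab+ipilimumab": 0.0003,
}

_COUNTRIES = ("JP", "US", "FR", "DE", "CA", "CN", "IT", "GB")
_COUNTRY_P = (0.30, 0.25, 0.08, 0.06, 0.03, 0.03, 0.10, 0.15)
_REPORTERS = ("MD", "OT", "CN", "PH")
_REPORTER_P = (0.45, 0.30, 0.15, 0.10)
_ORGAN_TERMS = (
    "Non-small cell lung cancer",
    "Malignant melanoma",
    "Bladder cancer",
    "Renal cell carcinoma",
    "Gastric cancer",
    "Malignant neoplasm",
)
_ORGAN_P = (0.34, 0.24, 0.06, 0.05, 0.05, 0.26)
_OUTCOMES = ("DE", "LT", "HO", "OT")
_OUTCOME_P = (0.18, 0.14, 0.31, 0.37)

_EPOCH = datetime.date(2012, 1, 1)
_WINDOW_DAYS = (datetime.date(2022, 12, 31) - _EPOCH).days


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic spontaneous-report cohort.

    ``planted_ratio`` multiplies the baseline event probability for reports
    exposed to the given strategy key (reporting-ratio multiplier rho); keys
    absent from the mapping default to 1 (null).
    """

    seed: int
    n_background: int = 50_000
    ici_exposure: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE)
    )
    baseline_event_prob: float = 0.003
    planted_ratio: Mapping[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    age_missing_rate: float = 0.20
    date_missing_rate: float = 0.55
    country_missing_rate: float = 0.05
    onset_median_days: float = 42.0
    onset_log_sd: float = 1.54

    def __post_init__(self) -> None:
        probs = list(self.ici_exposure.values()) + [
            self.baseline_event_prob,
            self.duplicate_rate,
            self.age_missing_rate,
            self.date_missing_rate,
            self.country_missing_rate,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.ici_exposure.values()) > 1:
            raise ValueError("exposure probabilities sum above 1")
        if any(r <= 0 for r in self.planted_ratio.values()):
            raise ValueError("planted ratios must be positive")


def _strategy_drugs(key: str, pid: str, start: datetime.date | None) -> list[DrugRecord]:
    return [
        DrugRecord(primary_id=pid, drug_name_raw=agent.upper(), role_code="PS",
                   therapy_start_date=start)
        for agent in key.split("+")
    ]


def gen_cohort(config: SyntheticConfig) -> list[CaseReport]:
    """Sample a background cohort with planted strategy-specific event rates.

    The event probability of a report exposed to strategy k is
    min(1, rho_k * baseline); unexposed reports use the baseline. All
    sampling is vectorized and fully reproducible from the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_background
    keys = list(config.ici_exposure)
    probs = np.array([config.ici_exposure[k] for k in keys] + [0.0])
    probs[-1] = 1.0 - probs[:-1].sum()
    exposure_idx = rng.choice(len(keys) + 1, size=n, p=probs)

    event_p = np.full(n, config.baseline_event_prob)
    for i, k in enumerate(keys):
        rho = config.planted_ratio.get(k, 1.0)
        event_p[exposure_idx == i] = min(1.0, rho * config.baseline_event_prob)
    events = rng.random(n) < event_p

    ages = np.clip(rng.normal(68.0, 10.0, n), 19.0, 95.0).round(1)
    age_missing = rng.random(n) < config.age_missing_rate
    sexes = np.where(rng.random(n) < 0.60, "M", "F")
    countries = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    country_missing = rng.random(n) < config.country_missing_rate
    reporters = rng.choice(_REPORTERS, size=n, p=_REPORTER_P)
    receipt_offsets = rng.integers(0, _WINDOW_DAYS + 1, size=n)
    organs = rng.choice(len(_ORGAN_TERMS), size=n, p=_ORGAN_P)
    outcome_idx = rng.choice(len(_OUTCOMES), size=n, p=_OUTCOME_P)
    ttos = np.maximum(
        1.0,
        rng.lognormal(math.log(config.onset_median_days), config.onset_log_sd, n),
    ).round()
    dates_missing = rng.random(n) < config.date_missing_rate

    reports: list[CaseReport] = []
    for i in range(n):
        pid = str(1_000_000 + i)
        receipt = _EPOCH + datetime.timedelta(days=int(receipt_offsets[i]))
        exposed = exposure_idx[i] < len(keys)
        has_dates = exposed and events[i] and not dates_missing[i]
        if has_dates:
            event_date = receipt - datetime.timedelta(days=30)
            start = event_date - datetime.timedelta(days=int(ttos[i]))
        else:
            event_date = None
            start = None
        if exposed:
            drugs = _strategy_drugs(keys[exposure_idx[i]], pid, start)
        else:
            drugs = [DrugRecord(primary_id=pid, drug_name_raw="PACLITAXEL",
                                role_code="PS")]
        reactions = (
            [ReactionRecord(primary_id=pid, pt=ITP_PT, event_onset_date=event_date)]
            if events[i]
            else []
        )
        reports.append(
            CaseReport(
                primary_id=pid,
                case_id="C" + pid,
                fda_receipt_date=receipt,
                age_years=None if age_missing[i] else float(ages[i]),
                sex=str(sexes[i]),
                country=None if country_missing[i] else str(countries[i]),
                reporter_type=str(reporters[i]),
                drugs=drugs,
                reactions=reactions,
                outcomes=[str(_OUTCOMES[outcome_idx[i]])] if events[i] else [],
                indications=[_ORGAN_TERMS[organs[i]]],
            )
        )
    if config.duplicate_rate > 0:
        reports = inject_duplicates(reports, config.duplicate_rate, config.seed + 1)
    return reports


def inject_duplicates(
    reports: Sequence[CaseReport], rate: float, seed: int
) -> list[CaseReport]:
    """Clone a fraction of reports as later case versions.

    Each clone keeps the CASEID, gets a fresh (larger) PRIMARYID and a later
    FDA receipt date, so deduplication must keep exactly the clones.
    """
    if not 0 <= rate < 1:
        raise ValueError("duplicate rate must lie in [0, 1)")
    if rate == 0 or not reports:
        return list(reports)
    rng = np.random.default_rng(seed)
    n_dup = int(round(rate * len(reports)))
    chosen = rng.choice(len(reports), size=n_dup, replace=False)
    max_pid = max(
        (int(r.primary_id) for r in reports if r.primary_id.isdigit()), default=0
    )
    out = list(reports)
    for j, idx in enumerate(sorted(chosen)):
        orig = reports[idx]
        pid = str(max_pid + 1 + j)
        clone = replace(
            orig,
            primary_id=pid,
            fda_receipt_date=orig.fda_receipt_date + datetime.timedelta(days=30),
            drugs=[replace(d, primary_id=pid) for d in orig.drugs],
            reactions=[replace(rx, primary_id=pid) for rx in orig.reactions],
            outcomes=list(orig.outcomes),
            indications=list(orig.indications),
        )
        out.append(clone)
    return out


# ---------------------------------------------------------------------------
# Deterministic in-study fixture
# ---------------------------------------------------------------------------


def _spread(lo: float, hi: float, n: int) -> list[int]:
    """n nondecreasing integers from lo to hi inclusive."""
    return [int(round(v)) for v in np.linspace(lo, hi, n)]


def _age_pools() -> dict[str, list[float]]:
    young = _spread(19, 59, 68) + [60, 60] + _spread(61, 64, 20)          # 90
    mid = (
        _spread(65, 68, 46) + [69, 69] + _spread(70, 75, 66)
        + [76, 76] + _spread(77, 85, 61)
    )                                                                      # 177
    old = [86, 87, 88, 89, 90, 91, 92]                                     # 7
    return {
        "18-65": [float(v) for v in young],
        "65-85": [float(v) for v in mid],
        ">85": [float(v) for v in old],
    }


def paper_tto_values() -> list[float]:
    """The 147 analyzable onset times, sorted ascending (days)."""
    values = (
        _spread(2, 16, 36) + [17, 17] + _spread(18, 30, 26)
        + _spread(31, 39, 9) + [42] + _spread(44, 58, 14)
        + _spread(62, 130, 21) + [135, 135] + _spread(140, 590, 36)
    )
    return [float(v) for v in values]


def _blocks(pairs: Sequence[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for value, count in pairs:
        out.extend([value] * count)
    return out


# (category, fatal count, non-fatal count) per variable; fatal cases are the
# first 62 of 345. Counts reproduce the published two-way tables. The country
# block as printed is internally inconsistent (its columns do not sum to the
# group sizes), so the non-fatal CN and pooled-country counts are reconciled
# to the group totals here and the country variable is not a reproduction
# surface.
_GENDER = (("M", 39, 172), ("F", 20, 78), (None, 3, 33))
_AGE_GROUP = (("18-65", 21, 69), ("65-85", 36, 141), (">85", 1, 6), (None, 4, 67))
_COUNTRY = (
    ("JP", 36, 115), ("US", 3, 72), ("FR", 2, 22), ("DE", 5, 15),
    ("CA", 4, 5), ("CN", 1, 9), ("IT", 11, 45),
)
_YEAR = (
    ("2012", 0, 2), ("2013", 2, 2), ("2014", 0, 2), ("2015", 0, 4),
    ("2016", 1, 12), ("2017", 5, 33), ("2018", 7, 36), ("2019", 14, 54),
    ("2020", 8, 37), ("2021", 15, 58), ("2022", 10, 43),
)
_STRATEGY = (
    ("ANTI_PD1", 42, 188), ("ANTI_PDL1", 7, 34),
    ("ANTI_CTLA4", 3, 16), ("COMBO", 10, 45),
)
_OUTCOME_BLOCK_FATAL = (("DE", 62),)
_OUTCOME_BLOCK_NONFATAL = (("LT", 47), ("HO", 108), ("DS", 1), ("OT", 126), ("", 1))
_ORGAN = (
    ("Lung", 29, 94), ("Skin", 13, 75), ("Bladder", 2, 17), ("Kidney", 3, 14),
    ("Stomach", 4, 10), ("Lymphoid", 2, 11), ("Pleura", 3, 7),
    ("Head and neck", 0, 6), ("Hematologic", 0, 5), ("Liver", 0, 5),
    ("Uterus", 0, 5), ("Brain", 2, 2), ("Esophagus", 0, 4), ("Breast", 0, 3),
    ("Ovary", 0, 3), ("Large intestine", 0, 1), ("Oropharynx", 0, 1),
    ("Prostate", 1, 0), ("Unspecified", 3, 3), (None, 0, 17),
)
_REPORTER = (("CN", 10, 32), ("MD", 32, 137), ("PH", 5, 23), ("OT", 15, 91))

# Agent pools consumed class-majorly within each strategy block.
_AGENT_POOLS = {
    "ANTI_PD1": _blocks(
        (("nivolumab", 115), ("pembrolizumab", 112), ("cemiplimab", 3))
    ),
    "ANTI_PDL1": _blocks((("atezolizumab", 23), ("avelumab", 6), ("durvalumab", 12))),
    "ANTI_CTLA4": _blocks((("ipilimumab", 19),)),
    "COMBO": _blocks(
        (("nivolumab+ipilimumab", 53), ("pembrolizumab+ipilimumab", 2))
    ),
}

_ORGAN_TERM = {
    "Lung": "Non-small cell lung cancer",
    "Skin": "Malignant melanoma",
    "Bladder": "Bladder cancer",
    "Kidney": "Renal cell carcinoma",
    "Stomach": "Gastric cancer",
    "Lymphoid": "Hodgkin's lymphoma",
    "Pleura": "Mesothelioma",
    "Head and neck": "Laryngeal cancer",
    "Hematologic": "Acute myeloid leukaemia",
    "Liver": "Hepatocellular carcinoma",
    "Uterus": "Endometrial cancer",
    "Brain": "Glioblastoma",
    "Esophagus": "Oesophageal carcinoma",
    "Breast": "Breast cancer",
    "Ovary": "Ovarian cancer",
    "Large intestine": "Colorectal cancer",
    "Oropharynx": "Oropharyngeal cancer",
    "Prostate": "Prostate cancer",
    "Unspecified": "Malignant neoplasm",
}

N_CASES = 345
N_FATAL = 62
N_TTO = 147


def gen_paper_fixture() -> list[CaseReport]:
    """Deterministic 345-report case series reproducing the published marginals.

    The published table prints only the two-way (category x fatality) counts,
    so the joint assignment across variables is fixed by a deterministic fill
    order: within the fatal block and then the non-fatal block, each
    variable's categories are laid out contiguously and assigned
    independently of the other variables. The first 147 reports in fixture
    order carry complete therapy/event dates, with onset times drawn from
    ``paper_tto_values``.
    """
    def seq(pairs) -> list:
        fatal = _blocks([(v, f) for v, f, _ in pairs])
        nonfatal = _blocks([(v, nf) for v, _, nf in pairs])
        assert len(fatal) == N_FATAL and len(fatal) + len(nonfatal) == N_CASES
        return fatal + nonfatal

    genders = seq(_GENDER)
    age_groups = seq(_AGE_GROUP)
    countries = seq(_COUNTRY)
    years = seq(_YEAR)
    strategies = seq(_STRATEGY)
    organs = seq(_ORGAN)
    reporters = seq(_REPORTER)
    outcomes = _blocks(_OUTCOME_BLOCK_FATAL) + _blocks(_OUTCOME_BLOCK_NONFATAL)

    pools = _age_pools()
    age_iter = {k: iter(v) for k, v in pools.items()}
    agent_iter = {k: iter(v) for k, v in _AGENT_POOLS.items()}
    tto_values = paper_tto_values()

    reports: list[CaseReport] = []
    for i in range(N_CASES):
        pid = str(100001 + i)
        year = int(years[i])
        receipt = datetime.date(year, 6, 15)
        has_tto = i < N_TTO
        if has_tto:
            tto = int(tto_values[i])
            event_date = receipt - datetime.timedelta(days=30)
            start = event_date - datetime.timedelta(days=tto)
        else:
            event_date = None
            start = None
        agent_key = next(agent_iter[strategies[i]])
        drugs = _strategy_drugs(agent_key, pid, start)
        group = age_groups[i]
        age = None if group is None else float(next(age_iter[group]))
        organ = organs[i]
        indications = [] if organ is None else [_ORGAN_TERM[organ]]
        reports.append(
            CaseReport(
                primary_id=pid,
                case_id="C" + pid,
                fda_receipt_date=receipt,
                age_years=age,
                sex=genders[i],
                country=countries[i],
                reporter_type=reporters[i],
                drugs=drugs,
                reactions=[
                    ReactionRecord(
                        primary_id=pid, pt=ITP_PT, event_onset_date=event_date
                    )
                ],
                outcomes=[outcomes[i]] if outcomes[i] else [],
                indications=indications,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Expression matrices with planted pathway-activity / reporting-ratio links
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionTruth:
    expression: pd.DataFrame            # genes x samples
    gene_set: list[str]
    sample_types: dict[str, str]        # sample id -> pseudo-cancer type
    type_ror: dict[str, float]          # planted per-type reporting ratio
    activity: dict[str, float]          # planted pathway activity per type


def gen_expression(
    seed: int,
    n_types: int = 17,
    samples_per_type: int = 8,
    n_genes: int = 200,
    set_size: int = 20,
    planted_rho: float = 0.8,
    activity_effect: float = 1.5,
) -> ExpressionTruth:
    """Expression matrix with a planted activity -> reporting-ratio link.

    Pathway-gene means are shifted per pseudo-cancer-type in proportion to a
    planted activity vector, and each type's reporting ratio is generated
    from a latent Gaussian copula with correlation ``planted_rho`` to that
    activity. ``planted_rho = 0`` plants a constant activity (null): scores
    then carry no type signal and the ratio is independent noise.
    """
    if n_types < 3 or n_genes < set_size:
        raise ValueError("need n_types >= 3 and n_genes >= set_size")
    rng = np.random.default_rng(seed)
    types = [f"T{i + 1:02d}" for i in range(n_types)]
    samples = [f"{t}_s{j}" for t in types for j in range(samples_per_type)]
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gene_set = genes[:set_size]

    if planted_rho == 0:
        activity = np.zeros(n_types)
        latent = rng.normal(size=n_types)
    else:
        activity = rng.normal(size=n_types)
        noise = rng.normal(size=n_types)
        latent = planted_rho * activity + math.sqrt(1 - planted_rho**2) * noise
    ror = np.exp(0.6 * latent + math.log(5.0))

    base = rng.normal(5.0, 1.0, size=(n_genes, len(samples)))
    for t_idx, t in enumerate(types):
        cols = slice(t_idx * samples_per_type, (t_idx + 1) * samples_per_type)
        base[:set_size, cols] += activity_effect * activity[t_idx]
    expression = pd.DataFrame(base, index=genes, columns=samples)
    return ExpressionTruth(
        expression=expression,
        gene_set=gene_set,
        sample_types={s: s.split("_")[0] for s in samples},
        type_ror={t: float(r) for t, r in zip(types, ror)},
        activity={t: float(a) for t, a in zip(types, activity)},
    )
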