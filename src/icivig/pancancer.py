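"""Pan-cancer stage: per-cancer-type reporting odds ratios within the ICI
cohort, single-sample gene-set enrichment scores, and their rank correlation.

The question this stage asks is which ICI-treated indication enriches for the
target event, so the 2x2 table for each cancer type is built *within* the ICI
cohort: a = reports of that type with the event, b = that type without,
c = other types with, d = other types without. Cancer-level RORs are then
correlated (Spearman) with per-type summaries of single-sample enrichment
scores computed from a gene x sample expression matrix.

The enrichment scorer is the standard rank-weighted running-sum statistic:
per sample, genes are ranked descending; walking down the ranking the running
sum gains |rank|^w (normalized over in-set genes, w = 0.25 by default) at each
in-set gene and loses 1/(N - m) at each out-of-set gene; the score is the sum
of the running statistic over all positions, min-max normalized across
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CaseReport, report_organ
from .signals import ContingencyTable, SignalResult, evaluate_signal
from ._dictionaries import ORGAN_TO_CANCER_TYPE

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_EXPONENT = 0.25


def ssgsea_score(
    expression: pd.DataFrame,
    gene_set: Sequence[str],
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    normalize: bool = True,
) -> pd.Series:
    """Single-sample enrichment score per sample (columns of ``expression``).

    Only the ranks of each sample's expression values matter, so the scores
    are invariant under any strictly monotone per-sample transform. Ties are
    broken deterministically by gene order. Raises if the gene set is empty
    or shares no genes with the expression matrix.
    """
    genes = list(expression.index)
    in_set = np.array([g in set(gene_set) for g in genes])
    m = int(in_set.sum())
    if len(gene_set) == 0:
        raise ValueError("ssgsea_score: empty gene set")
    if m == 0:
        raise ValueError("ssgsea_score: gene set shares no genes with the matrix")
    n_genes = len(genes)
    values = expression.to_numpy(dtype=float)
    scores = np.empty(expression.shape[1])
    for j in range(expression.shape[1]):
        order = np.argsort(-values[:, j], kind="stable")
        ranks = np.arange(n_genes, 0, -1, dtype=float)  # top gene has rank N
        set_mask = in_set[order]
        weights = np.abs(ranks) ** weight_exponent
        inc = np.where(set_mask, weights, 0.0)
        inc_total = inc.sum()
        if n_genes == m:
            # Whole universe in the set: no decrements, running sum is the
            # normalized cumulative weight for every sample.
            running = np.cumsum(inc / inc_total)
        else:
            dec = np.where(set_mask, 0.0, 1.0 / (n_genes - m))
            running = np.cumsum(inc / inc_total - dec)
        scores[j] = running.sum()
    out = pd.Series(scores, index=expression.columns, name="es")
    if normalize:
        span = out.max() - out.min()
        if span > 0:
            out = (out - out.min()) / span
        else:
            out = pd.Series(0.0, index=out.index, name="es")
    return out


def summarize_scores_by_type(
    scores: pd.DataFrame | pd.Series, sample_types: Mapping[str, str]
) -> pd.DataFrame:
    """Median enrichment score per (feature, cancer type).

    ``scores`` is feature x sample (a Series is treated as one feature);
    ``sample_types`` maps sample id to cancer-type label.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame().T
    types = pd.Series({s: sample_types[s] for s in scores.columns})
    return scores.T.groupby(types).median().T


@dataclass(slots=True)
class CancerRORRow:
    cancer_type: str
    signal: SignalResult
    table: ContingencyTable


def cancer_ror(
    ici_cohort: Sequence[CaseReport],
    case_flags: Mapping[str, bool],
    organ_map: Mapping[str, str] = ORGAN_TO_CANCER_TYPE,
) -> list[CancerRORRow]:
    """Reporting odds ratio of the event per cancer type within the ICI cohort.

    Reports whose indication organ has no cancer-type mapping (unspecified or
    missing indications) are left out of every type's index margin but stay in
    the comparator, so each row's cells still sum to the cohort size.
    """
    if not ici_cohort:
        raise ValueError("cancer_ror: empty ICI cohort")
    type_counts: dict[str, list[int]] = {}
    n_cases = 0
    n_total = len(ici_cohort)
    for r in ici_cohort:
        is_case = bool(case_flags.get(r.primary_id, False))
        n_cases += is_case
        ctype = organ_map.get(report_organ(r))
        if ctype is None:
            continue
        cell = type_counts.setdefault(ctype, [0, 0])
        cell[1 if is_case else 0] += 1
    rows: list[CancerRORRow] = []
    for ctype in sorted(type_counts):
        noncase, case = type_counts[ctype]
        if case + noncase == 0:
            logger.warning("cancer_ror: no reports for %s; omitted", ctype)
            continue
        t = ContingencyTable(
            a=case,
            b=noncase,
            c=n_cases - case,
            d=n_total - (case + noncase) - (n_cases - case),
        )
        rows.append(CancerRORRow(cancer_type=ctype, signal=evaluate_signal(t), table=t))
    return rows


@dataclass(slots=True)
class CorrelationResult:
    feature: str
    rho: float
    p: float
    n: int


def correlate_ror_scores(
    cancer_rors: Mapping[str, float],
    per_cancer_scores: pd.DataFrame | Mapping[str, Mapping[str, float]],
) -> list[CorrelationResult]:
    """Spearman correlation of per-type RORs with each score feature.

    Ties get midranks; the p-value is the asymptotic t approximation. The
    pairing is restricted to cancer types present in both inputs, and at
    least three shared types are required.
    """
    if not isinstance(per_cancer_scores, pd.DataFrame):
        per_cancer_scores = pd.DataFrame(per_cancer_scores).T
    shared = [c for c in per_cancer_scores.columns if c in cancer_rors]
    if len(shared) < 3:
        raise ValueError(
            f"correlate_ror_scores: only {len(shared)} shared cancer types (< 3)"
        )
    ror_vec = np.array([cancer_rors[c] for c in shared], dtype=float)
    results: list[CorrelationResult] = []
    for feature, row in per_cancer_scores.iterrows():
        rho, p = stats.spearmanr(ror_vec, row[shared].to_numpy(dtype=float))
        results.append(
            CorrelationResult(feature=str(feature), rho=float(rho), p=float(p),
                              n=len(shared))
        )
    return results


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name, description, then gene symbols."""
    sets: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
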