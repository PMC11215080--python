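import numpy as np
import pandas as pd
import pytest

from icivig import pancancer
from icivig.pancancer import correlate_ror_scores, ssgsea_score

from conftest import make_report


def ssgsea_oracle_one_sample(values, in_set, w=0.25):
    """Step-by-step running-sum evaluation for one sample, written plainly."""
    n = len(values)
    order = np.argsort(-np.asarray(values), kind="stable")
    ranks = list(range(n, 0, -1))
    m = sum(in_set)
    norm = sum(abs(ranks[i]) ** w for i in range(n) if in_set[order[i]])
    running, total = 0.0, 0.0
    for i in range(n):
        if in_set[order[i]]:
            running += abs(ranks[i]) ** w / norm
        else:
            running -= 1.0 / (n - m)
        total += running
    return total


class TestSsgsea:
    def test_whole_universe_set_scores_equal_everywhere(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(6, 4)),
                            index=[f"g{i}" for i in range(6)],
                            columns=list("abcd"))
        scores = ssgsea_score(expr, list(expr.index))
        assert np.allclose(scores, scores.iloc[0])

    def test_four_gene_universe_matches_hand_oracle(self):
        expr = pd.DataFrame(
            {"s1": [4.0, 3.0, 2.0, 1.0], "s2": [1.0, 4.0, 3.0, 2.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        raw = ssgsea_score(expr, ["g1", "g3"], normalize=False)
        for col in expr.columns:
            expected = ssgsea_oracle_one_sample(
                expr[col].to_numpy(), [g in ("g1", "g3") for g in expr.index]
            )
            assert raw[col] == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_monotone_transform_of_one_sample(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(5, 1, size=(50, 6)),
                            index=[f"g{i}" for i in range(50)],
                            columns=[f"s{i}" for i in range(6)])
        gene_set = [f"g{i}" for i in range(0, 10)]
        base = ssgsea_score(expr, gene_set)
        transformed = expr.copy()
        transformed["s0"] = np.exp(transformed["s0"] / 3.0)
        assert np.allclose(base, ssgsea_score(transformed, gene_set))

    def test_empty_or_disjoint_gene_set_is_fatal(self):
        expr = pd.DataFrame({"s": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            ssgsea_score(expr, [])
        with pytest.raises(ValueError):
            ssgsea_score(expr, ["zz"])


def _ici_cohort_with_rates(rates, per_type=40, seed=0):
    """ICI reports whose indication organ maps to a cancer type, with the
    given per-type event probabilities."""
    organs = {
        "SKCM": "Malignant melanoma",
        "LUNG": "Non-small cell lung cancer",
        "BLCA": "Bladder cancer",
        "KIRC": "Renal cell carcinoma",
        "STAD": "Gastric cancer",
    }
    rng = np.random.default_rng(seed)
    reports = []
    i = 0
    for ctype, rate in rates.items():
        for _ in range(per_type):
            i += 1
            is_case = rng.random() < rate
            reports.append(
                make_report(
                    pid=str(i),
                    reactions=("Immune thrombocytopenia",) if is_case else ("Pyrexia",),
                    indications=(organs[ctype],),
                )
            )
    return reports


class TestCancerRor:
    def test_cells_sum_to_cohort_size(self):
        from icivig.cohort import select_cases

        cohort = _ici_cohort_with_rates(
            {"SKCM": 0.5, "LUNG": 0.2, "BLCA": 0.2, "KIRC": 0.1}
        )
        rows = pancancer.cancer_ror(cohort, select_cases(cohort))
        for row in rows:
            assert row.table.n == len(cohort)

    def test_identical_tables_give_identical_rors(self):
        from icivig.cohort import select_cases, CaseReport

        cohort = []
        for j, organ in enumerate(["Malignant melanoma", "Gastric cancer"]):
            for i in range(20):
                cohort.append(
                    make_report(
                        pid=f"{j}_{i}",
                        reactions=("Immune thrombocytopenia",) if i < 5 else ("Pyrexia",),
                        indications=(organ,),
                    )
                )
        rows = pancancer.cancer_ror(cohort, select_cases(cohort))
        assert len(rows) == 2
        assert rows[0].signal.ror == pytest.approx(rows[1].signal.ror)
        assert rows[0].signal.ror == pytest.approx(1.0)

    def test_empty_cohort_is_fatal(self):
        with pytest.raises(ValueError):
            pancancer.cancer_ror([], {})


class TestCorrelate:
    def test_perfectly_monotone_pairs(self):
        rors = {f"T{i}": float(i) for i in range(1, 6)}
        scores = pd.DataFrame(
            {f"T{i}": [np.log(i)] for i in range(1, 6)}, index=["path"]
        )
        (res,) = correlate_ror_scores(rors, scores)
        assert res.rho == pytest.approx(1.0)
        reversed_scores = -scores
        (res,) = correlate_ror_scores(rors, reversed_scores)
        assert res.rho == pytest.approx(-1.0)

    def test_midrank_tie_handling_matches_hand_computation(self):
        # y has one tie; Pearson on midranks gives sqrt(9.5/10)
        rors = {f"T{i}": float(i) for i in range(1, 6)}
        scores = pd.DataFrame(
            {"T1": [1.0], "T2": [2.0], "T3": [2.0], "T4": [4.0], "T5": [5.0]},
            index=["path"],
        )
        (res,) = correlate_ror_scores(rors, scores)
        assert res.rho == pytest.approx(np.sqrt(9.5 / 10.0), rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        rors = {f"T{i}": float(v) for i, v in enumerate(rng.random(10))}
        vals = rng.random(10)
        scores = pd.DataFrame([vals], index=["path"], columns=list(rors))
        (a,) = correlate_ror_scores(rors, scores)
        (b,) = correlate_ror_scores(
            {k: np.exp(3 * v) for k, v in rors.items()}, scores
        )
        assert a.rho == pytest.approx(b.rho)

    def test_fewer_than_three_shared_types_is_fatal(self):
        with pytest.raises(ValueError):
            correlate_ror_scores(
                {"A": 1.0, "B": 2.0},
                pd.DataFrame({"A": [0.1], "B": [0.2]}, index=["path"]),
            )
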