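import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from icivig import signals
from icivig.signals import ContingencyTable, UndefinedStatistic


# --- independent direct-arithmetic oracle (exact rationals where possible) ---

def oracle(a, b, c, d):
    n = a + b + c + d
    out = {}
    if min(a, b, c, d) > 0:
        ror = Fraction(a * d, b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        out["ror"] = float(ror)
        out["ror_ci"] = (
            math.exp(math.log(float(ror)) - 1.96 * se),
            math.exp(math.log(float(ror)) + 1.96 * se),
        )
    if c > 0 and (a + b) > 0:
        out["prr"] = float(Fraction(a, a + b) / Fraction(c, c + d))
        out["chi2"] = float(
            Fraction((a * d - b * c) ** 2 * n, (a + b) * (c + d) * (a + c) * (b + d))
        )
    if a > 0:
        rrr = Fraction(a * n, (a + c) * (a + b))
        out["ebgm"] = float(rrr)
        out["ic"] = math.log2(float(rrr))
        if min(a, b, c, d) > 0:
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            out["ebgm05"] = math.exp(math.log(float(rrr)) - 1.64 * se)
            if out["ic"] > 0:
                out["ic025"] = math.exp(math.log(out["ic"]) - 1.96 * se)
    return out


def test_reference_table_matches_hand_arithmetic():
    t = ContingencyTable(20, 80, 10, 890)
    ror, ci = signals.compute_ror(t)
    assert ror == pytest.approx(22.25)
    se = math.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 890)
    assert ci == pytest.approx(
        (math.exp(math.log(22.25) - 1.96 * se), math.exp(math.log(22.25) + 1.96 * se))
    )
    prr, chi2 = signals.compute_prr(t)
    assert prr == pytest.approx(18.0)
    assert chi2 == pytest.approx(17000**2 * 1000 / (100 * 900 * 30 * 970))
    ic, ic025 = signals.compute_ic(t)
    assert ic == pytest.approx(math.log2(20 * 1000 / (30 * 100)))
    ebgm, ebgm05 = signals.compute_ebgm(t)
    assert ebgm == pytest.approx(20 * 1000 / (30 * 100))
    assert ebgm05 == pytest.approx(math.exp(math.log(ebgm) - 1.64 * se))
    res = signals.evaluate_signal(t)
    assert res.joint_positive and all(res.flags.values())


def test_independence_table_is_null_everywhere():
    t = ContingencyTable(5, 5, 5, 5)
    ror, ci = signals.compute_ror(t)
    assert ror == 1.0 and ci[0] < 1.0 < ci[1]
    prr, chi2 = signals.compute_prr(t)
    assert prr == 1.0 and chi2 == 0.0
    ic, ic025 = signals.compute_ic(t)
    assert ic == 0.0 and ic025 is None
    res = signals.evaluate_signal(t)
    assert not res.joint_positive and not any(res.flags.values())


def test_zero_cells_raise_named_undefined_errors():
    with pytest.raises(UndefinedStatistic, match="cell a"):
        signals.compute_ror(ContingencyTable(0, 10, 5, 85))
    with pytest.raises(UndefinedStatistic, match="cell c"):
        signals.compute_prr(ContingencyTable(2, 8, 0, 90))
    with pytest.raises(UndefinedStatistic, match="cell a"):
        signals.compute_ic(ContingencyTable(0, 10, 5, 85))


def test_prr_defined_with_zero_b_cell():
    # b = 0 is legal for PRR though not for ROR
    prr, chi2 = signals.compute_prr(ContingencyTable(2, 0, 1, 997))
    assert prr == pytest.approx((2 / 2) / (1 / 998))
    with pytest.raises(UndefinedStatistic):
        signals.compute_ror(ContingencyTable(2, 0, 1, 997))


def test_single_case_never_joint_positive():
    # strong disproportionality but a = 1 fails the case-count threshold
    res = signals.evaluate_signal(ContingencyTable(1, 1, 1, 10_000))
    assert not res.flags["ror"] and not res.flags["prr"]
    assert not res.joint_positive


valid_tables = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
)


@settings(max_examples=300, deadline=None)
@given(valid_tables)
def test_ic_is_log2_of_ebgm(cells):
    t = ContingencyTable(*cells)
    ic, _ = signals.compute_ic(t)
    ebgm, _ = signals.compute_ebgm(t)
    assert 2**ic == pytest.approx(ebgm, rel=1e-12)


@settings(max_examples=200, deadline=None)
@given(valid_tables)
def test_statistics_match_oracle(cells):
    t = ContingencyTable(*cells)
    exp = oracle(*cells)
    res = signals.evaluate_signal(t)
    assert res.ror == pytest.approx(exp["ror"], rel=1e-12)
    assert res.prr == pytest.approx(exp["prr"], rel=1e-12)
    assert res.chi2 == pytest.approx(exp["chi2"], rel=1e-12)
    assert res.ic == pytest.approx(exp["ic"], rel=1e-12, abs=1e-12)
    assert res.ebgm == pytest.approx(exp["ebgm"], rel=1e-12)


@settings(max_examples=200, deadline=None)
@given(st.integers(2, 50), st.integers(1, 200), st.integers(1, 50), st.integers(1, 2000))
def test_monotone_in_case_count_at_fixed_margins(a, b, c, d):
    t1 = ContingencyTable(a, b + 1, c, d)
    t2 = ContingencyTable(a + 1, b, c, d)
    assert signals.compute_ror(t2)[0] > signals.compute_ror(t1)[0]
    assert signals.compute_prr(t2)[0] > signals.compute_prr(t1)[0]
    assert signals.compute_ic(t2)[0] > signals.compute_ic(t1)[0]
    assert signals.compute_ebgm(t2)[0] > signals.compute_ebgm(t1)[0]


def test_null_table_with_ad_equal_bc():
    for cells in [(2, 4, 3, 6), (10, 20, 30, 60), (7, 7, 7, 7)]:
        t = ContingencyTable(*cells)
        assert signals.compute_ror(t)[0] == pytest.approx(1.0)
        assert signals.compute_prr(t)[0] == pytest.approx(1.0)
        assert signals.compute_ic(t)[0] == pytest.approx(0.0, abs=1e-12)
        assert signals.compute_ebgm(t)[0] == pytest.approx(1.0)


class TestBuildContingency:
    def test_partition_of_six_reports(self):
        from conftest import make_report

        reports = [
            make_report(pid="1", drugs=("NIVOLUMAB",)),   # index + event
            make_report(pid="2", drugs=("NIVOLUMAB",)),   # index + event
            make_report(pid="3", drugs=("NIVOLUMAB",), reactions=("Pyrexia",)),
            make_report(pid="4", drugs=("ASPIRIN",)),      # other + event
            make_report(pid="5", drugs=("ASPIRIN",), reactions=("Pyrexia",)),
            make_report(pid="6", drugs=("ASPIRIN",), reactions=()),
        ]
        from icivig.cohort import select_cases

        flags = select_cases(reports)
        is_index = lambda r: r.drugs[0].drug_name_raw == "NIVOLUMAB"  # noqa: E731
        t = signals.build_contingency(reports, is_index, flags)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
        assert t.n == len(reports)

    def test_empty_background_is_fatal(self):
        with pytest.raises(ValueError):
            signals.build_contingency([], lambda r: True, lambda r: True)


class TestScanStrategies:
    def test_fixture_row_counts_match_planted_strategy_table(self, paper_fixture):
        results = signals.scan_strategies(paper_fixture)
        n = {k: v.n_cases for k, v in results.items()}
        assert n["Total"] == 345
        assert n["Anti-PD-1"] == 230 and n["Anti-PD-L1"] == 41
        assert n["Anti-CTLA-4"] == 19
        assert n["Nivolumab"] == 115 and n["Pembrolizumab"] == 112
        assert n["Nivolumab + ipilimumab"] == 53
        assert n["Pembrolizumab + ipilimumab"] == 2

    def test_structure_total_classes_agents_pairs(self, paper_fixture):
        results = signals.scan_strategies(paper_fixture)
        # 1 Total + 3 classes + 7 agents present + 2 pairs present
        assert len(results) == 1 + 3 + 7 + 2

    def test_no_cases_anywhere_gives_not_applicable_rows(self):
        from conftest import make_report

        reports = [
            make_report(pid=str(i), reactions=("Pyrexia",)) for i in range(10)
        ] + [make_report(pid="99", drugs=("ASPIRIN",), reactions=("Pyrexia",))]
        results = signals.scan_strategies(reports)
        for res in results.values():
            assert res.n_cases == 0 and not res.joint_positive
            assert res.ror is None
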