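import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icivig import onset

from conftest import make_report


def logrank_oracle_two_groups(g1, g2):
    """Hypergeometric-increment log-rank sums, written independently."""
    all_times = sorted(set(g1) | set(g2))
    u = 0.0
    v = 0.0
    for t in all_times:
        n1 = sum(1 for x in g1 if x >= t)
        n2 = sum(1 for x in g2 if x >= t)
        d1 = sum(1 for x in g1 if x == t)
        d2 = sum(1 for x in g2 if x == t)
        n, d = n1 + n2, d1 + d2
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u * u / v


class TestComputeTto:
    def test_calendar_arithmetic(self):
        r = make_report(
            therapy_start=datetime.date(2020, 1, 1),
            event_date=datetime.date(2020, 2, 12),
        )
        tto, reason = onset.compute_tto(r)
        assert tto == 42.0 and reason == "ok"

    def test_event_before_start_is_excluded(self):
        r = make_report(
            therapy_start=datetime.date(2020, 3, 1),
            event_date=datetime.date(2020, 2, 1),
        )
        assert onset.compute_tto(r) == (None, "non-positive TTO")

    def test_missing_therapy_date_is_excluded(self):
        r = make_report(event_date=datetime.date(2020, 2, 1))
        assert onset.compute_tto(r) == (None, "no therapy date")

    def test_missing_event_date_is_excluded(self):
        r = make_report(therapy_start=datetime.date(2020, 1, 1))
        assert onset.compute_tto(r) == (None, "no event date")

    def test_imprecise_event_date_is_excluded(self):
        r = make_report(
            therapy_start=datetime.date(2020, 1, 1),
            event_date=datetime.date(2020, 2, 1),
        )
        r.reactions[0].onset_imprecise = True
        assert onset.compute_tto(r)[1] == "imprecise event date"

    def test_analyzable_plus_excluded_equals_case_count(self, paper_fixture):
        records, excluded = onset.onset_records(paper_fixture)
        assert len(records) + len(excluded) == len(paper_fixture)


class TestBinTto:
    @pytest.mark.parametrize(
        "tto, label",
        [(1, "(0,30]"), (30, "(0,30]"), (31, "(30,60]"), (60, "(30,60]"),
         (90, "(60,90]"), (180, "(90,180]"), (200, ">180")],
    )
    def test_boundaries_right_closed(self, tto, label):
        assert onset.bin_tto(tto) == label

    def test_nonpositive_is_fatal(self):
        with pytest.raises(ValueError):
            onset.bin_tto(0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.5, 1000), min_size=1, max_size=50))
    def test_binning_partitions(self, ttos):
        labels = [onset.bin_tto(t) for t in ttos]
        assert len(labels) == len(ttos)
        assert set(labels) <= set(onset.TTO_BIN_LABELS)


class TestKmCurve:
    def test_single_event(self):
        curve = onset.km_curve([5])
        assert curve.probability_at(4.9) == 1.0
        assert curve.probability_at(5) == 0.0

    def test_product_limit_with_ties(self):
        curve = onset.km_curve([2, 4, 4, 7])
        assert curve.probability_at(2) == pytest.approx(0.75)
        assert curve.probability_at(4) == pytest.approx(0.25)
        assert curve.probability_at(7) == pytest.approx(0.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.1, 500), min_size=1, max_size=60))
    def test_equals_one_minus_ecdf_without_censoring(self, ttos):
        curve = onset.km_curve(ttos)
        arr = np.asarray(ttos)
        for t, s in zip(curve.times, curve.survival):
            ecdf = np.mean(arr <= t)
            assert s == pytest.approx(1 - ecdf, abs=1e-12)

    def test_monotone_nonincreasing_reaching_zero(self, paper_fixture):
        from icivig.synthgen import paper_tto_values

        curve = onset.km_curve(paper_tto_values())
        assert np.all(np.diff(curve.survival) <= 0)
        assert curve.survival[-1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_is_fatal(self):
        with pytest.raises(ValueError):
            onset.km_curve([])


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        g = [3.0, 8.0, 15.0, 40.0]
        stat, p = onset.logrank_test([g, list(g)])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_hand_oracle(self):
        g1, g2 = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        stat, p = onset.logrank_test([g1, g2])
        assert stat == pytest.approx(logrank_oracle_two_groups(g1, g2), rel=1e-6)
        assert p < 0.05

    def test_label_order_invariance(self):
        g1, g2, g3 = [1.0, 5.0], [2.0, 9.0], [4.0, 11.0]
        _, p_a = onset.logrank_test([g1, g2, g3])
        _, p_b = onset.logrank_test([g3, g1, g2])
        assert p_a == pytest.approx(p_b)

    def test_empty_group_is_fatal(self):
        with pytest.raises(ValueError):
            onset.logrank_test([[1.0], []])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = onset.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)

    def test_hand_ranked_formula(self):
        # ranks 1..4, R1 = 3, R2 = 7 -> H = 0.6 * 29 - 15 = 2.4
        h, _ = onset.kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)

    def test_rank_invariance_under_monotone_transform(self):
        g1, g2 = [1.0, 3.0, 7.0], [2.0, 9.0, 20.0]
        h1, _ = onset.kruskal_wallis([g1, g2])
        h2, _ = onset.kruskal_wallis(
            [list(np.exp(g1)), list(np.exp(g2))]
        )
        assert h1 == pytest.approx(h2)

    def test_all_identical_values_convention(self):
        h, p = onset.kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)


class TestMedianIqr:
    def test_three_values_type7(self):
        med, q1, q3 = onset.median_iqr([17, 42, 135])
        assert (med, q1, q3) == (42.0, 29.5, 88.5)

    def test_single_value(self):
        assert onset.median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_permutation_invariance(self):
        vals = [5.0, 1.0, 9.0, 3.0, 22.0]
        assert onset.median_iqr(vals) == onset.median_iqr(sorted(vals, reverse=True))

    def test_empty_is_fatal(self):
        with pytest.raises(ValueError):
            onset.median_iqr([])
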