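"""Contingency, rank and survival statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecsubtype.stats import (ContingencyTable, SurvivalRecord, chi_square_test,
                             km_estimate, logrank_test, rank_test)


def _pearson_oracle(table):
    """Brute-force sum of (O-E)^2/E with expectations from the margins."""
    arr = np.asarray(table, dtype=float)
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row @ col / arr.sum()
    return float(((arr - expected) ** 2 / expected).sum())


class TestChiSquare:
    def test_tp53_by_histology_table(self):
        # serous tumors carry more TP53 mutations: [[24, 8], [59, 5]]
        stat, df, p = chi_square_test([[24, 8], [59, 5]])
        assert stat == pytest.approx(5.383, abs=5e-3)
        assert df == 1
        assert p == pytest.approx(0.0203, abs=5e-4)

    def test_pten_by_histology_is_highly_significant(self):
        stat, df, p = chi_square_test([[53, 0], [30, 13]])
        assert p < 0.001

    def test_proportional_rows_give_zero(self):
        stat, df, p = chi_square_test([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @given(st.lists(st.lists(st.integers(1, 50), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
                        lambda rows: len({len(r) for r in rows}) == 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, rows):
        stat, df, p = chi_square_test(rows)
        assert stat == pytest.approx(_pearson_oracle(rows), abs=1e-12)
        assert df == (len(rows) - 1) * (len(rows[0]) - 1)

    def test_zero_margin_is_named(self):
        with pytest.raises(ValueError, match="PTEN-"):
            chi_square_test(ContingencyTable.from_lists(
                [[5, 3], [0, 0]], row_labels=("PTEN+", "PTEN-")))

    def test_yates_correction_available(self):
        stat_none, _, _ = chi_square_test([[24, 8], [59, 5]], correction="none")
        stat_yates, _, _ = chi_square_test([[24, 8], [59, 5]], correction="yates")
        assert stat_yates < stat_none


class TestRankTests:
    def test_two_group_extreme_ranks_match_enumeration_oracle(self):
        """{1,2,3} vs {4,5,6}: exact two-sided p over all 20 assignments."""
        stat, p = rank_test([[1, 2, 3], [4, 5, 6]])
        # enumeration oracle: rank-sum of group 1 over all C(6,3) splits
        pooled = [1, 2, 3, 4, 5, 6]
        observed = sum([1, 2, 3])
        sums = [sum(c) for c in itertools.combinations(pooled, 3)]
        lo = sum(1 for s in sums if s <= observed) / len(sums)
        exact_two_sided = min(1.0, 2 * lo)  # symmetric null distribution
        assert p == pytest.approx(exact_two_sided)

    def test_identical_groups_are_not_significant(self):
        stat, p = rank_test([[5, 6, 7, 8, 9]] * 3)
        assert p > 0.95

    def test_kruskal_for_four_groups_detects_shift(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1, 40) for loc in (0, 0, 0, 2)]
        stat, p = rank_test([g.tolist() for g in groups])
        assert p < 1e-6

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            rank_test([[1, 2], []])


class TestKaplanMeier:
    def test_half_survival_after_one_of_two_events(self):
        recs = [SurvivalRecord("a", 1.0, 1), SurvivalRecord("b", 5.0, 0)]
        km = km_estimate(recs)
        assert km.at(1.0) == pytest.approx(0.5)

    def test_three_events_step_function_and_median(self):
        recs = [SurvivalRecord(s, t, 1) for s, t in (("a", 1), ("b", 2), ("c", 3))]
        km = km_estimate(recs)
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(2) == pytest.approx(1 / 3)
        assert km.at(3) == pytest.approx(0.0)
        assert km.median == 2

    def test_censoring_after_events_at_same_time(self):
        # subject censored at t stays at risk for the event at t
        recs = [SurvivalRecord("a", 2.0, 1), SurvivalRecord("b", 2.0, 0),
                SurvivalRecord("c", 4.0, 0)]
        km = km_estimate(recs)
        assert km.at(2.0) == pytest.approx(2 / 3)

    def test_no_events_curve_stays_at_one(self):
        recs = [SurvivalRecord(str(i), float(i + 1), 0) for i in range(5)]
        km = km_estimate(recs)
        assert km.at(100.0) == 1.0
        assert km.median is None

    def test_curve_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        recs = [SurvivalRecord(str(i), float(t), int(e))
                for i, (t, e) in enumerate(zip(rng.exponential(10, 50) + 0.1,
                                               rng.integers(0, 2, 50)))]
        km = km_estimate(recs)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.at(0.0) == 1.0


def _two_group_logrank_oracle(times1, times2):
    """Direct O-E summation over distinct event times (no censoring)."""
    events = sorted(set(times1) | set(times2))
    O1 = E1 = V = 0.0
    for t in events:
        n1 = sum(1 for x in times1 if x >= t)
        n2 = sum(1 for x in times2 if x >= t)
        d1 = sum(1 for x in times1 if x == t)
        d2 = sum(1 for x in times2 if x == t)
        n, d = n1 + n2, d1 + d2
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        recs = ([SurvivalRecord(f"a{i}", float(i + 1), 1, group="A") for i in range(5)]
                + [SurvivalRecord(f"b{i}", float(i + 1), 1, group="B") for i in range(5)])
        res = logrank_test(recs)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        t1, t2 = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        recs = ([SurvivalRecord(f"a{i}", t, 1, group="A") for i, t in enumerate(t1)]
                + [SurvivalRecord(f"b{i}", t, 1, group="B") for i, t in enumerate(t2)])
        res = logrank_test(recs)
        assert res.statistic == pytest.approx(_two_group_logrank_oracle(t1, t2),
                                              abs=1e-9)
        assert res.df == 1

    def test_invariance_to_relabeling_and_time_rescaling(self):
        rng = np.random.default_rng(8)
        recs = [SurvivalRecord(str(i), float(t) + 0.1, int(e), group=g)
                for i, (t, e, g) in enumerate(zip(
                    rng.exponential(20, 60), rng.integers(0, 2, 60),
                    rng.choice(["A", "B", "C"], 60)))]
        base = logrank_test(recs)
        relabeled = [SurvivalRecord(r.sample_id, r.time, r.event,
                                    group={"A": "Z", "B": "Y", "C": "X"}[r.group])
                     for r in recs]
        rescaled = [SurvivalRecord(r.sample_id, r.time * 12.0, r.event,
                                   group=r.group) for r in recs]
        assert logrank_test(relabeled).statistic == pytest.approx(base.statistic)
        assert logrank_test(rescaled).statistic == pytest.approx(base.statistic)

    def test_fully_censored_input_warns_and_returns_null(self):
        recs = [SurvivalRecord(str(i), float(i + 1), 0, group="AB"[i % 2])
                for i in range(6)]
        res = logrank_test(recs)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([SurvivalRecord("a", 1.0, 1, group="A")])
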