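import numpy as np
import pandas as pd
import pytest

from rankgrade import (
    SimulationConfig,
    classify_matrix,
    confusion_table,
    km_curve,
    logrank_test,
    overall_accuracy_g1g3,
    published_cohort_tables,
    round_percentage,
    simulate_cohort,
    stratify_g2,
)
from rankgrade.evaluate import ConfusionTable


def table_from_counts(g1_row, g3_row):
    counts = pd.DataFrame(
        [g1_row, g3_row],
        index=pd.Index(["G1", "G3"], name="genomic"),
        columns=pd.Index(["G1", "G2", "G3"], name="histological"),
    )
    return ConfusionTable(counts=counts)


class TestConfusionTable:
    def test_counting_matches_brute_force(self):
        rng = np.random.default_rng(8)
        n = 60
        ids = [f"s{i}" for i in range(n)]
        genomic = pd.Series(rng.choice(["G1", "G3"], size=n), index=ids)
        histo = pd.Series(rng.choice(["G1", "G2", "G3"], size=n), index=ids)
        table = confusion_table(genomic, histo)
        for g in ("G1", "G3"):
            for h in ("G1", "G2", "G3"):
                expected = sum(
                    1 for i in ids if genomic[i] == g and histo[i] == h
                )
                assert table.counts.loc[g, h] == expected
        assert table.counts.to_numpy().sum() == n
        # order permutation changes nothing
        perm = list(reversed(ids))
        table2 = confusion_table(genomic.loc[perm], histo.loc[perm])
        assert table2.counts.equals(table.counts)

    def test_missing_histology_excluded_and_counted(self):
        genomic = pd.Series({"a": "G1", "b": "G3", "c": "G1"})
        histo = pd.Series({"a": "G1", "b": "G3"})
        table = confusion_table(genomic, histo)
        assert table.counts.to_numpy().sum() == 2 and table.n_excluded == 1

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError, match="no samples"):
            confusion_table(pd.Series({"a": "G1"}), pd.Series({"b": "G1"}))

    def test_column_percentage_convention(self):
        # printed-style column: 63 vs 5 -> 93% and 7.4%
        table = table_from_counts([63, 0, 0], [5, 0, 1])
        pct = table.column_percentages
        assert pct.loc["G1", "G1"] == 93.0 and pct.loc["G3", "G1"] == 7.4

    def test_degenerate_single_cell(self):
        table = table_from_counts([0, 0, 0], [0, 0, 10])
        assert table.column_percentages.loc["G3", "G3"] == 100.0


class TestPublishedTables:
    """The evaluate conventions reproduce every printed cell of the published table."""

    EXPECTED_PCT = {
        "Uppsala": [[93, 62, 7.3], [7.4, 38, 93]],
        "Stockholm": [[93, 76, 15], [7.1, 24, 85]],
        "Guys Hospital": [[94, 43, 0], [5.9, 57, 100]],
        "Oxford": [[83, 48, 7.1], [17, 52, 93]],
        "NKI": [[85, 67, 26], [15, 33, 74]],
    }
    EXPECTED_ACC = {"Stockholm": 88, "Guys Hospital": 97, "Oxford": 88, "NKI": 78}

    def test_column_percentages(self):
        for cohort, table in published_cohort_tables().items():
            got = table.column_percentages.to_numpy().tolist()
            expected = [[float(x) for x in row] for row in self.EXPECTED_PCT[cohort]]
            assert got == expected, cohort

    def test_pooled_accuracies(self):
        tables = published_cohort_tables()
        for cohort, acc in self.EXPECTED_ACC.items():
            assert round_percentage(overall_accuracy_g1g3(tables[cohort])) == acc

    def test_accuracy_ignores_g2_column(self):
        t = published_cohort_tables()["Stockholm"]
        modified = table_from_counts(
            [t.counts.loc["G1", "G1"], 999, t.counts.loc["G1", "G3"]],
            [t.counts.loc["G3", "G1"], 0, t.counts.loc["G3", "G3"]],
        )
        assert overall_accuracy_g1g3(modified) == overall_accuracy_g1g3(t)

    def test_perfect_table_is_100(self):
        assert overall_accuracy_g1g3(table_from_counts([10, 0, 0], [0, 0, 7])) == 100.0

    def test_empty_denominator_is_error(self):
        with pytest.raises(ValueError, match="G1 or G3"):
            overall_accuracy_g1g3(table_from_counts([0, 5, 0], [0, 3, 0]))


class TestKMCurve:
    def test_no_censoring_equals_empirical_survivor(self):
        times = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        curve = km_curve(times, np.ones(5, dtype=bool))
        for t in [0.5, 1.0, 2.0, 2.5, 3.0, 4.9, 5.0]:
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_all_censored_is_flat_at_one(self):
        curve = km_curve([1.0, 2.0, 3.0], [False, False, False])
        assert curve.event_times.size == 0 and curve.survival_at(10.0) == 1.0

    def test_hand_computed_product_limit(self):
        """6 patients: events at 1,2,3,5 with censoring at 2 and 4.

        S = 5/6, 5/6*4/5=2/3, 2/3*2/3=4/9, then 0 at the last event.
        """
        times = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        events = [True, True, False, True, False, True]
        curve = km_curve(times, events)
        np.testing.assert_allclose(curve.event_times, [1.0, 2.0, 3.0, 5.0])
        np.testing.assert_allclose(curve.survival, [5 / 6, 2 / 3, 4 / 9, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [6, 5, 3, 1])

    def test_empty_and_negative_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve([], [])
        with pytest.raises(ValueError, match="negative"):
            km_curve([-1.0], [True])


class TestLogRank:
    def test_duplicated_groups_give_zero_statistic(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 0, 1], dtype=bool)
        res = logrank_test(
            np.repeat(["a", "b"], 6), np.tile(times, 2), np.tile(events, 2)
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(5, size=40)
        events = rng.random(40) < 0.7
        groups = rng.choice(["x", "y"], size=40)
        a = logrank_test(groups, times, events)
        swapped = np.where(groups == "x", "y", "x")
        b = logrank_test(swapped, times, events)
        assert a.statistic == pytest.approx(b.statistic)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(["a", "a"], [1.0, 2.0], [True, True])

    def test_strong_separation_has_small_p(self):
        rng = np.random.default_rng(10)
        n = 200
        groups = np.repeat(["lo", "hi"], n // 2)
        rates = np.where(groups == "lo", 0.05, 0.15)
        times = np.minimum(rng.exponential(1 / rates), 10.0)
        events = times < 10.0
        assert logrank_test(groups, times, events).p_value < 0.001


class TestStratifyG2:
    def test_simulated_split_is_significant(self):
        cfg = SimulationConfig(n_samples=300, effect_size=3.0, seed=21)
        cohort = simulate_cohort(cfg)
        calls = classify_matrix(cohort.matrix, cfg.signature)
        km_g1, km_g3, res = stratify_g2(calls, cohort.histo_grade, cohort.survival)
        assert res.p_value < 0.05
        # genomic G3 stratum does worse at the horizon midpoint
        assert km_g3.survival_at(5.0) < km_g1.survival_at(5.0)

    def test_all_g2_called_same_grade_is_error(self):
        histo = pd.Series({"a": "G2", "b": "G2", "c": "G1"})
        calls = pd.Series({"a": "G3", "b": "G3", "c": "G1"})
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [True, True, False]},
            index=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="genomic G1"):
            stratify_g2(calls, histo, surv)

    def test_low_event_stratum_warns(self):
        histo = pd.Series({s: "G2" for s in "abcdef"})
        calls = pd.Series(
            {"a": "G1", "b": "G1", "c": "G1", "d": "G3", "e": "G3", "f": "G3"}
        )
        surv = pd.DataFrame(
            {
                "time": [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],
                "event": [False, False, True, True, True, False],
            },
            index=list("abcdef"),
        )
        with pytest.warns(UserWarning, match="insufficient"):
            stratify_g2(calls, histo, surv)
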