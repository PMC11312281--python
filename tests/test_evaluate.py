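import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorshoney import evaluate as ev
from sorshoney import models, preprocess, synthetic
from sorshoney.evaluate import (
    DesignError,
    SplitPlan,
    aggregate,
    enumerate_splits,
    hard_soft_metrics,
    heather_binary_experiment,
    regression_metrics,
    rmse,
    run_experiment,
)
from sorshoney.models import RFConfig, RegressionTask, five_level_task

FAST_RF = RFConfig(n_trees=30, tune=False)


class TestEnumerateSplits:
    @pytest.mark.parametrize("n, k, expected", [(14, 2, 91), (3, 2, 3), (8, 2, 28)])
    def test_counts_match_enumeration(self, n, k, expected):
        types = [f"H{i}" for i in range(n)]
        plan = enumerate_splits(types, k)
        brute = len(list(itertools.combinations(types, k)))
        assert len(plan.splits) == expected == brute

    def test_splits_partition_and_are_distinct(self):
        types = [f"H{i}" for i in range(6)]
        plan = enumerate_splits(types, 2)
        seen = set()
        for train, test in plan.splits:
            assert len(test) == 2
            assert set(train) | set(test) == set(types)
            assert not set(train) & set(test)
            seen.add(test)
        assert len(seen) == len(plan.splits)

    def test_invalid_k_rejected(self):
        with pytest.raises(DesignError):
            enumerate_splits(["a", "b"], 2)


class TestRunExperiment:
    def test_single_split_single_type_gives_five_predictions(self, small_pre):
        types = sorted(small_pre.meta["honey_type"].unique())
        plan = SplitPlan(((tuple(types[1:]), (types[0],)),), 1)
        log = run_experiment(small_pre, five_level_task("rice"), "rf", plan, seed=0, rf_config=FAST_RF)
        assert len(log) == 5
        assert set(log["honey_type"]) == {types[0]}

    def test_combined_task_prediction_count(self, small_pre):
        types = sorted(small_pre.meta["honey_type"].unique())
        plan = enumerate_splits(types, 2)  # C(5,2) = 10 splits
        log = run_experiment(small_pre, models.combined_task(), "rf", plan, seed=0, rf_config=FAST_RF)
        # 2 pure + 2 x 8 spiked test samples per split
        assert len(log) == len(plan.splits) * 18

    def test_group_integrity(self, small_pre):
        types = sorted(small_pre.meta["honey_type"].unique())
        plan = enumerate_splits(types, 2)
        log = run_experiment(small_pre, five_level_task("rice"), "rf", plan, seed=0, rf_config=FAST_RF)
        for i, (train, test) in enumerate(plan.splits):
            tested = set(log.loc[log["split_index"] == i, "honey_type"])
            assert tested == set(test)
            assert not tested & set(train)

    def test_predictions_within_task_classes(self, small_pre):
        task = five_level_task("rice")
        types = sorted(small_pre.meta["honey_type"].unique())
        plan = SplitPlan(plan_slice(types, 2), 2)
        log = run_experiment(small_pre, task, "plsda", plan, seed=0)
        assert set(log["predicted_class"]) <= set(task.classes)

    def test_metadata_never_leaks_into_features(self, small_pre):
        """Scrambling non-structural metadata leaves predictions unchanged."""
        types = sorted(small_pre.meta["honey_type"].unique())
        plan = SplitPlan(plan_slice(types, 1), 2)
        log_a = run_experiment(small_pre, five_level_task("rice"), "rf", plan, seed=0, rf_config=FAST_RF)
        scrambled = small_pre.copy()
        rng = np.random.default_rng(0)
        scrambled.meta["spatial_offset_mm"] = rng.uniform(0, 9, len(scrambled.meta))
        log_b = run_experiment(scrambled, five_level_task("rice"), "rf", plan, seed=0, rf_config=FAST_RF)
        assert np.all(log_a["predicted_class"].values == log_b["predicted_class"].values)

    def test_missing_level_raises_design_error(self, small_pre):
        broken = small_pre.select((small_pre.meta["level_pct"] != 30.0).to_numpy())
        types = sorted(broken.meta["honey_type"].unique())
        plan = SplitPlan(plan_slice(types, 1), 2)
        with pytest.raises(DesignError, match="missing"):
            run_experiment(broken, five_level_task("rice"), "rf", plan, seed=0, rf_config=FAST_RF)


def plan_slice(types, n):
    return tuple(enumerate_splits(types, 2).splits[:n])


def toy_log(true, pred, split=0):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(true))],
            "honey_type": ["H"] * len(true),
            "split_index": split,
            "algorithm": "rf",
            "true_class": true,
            "predicted_class": pred,
        }
    )


class TestHardSoftMetrics:
    def test_all_correct_gives_zero_rates(self):
        labels = ["pure", "rice_10", "rice_50"]
        m = hard_soft_metrics(toy_log(labels, labels))
        assert (m.pure_as_adulterated_pct, m.adulterated_as_pure_pct,
                m.soft_misclassified_pct, m.total_error_pct) == (0, 0, 0, 0)

    def test_direct_counting_example(self):
        true = ["pure", "pure"] + ["rice_10"] * 4 + ["rice_20"] * 4
        pred = ["rice_10", "pure"] + ["rice_10"] * 4 + ["rice_20"] * 4
        m = hard_soft_metrics(toy_log(true, pred))
        assert m.pure_as_adulterated_pct == pytest.approx(50.0)
        assert m.adulterated_as_pure_pct == 0 and m.soft_misclassified_pct == 0
        assert m.total_error_pct == pytest.approx(10.0)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.tuples(st.sampled_from(["pure", "rice_10", "rice_20", "rice_50"]),
                              st.sampled_from(["pure", "rice_10", "rice_20", "rice_50"])),
                    min_size=1, max_size=40))
    def test_taxonomy_partitions_all_predictions(self, pairs):
        true, pred = zip(*pairs)
        m = hard_soft_metrics(toy_log(list(true), list(pred)))
        # brute-force tally
        n_wrong = sum(1 for t, p in pairs if t != p)
        assert m.n_correct + m.n_pure_as_adulterated + m.n_adulterated_as_pure + m.n_soft == m.n_total
        assert m.total_error_pct == pytest.approx(100.0 * n_wrong / len(pairs))

    def test_combined_task_confusion_rates(self):
        true = ["rice_10", "rice_20", "sugar_beet_10", "sugar_beet_20", "pure"]
        pred = ["sugar_beet_10", "rice_20", "rice_50", "sugar_beet_20", "pure"]
        m = hard_soft_metrics(toy_log(true, pred))
        assert m.adulterant_confusion_pct["rice_as_sugar_beet_pct"] == pytest.approx(50.0)
        assert m.adulterant_confusion_pct["sugar_beet_as_rice_pct"] == pytest.approx(50.0)
        assert m.n_soft == 2

    def test_empty_log_rejected(self):
        with pytest.raises(DesignError):
            hard_soft_metrics(toy_log([], []))


class TestRmse:
    def test_exact_predictions_give_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computed(self):
        assert rmse([13, 17], [10, 20]) == pytest.approx(3.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(12)
        yhat, y = rng.normal(size=100), rng.normal(size=100)
        loop = np.sqrt(sum((a - b) ** 2 for a, b in zip(yhat, y)) / 100)
        assert rmse(yhat, y) == pytest.approx(loop, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestAggregate:
    def test_identical_values(self):
        s = aggregate([4.0] * 5)
        assert s["sd"] == 0 and s["min"] == s["max"] == s["mean"] == 4.0

    def test_three_values(self):
        s = aggregate([1.0, 2.0, 3.0])
        assert (s["mean"], s["min"], s["max"], s["median"]) == (2.0, 1.0, 3.0, 2.0)

    def test_sd_matches_two_pass_loop(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 1, 91)
        mean = sum(values) / 91
        loop_sd = np.sqrt(sum((v - mean) ** 2 for v in values) / 90)
        assert aggregate(values)["sd"] == pytest.approx(loop_sd, abs=1e-12)

    def test_skew_direction_flag(self):
        assert aggregate([0.0, 0.9, 0.95, 1.0])["skew_direction"] == 1.0


class TestRegressionMetrics:
    def test_perfect_split_has_zero_rmse_unit_r2(self):
        log = pd.DataFrame({"split_index": [0, 0, 0], "true_level": [0.0, 20.0, 50.0],
                            "predicted_level": [0.0, 20.0, 50.0]})
        m = regression_metrics(log)
        assert m.mean_rmse == 0.0 and m.mean_r2 == pytest.approx(1.0)

    def test_end_to_end_level_recovery(self, small_pre):
        types = sorted(small_pre.meta["honey_type"].unique())
        plan = enumerate_splits(types, 2)
        log = run_experiment(small_pre, RegressionTask(("rice",)), "rf_regression", plan,
                             seed=0, rf_config=RFConfig(n_trees=150))
        m = regression_metrics(log)
        assert m.mean_rmse < 6.0


@pytest.fixture(scope="module")
def heather_pre():
    design = synthetic.year1_design(n_types=6, seed=13)
    sset = synthetic.generate_study(design)
    return preprocess.preprocess_pipeline(sset, preprocess.year1_config())


class TestHeatherExperiment:
    def test_separable_data_mean_accuracy_one(self, heather_pre):
        result = heather_binary_experiment(heather_pre, n_models=5, seed=1,
                                           rf_config=RFConfig(n_trees=100, tune=False))
        assert result.mean_accuracy == pytest.approx(1.0)

    def test_single_model_has_zero_sd(self, heather_pre):
        result = heather_binary_experiment(heather_pre, n_models=1, seed=2,
                                           rf_config=RFConfig(n_trees=50, tune=False))
        assert result.sd_accuracy == 0.0

    def test_fixed_seed_reproducible(self, heather_pre):
        kw = dict(n_models=3, seed=4, rf_config=RFConfig(n_trees=50, tune=False))
        a = heather_binary_experiment(heather_pre, **kw)
        b = heather_binary_experiment(heather_pre, **kw)
        assert a.binary.per_split_accuracy == b.binary.per_split_accuracy
        assert a.ordinal.per_split_accuracy == b.ordinal.per_split_accuracy
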