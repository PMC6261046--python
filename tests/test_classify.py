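import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from corticodev.classify import (
    ClassifierConfig,
    EmpiricalDataset,
    aggregate_instance,
    aggregate_layout,
    anova_origins,
    classify_with_threshold,
    evaluate_threshold,
    permutation_null,
    train_classifier,
)


class TestThresholdRule:
    def test_dual_threshold_labelling(self):
        assert classify_with_threshold(np.array([0.9]), 0.85)[0] == 1
        assert classify_with_threshold(np.array([0.2]), 0.75)[0] == -1  # 0.2 < 0.25
        for thr in (0.75, 0.9, 0.975):
            assert classify_with_threshold(np.array([0.5]), thr)[0] == 0

    def test_threshold_outside_open_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_with_threshold(np.array([0.9]), 0.5)

    @given(st.integers(0, 2**31 - 1))
    def test_raising_threshold_nests_classified_sets(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(200)
        prev = None
        for thr in ClassifierConfig().thresholds:
            classified = classify_with_threshold(p, thr) != 0
            if prev is not None:
                assert not (classified & ~prev).any()
            prev = classified


class TestThresholdEvaluation:
    def test_accuracy_over_classified_rows_only(self):
        pred = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1, 0, 0])
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1, 0])
        ev = evaluate_threshold(pred, truth)
        assert ev.accuracy == pytest.approx(0.8)
        assert ev.fraction_classified == pytest.approx(10 / 12)

    def test_youden_from_sensitivity_and_specificity(self):
        # sensitivity 0.8 (4/5 positives hit), specificity 0.7 (7/10)
        truth = np.array([1] * 5 + [0] * 10)
        pred = np.array([1, 1, 1, 1, -1] + [-1] * 7 + [1] * 3)
        ev = evaluate_threshold(pred, truth)
        assert ev.youden_j == pytest.approx(0.5)

    def test_perfect_predictions_give_j_of_one(self):
        truth = np.array([1, 0, 1, 0])
        pred = np.where(truth == 1, 1, -1)
        assert evaluate_threshold(pred, truth).youden_j == pytest.approx(1.0)

    def test_nothing_classified_is_recorded_as_missing(self):
        ev = evaluate_threshold(np.zeros(5, dtype=int), np.ones(5, dtype=int))
        assert math.isnan(ev.accuracy) and math.isnan(ev.youden_j)
        assert ev.fraction_classified == 0.0

    def test_j_undefined_when_one_truth_class_classified(self):
        ev = evaluate_threshold(np.array([1, 1]), np.array([1, 1]))
        assert math.isnan(ev.youden_j)
        assert ev.accuracy == 1.0


class TestTrainedClassifier:
    def test_posterior_decreases_in_separating_feature(self, rng):
        n = 300
        dist = rng.normal(size=n)
        other = rng.normal(size=n)
        y = (dist < 0).astype(int)
        feats = np.column_stack([other, dist])
        clf = train_classifier(feats, y, random_state=0)
        grid = np.column_stack([np.zeros(9), np.linspace(-2, 2, 9)])
        p = clf.p_present(grid)
        # monotone non-increasing (Platt calibration saturates at the ends)
        assert (np.diff(p) <= 1e-9).all()
        assert p[0] > 0.9 and p[-1] < 0.1

    def test_label_swap_flips_posteriors(self, rng):
        n = 400
        x = rng.normal(size=(n, 2))
        y = (x.sum(axis=1) + rng.normal(scale=0.5, size=n) > 0).astype(int)
        grid = rng.normal(size=(50, 2))
        p = train_classifier(x, y).p_present(grid)
        p_swapped = train_classifier(x, 1 - y).p_present(grid)
        assert np.corrcoef(p, 1 - p_swapped)[0, 1] > 0.99

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError):
            train_classifier(rng.normal(size=(10, 2)), np.ones(10))


class TestPermutationNull:
    def test_null_construction_is_calibrated(self, rng):
        # label-independent posteriors: observed J sits inside its own null
        truth = rng.integers(0, 2, 400)
        p = rng.random(400)
        ev = permutation_null(truth, p, 0.75, n_permutations=100, rng=rng)
        mean, sd = ev.null_mean["youden_j"], ev.null_sd["youden_j"]
        assert abs(ev.youden_j - mean) < 3 * max(sd, 1e-9)
        assert ev.z_p_value["youden_j"] > 0.001

    def test_strong_signal_is_detected(self, rng):
        truth = rng.integers(0, 2, 400)
        p = np.where(truth == 1, 0.99, 0.01)
        ev = permutation_null(truth, p, 0.9, n_permutations=100, rng=rng)
        assert ev.z_p_value["youden_j"] < 1e-6
        assert ev.z_p_value["accuracy"] < 1e-6

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_null(np.array([0, 1]), np.array([0.1, 0.9]), 0.75, 1, rng)


class TestAggregation:
    def test_equal_metrics_average_to_themselves(self):
        from corticodev.classify import ThresholdEvaluation

        evs = [
            ThresholdEvaluation(t, 0.8, 0.4, 0.5, {}, {}, {"accuracy": 0.01, "youden_j": 0.02})
            for t in ClassifierConfig().thresholds
        ]
        inst = aggregate_instance(evs)
        assert inst.mean_accuracy == pytest.approx(0.8)
        assert inst.mean_youden == pytest.approx(0.4)
        assert inst.median_z_p["accuracy"] == pytest.approx(0.01)

    def test_instance_with_nothing_classified_is_missing(self):
        from corticodev.classify import ThresholdEvaluation

        evs = [
            ThresholdEvaluation(t, float("nan"), float("nan"), 0.0)
            for t in ClassifierConfig().thresholds
        ]
        inst = aggregate_instance(evs)
        assert inst.missing
        agg = aggregate_layout([inst])
        assert agg["n_missing"] == 1
        assert agg["sign_p_youden_j"] == 1.0

    def test_consistently_small_p_yields_significant_sign_test(self):
        from corticodev.classify import ThresholdEvaluation

        instances = []
        for _ in range(100):
            evs = [
                ThresholdEvaluation(t, 0.8, 0.5, 0.6, {}, {}, {"accuracy": 1e-6, "youden_j": 1e-6})
                for t in ClassifierConfig().thresholds
            ]
            instances.append(aggregate_instance(evs))
        agg = aggregate_layout(instances)
        assert agg["sign_p_youden_j"] < 1e-20
        assert agg["sign_z_youden_j"] == pytest.approx(-9.9)


class TestEmpiricalDataset:
    def test_missing_measure_column_rejected(self):
        frame = pd.DataFrame({"source": [0], "target": [1], "exists": [1]})
        with pytest.raises(ValueError):
            EmpiricalDataset("x", frame)

    def test_zscored_features_are_standardized(self, rng):
        frame = pd.DataFrame(
            {
                "source": np.arange(50),
                "target": np.arange(50) + 1,
                "exists": rng.integers(0, 2, 50),
                "differentiation": rng.uniform(0, 3, 50),
                "distance": rng.uniform(0, 9, 50),
            }
        )
        f = EmpiricalDataset("x", frame).features_z()
        assert np.allclose(f.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(f.std(axis=0, ddof=1), 1, atol=1e-12)


class TestAnova:
    @staticmethod
    def balanced_table(noise, rng, n=100, effect=0.1):
        rows = []
        for sp in ("macaque", "cat"):
            for gm in ("1D_1row", "1D_2rows", "2D"):
                for orig in ("1", "2", "3/4"):
                    eff = {"1": 0.0, "2": effect, "3/4": effect}[orig]
                    for _ in range(n):
                        rows.append(
                            dict(
                                species=sp,
                                growth_mode=gm,
                                origins=orig,
                                value=0.7 + eff + rng.normal(0, noise),
                            )
                        )
        return pd.DataFrame(rows)

    def test_error_df_is_1794_on_full_design(self, rng):
        res = anova_origins(self.balanced_table(0.05, rng))
        assert res["error_df"] == 1794
        assert int(res["anova"].loc["Residual", "df"]) == 1794

    def test_noiseless_origin_effect_recovered_exactly(self, rng):
        res = anova_origins(self.balanced_table(1e-12, rng))
        diffs = {r["pair"]: r["difference"] for _, r in res["posthoc"].iterrows()}
        assert diffs["1 vs 2"] == pytest.approx(-0.1, abs=1e-9)
        assert diffs["2 vs 3/4"] == pytest.approx(0.0, abs=1e-9)
        assert res["emmeans"]["2"] - res["emmeans"]["1"] == pytest.approx(0.1, abs=1e-9)

    def test_unbalanced_design_rejected(self, rng):
        df = self.balanced_table(0.05, rng, n=5).iloc[:-1]
        with pytest.raises(ValueError):
            anova_origins(df)

    def test_null_table_type_one_error_rate(self):
        # p-values under the null are approximately uniform
        ps = []
        rng = np.random.default_rng(0)
        for _ in range(20):
            res = anova_origins(self.balanced_table(0.05, rng, n=5, effect=0.0))
            ps.append(res["anova"].loc["C(origins)", "PR(>F)"])
        assert 0 <= np.mean(np.array(ps) < 0.05) <= 0.25
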