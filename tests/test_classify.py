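"""Subset enumeration, CV training, importance, minimal model, evaluation."""

import numpy as np
import pandas as pd
import pytest

from colonymorph import classify as clf
from colonymorph import synth
from colonymorph.morphometry import COLONY_PARAMETERS

FAST = clf.ClassifierConfig(model_family="logistic", cv_folds=5,
                            cv_repeats=2, seed=0)


class TestEnumerateSubsets:
    def test_seven_parameters_sizes_2_to_7(self):
        subsets = clf.enumerate_subsets(list("abcdefg"))
        assert len(subsets) == 120  # 2^7 - 7 - 1

    def test_four_parameters_sizes_2_to_4(self):
        assert len(clf.enumerate_subsets(list("abcd"))) == 11  # 6 + 4 + 1

    def test_deterministic_order(self):
        assert clf.enumerate_subsets(["x", "y", "z"]) == [
            ("x", "y"), ("x", "z"), ("y", "z"), ("x", "y", "z")]

    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            clf.enumerate_subsets(list("abcd"), min_size=4, max_size=3)
        with pytest.raises(ValueError):
            clf.enumerate_subsets([])


class TestTrainCV:
    def test_null_table_near_majority_rate(self):
        df = synth.planted_signal_table({}, 100, seed=0)  # no signal
        res = clf.train_cv(df, COLONY_PARAMETERS, FAST)
        majority = 0.5
        assert abs(res.mean_accuracy - majority) <= max(3 * res.sem_accuracy,
                                                        0.1)

    def test_separable_signal_above_95pct(self):
        df = synth.planted_signal_table({"ais": 8.0}, 60, seed=1)
        res = clf.train_cv(df, ("ais",) + tuple(
            q for q in COLONY_PARAMETERS if q != "ais"), FAST)
        assert res.mean_accuracy > 0.95

    def test_same_seed_identical_fold_accuracies(self):
        df = synth.planted_signal_table({"ais": 1.0}, 50, seed=3)
        a = clf.train_cv(df, COLONY_PARAMETERS, FAST)
        b = clf.train_cv(df, COLONY_PARAMETERS, FAST)
        assert np.array_equal(a.per_fold_accuracies, b.per_fold_accuracies)
        assert a.best_params == b.best_params

    def test_single_class_rejected(self):
        df = synth.planted_signal_table({}, 20, seed=0)
        with pytest.raises(ValueError, match="two phenotype classes"):
            clf.train_cv(df[df["phenotype"] == "good"], COLONY_PARAMETERS,
                         FAST)

    def test_unknown_parameter_rejected(self):
        df = synth.planted_signal_table({}, 20, seed=0)
        with pytest.raises(KeyError, match="no_such"):
            clf.train_cv(df, ("area", "no_such"), FAST)

    def test_mlp_family_runs_and_is_deterministic(self):
        df = synth.planted_signal_table({"ais": 3.0}, 40, seed=2)
        cfg = clf.ClassifierConfig(model_family="mlp", hidden_units=(4,),
                                   alphas=(1e-4,), cv_folds=3, cv_repeats=1,
                                   seed=1)
        a = clf.train_cv(df, ("ais", "area"), cfg)
        b = clf.train_cv(df, ("ais", "area"), cfg)
        assert np.array_equal(a.per_fold_accuracies, b.per_fold_accuracies)
        assert a.mean_accuracy > 0.9


@pytest.fixture(scope="module")
def planted_importance():
    cfg = clf.ClassifierConfig(model_family="logistic", cv_folds=5,
                               cv_repeats=1, seed=0)
    df = synth.planted_signal_table({"ais": 1.5}, 60, seed=10)
    return clf.importance_table(df, COLONY_PARAMETERS, cfg)


class TestImportance:
    def test_informative_descriptor_ranks_first(self, planted_importance):
        assert planted_importance.parameters[0] == "ais"

    def test_model_counts(self, planted_importance):
        assert (planted_importance.table["n_models"] == 63).all()  # 2^6 - 1

    def test_all_subsets_trained(self, planted_importance):
        assert len(planted_importance.subset_results) == 120

    def test_noise_descriptors_share_a_common_baseline(self):
        cfg = clf.ClassifierConfig(model_family="logistic", cv_folds=5,
                                   cv_repeats=1, seed=0)
        df = synth.planted_signal_table({}, 80, seed=5)
        imp = clf.importance_table(df, COLONY_PARAMETERS, cfg)
        spread = imp.table["importance"].max() - imp.table["importance"].min()
        assert spread < 0.1


class TestTopKAndMinimalModel:
    def test_curve_has_p_minus_one_points_and_full_model_identity(self):
        cfg = clf.ClassifierConfig(model_family="logistic", cv_folds=4,
                                   cv_repeats=1, seed=0)
        df = synth.planted_signal_table({"ais": 2.0}, 40, seed=4)
        imp = clf.importance_table(df, COLONY_PARAMETERS, cfg)
        curve = clf.topk_curve(df, imp, cfg)
        assert len(curve) == 6  # k = 2..7
        full = clf.train_cv(df, tuple(imp.parameters), cfg)
        assert curve[-1].mean_accuracy == full.mean_accuracy
        assert np.array_equal(curve[-1].per_fold_accuracies,
                              full.per_fold_accuracies)

    def test_flat_curve_selects_smallest_k(self):
        curve = [clf.SubsetResult(tuple("ab"[:2]), 0.7, 0.01,
                                  np.full((1, 2), 0.7))]
        curve += [clf.SubsetResult(tuple("abcdefg"[:k]), 0.7, 0.01,
                                   np.full((1, 2), 0.7)) for k in (3, 4)]
        k, subset = clf.select_minimal_model(curve)
        assert k == 2

    def test_one_sem_rule_arithmetic(self):
        """Means (.66,.70,.73,.74,.74,.735,.74) with SEM .006 at the max
        select the first k reaching .734."""
        means = [0.66, 0.70, 0.73, 0.74, 0.74, 0.735, 0.74]
        curve = [clf.SubsetResult(tuple("abcdefg"[:k + 1]), m, 0.006,
                                  np.full((1, 2), m))
                 for k, m in enumerate(means)]
        k, _ = clf.select_minimal_model(curve)
        assert k == 4

    def test_two_informative_features_select_k2(self):
        df = synth.planted_signal_table({"ais": 8.0, "shape_factor": 8.0},
                                        60, seed=6)
        cfg1 = clf.ClassifierConfig(model_family="logistic", cv_folds=5,
                                    cv_repeats=1, seed=0)
        imp = clf.importance_table(df, COLONY_PARAMETERS, cfg1)
        curve = clf.topk_curve(df, imp, FAST)
        k, subset = clf.select_minimal_model(curve)
        assert k == 2
        assert set(subset) == {"ais", "shape_factor"}

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            clf.select_minimal_model([])


class TestEvaluate:
    def test_counts_metrics(self):
        ev = clf.evaluate_counts(55, 21, 12, 58)
        assert ev.accuracy_pct == 77
        assert ev.class_pct("bad") == 72
        assert ev.class_pct("good") == 83

    def test_larger_sample_metrics(self):
        ev = clf.evaluate_counts(720, 379, 513, 1248)
        assert ev.accuracy_pct == 69
        assert ev.class_pct("bad") == 66
        assert ev.class_pct("good") == 71

    def test_perfect_predictions(self):
        obs = np.array(["bad"] * 5 + ["good"] * 7)
        ev = clf.evaluate(obs, obs.copy())
        assert ev.accuracy_pct == 100
        assert ev.confusion.counts[0, 1] == 0
        assert ev.confusion.counts[1, 0] == 0

    def test_rounding_half_up(self):
        assert clf.round_percent(0.665) == 67
        assert clf.round_percent(0.664999) == 66
        assert clf.round_percent(0.5) == 50

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError):
            clf.evaluate(["bad", "good"], ["bad"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unexpected"):
            clf.evaluate(["bad", "ugly"], ["bad", "bad"])

    def test_per_line_breakdown(self):
        obs = np.array(["bad", "bad", "good", "good"])
        pred = np.array(["bad", "good", "good", "good"])
        lines = np.array(["A", "A", "A", "B"])
        ev = clf.evaluate(obs, pred, lines=lines)
        tab = ev.per_line_misclassified.set_index("line")
        assert tab.loc["A", "misclassified"] == 1
        assert tab.loc["B", "misclassified"] == 0


class TestPerLineModels:
    def test_one_result_per_line(self, feature_table):
        out = clf.per_line_models(feature_table,
                                  ("ais", "shape_factor"), FAST)
        assert set(out) == {"ES1", "iPS1", "iPS2"}

    def test_single_line_matches_pooled(self):
        df = synth.planted_signal_table({"ais": 1.0}, 40, seed=7)
        pooled = clf.train_cv(df, ("ais", "area"), FAST)
        per_line = clf.per_line_models(df, ("ais", "area"), FAST)
        assert list(per_line) == ["L1"]
        assert per_line["L1"].mean_accuracy == pooled.mean_accuracy

    def test_single_class_line_skipped_with_warning(self):
        df = synth.planted_signal_table({"ais": 1.0}, 30, seed=8)
        other = df.copy()
        other["line"] = "L2"
        other = other[other["phenotype"] == "good"]
        combined = pd.concat([df, other], ignore_index=True)
        with pytest.warns(UserWarning, match="single phenotype"):
            out = clf.per_line_models(combined, ("ais", "area"), FAST)
        assert set(out) == {"L1"}


class TestPrefilterAndFacade:
    def test_drop_correlated_removes_near_duplicates(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 500)
        df = pd.DataFrame({
            "area": base, "feret_d": base + rng.normal(0, 0.01, 500),
            "shape_factor": rng.normal(0, 1, 500),
        })
        kept = clf.drop_correlated(df, ["area", "feret_d", "shape_factor"],
                                   threshold=0.95)
        assert kept == ["area", "shape_factor"]

    def test_facade_reports_planted_minimal_model(self):
        df = synth.planted_signal_table({"ais": 8.0, "shape_factor": 8.0},
                                        50, seed=9)
        cfg = clf.ClassifierConfig(model_family="logistic", cv_folds=5,
                                   cv_repeats=1, seed=0)
        results = clf.PhenotypeClassifier(df, config=cfg).fit()
        assert results.minimal_k == 2
        assert set(results.minimal_subset) == {"ais", "shape_factor"}
        text = results.summary()
        assert "minimal model" in text
        assert "overall accuracy" in text

    def test_pipeline_determinism_of_importance(self):
        cfg = clf.ClassifierConfig(model_family="logistic", cv_folds=4,
                                   cv_repeats=1, seed=5)
        df = synth.planted_signal_table({"ais": 1.0}, 40, seed=2)
        a = clf.importance_table(df, ("ais", "area", "perimeter"), cfg)
        b = clf.importance_table(df, ("ais", "area", "perimeter"), cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
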