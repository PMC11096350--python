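import numpy as np
import pandas as pd
import pytest

from hrvpc.errors import ValidationError
from hrvpc.model_bench import (ALGORITHMS, ModelSpec, confusion_metrics,
                               count_possible_combinations, evaluate_model,
                               generate_combinations, run_benchmark, smote,
                               split_cohort)
from oracles import confusion_reference


def _features(n, k=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, k)),
                        columns=[f"f{i}" for i in range(k)],
                        index=[f"s{i}" for i in range(n)])


class TestSmote:
    def test_balanced_input_unchanged(self):
        X = _features(10)
        y = pd.Series(["dcSSc"] * 5 + ["lcSSc"] * 5, index=X.index)
        Xb, yb = smote(X, y, seed=1)
        pd.testing.assert_frame_equal(Xb, X)

    def test_parity_and_segment_geometry(self):
        X = _features(14, seed=2)
        y = pd.Series(["dcSSc"] * 4 + ["lcSSc"] * 10, index=X.index)
        Xb, yb = smote(X, y, k=3, seed=2)
        assert (yb == "dcSSc").sum() == (yb == "lcSSc").sum() == 10
        # originals unchanged
        pd.testing.assert_frame_equal(Xb.loc[X.index], X)
        # each synthetic point lies on a segment between two minority points
        minority = X[y == "dcSSc"].to_numpy()
        for _, row in Xb.loc[Xb.index.str.startswith("synthetic")].iterrows():
            p = row.to_numpy()
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    a, b = minority[i], minority[j]
                    ab = b - a
                    denom = ab @ ab
                    if denom == 0:
                        continue
                    u = (p - a) @ ab / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.linalg.norm(
                            a + u * ab - p) < 1e-9:
                        on_segment = True
            assert on_segment

    def test_one_dimensional_convexity(self):
        X = pd.DataFrame({"f0": [0.0, 1.0] + [5.0] * 8},
                         index=[f"s{i}" for i in range(10)])
        y = pd.Series(["dcSSc"] * 2 + ["lcSSc"] * 8, index=X.index)
        with pytest.warns(UserWarning, match="reducing k"):
            Xb, _ = smote(X, y, k=5, seed=3)
        synth = Xb.loc[Xb.index.str.startswith("synthetic"), "f0"]
        assert ((synth >= 0) & (synth <= 1)).all()

    def test_single_class_rejected(self):
        X = _features(6)
        with pytest.raises(ValidationError):
            smote(X, pd.Series(["dcSSc"] * 6, index=X.index))


class TestCombinatorics:
    def test_five_features_31_subsets(self):
        assert len(generate_combinations(list("abcde"))) == 31

    def test_singleton(self):
        assert generate_combinations(["x"]) == [("x",)]

    def test_three_features_seven_subsets(self):
        assert len(generate_combinations(list("abc"))) == 7

    def test_counts(self):
        assert count_possible_combinations(24, 5) == 55454
        assert count_possible_combinations(5, 5) == 31
        assert count_possible_combinations(3, 5) == 7
        assert count_possible_combinations(5, 3) == 25

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            generate_combinations([])


class TestSplit:
    def test_16_42_stratification(self):
        X = _features(58)
        y = pd.Series(["dcSSc"] * 16 + ["lcSSc"] * 42, index=X.index)
        X_tr, X_va, y_tr, y_va = split_cohort(X, y, seed=0)
        assert 46 <= len(X_tr) <= 47
        assert set(y_tr.unique()) == set(y_va.unique()) == {"dcSSc", "lcSSc"}
        assert abs((y_tr == "dcSSc").mean() - 16 / 58) < 0.05

    def test_partition_and_determinism(self):
        X = _features(30)
        y = pd.Series(["dcSSc"] * 10 + ["lcSSc"] * 20, index=X.index)
        a = split_cohort(X, y, seed=5)
        b = split_cohort(X, y, seed=5)
        assert set(a[0].index) | set(a[1].index) == set(X.index)
        assert set(a[0].index) & set(a[1].index) == set()
        assert list(a[0].index) == list(b[0].index)


class TestConfusionMetrics:
    def test_hand_computed_cell(self):
        # TP=9, FN=1, TN=7, FP=3
        y = np.array([1] * 10 + [0] * 10)
        prob = np.array([0.9] * 9 + [0.1] + [0.8] * 3 + [0.2] * 7)
        m = confusion_metrics(y, prob)
        ref = confusion_reference(tp=9, fn=1, tn=7, fp=3)
        for key, val in ref.items():
            assert m[key] == pytest.approx(val, abs=1e-9), key
        assert m["F1"] == pytest.approx(0.818, abs=1e-3)

    def test_brier_is_probability_mse(self):
        y = np.array([1, 0])
        prob = np.array([0.7, 0.2])
        m = confusion_metrics(y, prob)
        assert m["MSE"] == pytest.approx((0.3 ** 2 + 0.2 ** 2) / 2)


class TestEvaluateModel:
    @staticmethod
    def _separable(n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({
            "f0": np.concatenate([rng.normal(4, 0.3, n // 2),
                                  rng.normal(-4, 0.3, n // 2)]),
            "f1": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)])
        y = pd.Series(["dcSSc"] * (n // 2) + ["lcSSc"] * (n // 2), index=X.index)
        return X, y

    def test_separable_limit(self):
        X, y = self._separable()
        X_tr, X_va, y_tr, y_va = split_cohort(X, y, seed=1)
        score = evaluate_model(ModelSpec(("f0",), "logistic_regression", seed=1),
                               (X_tr, y_tr), (X_va, y_va), cv_repeats=0)
        assert score.Sensitivity == 1 and score.Specificity == 1
        assert score.AUC == 1 and score.LogLoss < 0.1

    def test_label_permutation_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _features(60, seed=seed)
            y = pd.Series(rng.permutation(["dcSSc"] * 20 + ["lcSSc"] * 40),
                          index=X.index)
            X_tr, X_va, y_tr, y_va = split_cohort(X, y, seed=seed)
            score = evaluate_model(
                ModelSpec(("f0", "f1"), "logistic_regression", seed=seed),
                (X_tr, y_tr), (X_va, y_va), cv_repeats=0)
            aucs.append(score.AUC)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_cv_dispersion_reported(self):
        X, y = self._separable(n=30, seed=3)
        X_tr, X_va, y_tr, y_va = split_cohort(X, y, seed=3)
        score = evaluate_model(ModelSpec(("f0",), "decision_tree", seed=3),
                               (X_tr, y_tr), (X_va, y_va), cv_k=3, cv_repeats=2)
        assert "AUC" in score.cv_mean and "AUC" in score.cv_sd

    def test_smote_stays_inside_training_folds(self, monkeypatch):
        """Leakage guard: SMOTE must only ever see training-fold rows."""
        import hrvpc.model_bench as mb
        X, y = self._separable(n=30, seed=4)
        X_tr, X_va, y_tr, y_va = split_cohort(X, y, seed=4)
        seen_sizes = []
        real_smote = mb.smote

        def spy(features, labels, k=5, seed=0):
            seen_sizes.append(len(features))
            assert not any(str(i).startswith("synthetic") for i in features.index)
            return real_smote(features, labels, k=k, seed=seed)

        monkeypatch.setattr(mb, "smote", spy)
        evaluate_model(ModelSpec(("f0",), "logistic_regression", seed=4),
                       (X_tr, y_tr), (X_va, y_va), cv_k=3, cv_repeats=1,
                       smote_policy="within_folds")
        assert max(seen_sizes) <= len(X_tr)  # never the full table


class TestRunBenchmark:
    def test_grid_arithmetic(self, synthetic_cohort):
        report, grid = run_benchmark(
            synthetic_cohort, ["mean_HR_S2", "SD2_delta"], seed=0,
            cv_repeats=0, algorithms=("logistic_regression", "decision_tree"))
        assert len(grid) == 3 * 2
        assert set(report["n_variables"]) <= {1, 2}

    def test_full_registry_has_11_algorithms(self):
        assert len(ALGORITHMS) == 11
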