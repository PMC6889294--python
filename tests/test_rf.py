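"""Random-forest protocol: split, tuning, training, metric suite, Gini."""

import numpy as np
import pandas as pd
import pytest

from ecsubtype.panel import GenePanel
from ecsubtype.rf import (RfModel, TrainingSet, gini_importance,
                          performance_metrics, stratified_split, train_rf,
                          tune_mtry)
from ecsubtype.synthetic import simulate_training_set


def _toy_set(n=40, seed=0, p_flip=0.0):
    """TP53 equals the label (optionally flipped with prob p_flip); other
    genes are noise."""
    rng = np.random.default_rng(seed)
    genes = GenePanel().rf_genes
    y = np.array(["CNH", "CNL"] * (n // 2))
    X = pd.DataFrame(rng.integers(0, 2, (n, len(genes))), columns=list(genes))
    tp53 = (y == "CNH").astype(int)
    flip = rng.random(n) < p_flip
    X["TP53"] = np.where(flip, 1 - tp53, tp53)
    return TrainingSet(X, pd.Series(y))


class TestTrainingSet:
    def test_rejects_non_binary_features(self):
        X = pd.DataFrame({g: [0, 1, 2, 0] for g in GenePanel().rf_genes})
        with pytest.raises(ValueError, match="binary"):
            TrainingSet(X, pd.Series(["CNL", "CNH", "CNL", "CNH"]))

    def test_rejects_single_class(self):
        X = pd.DataFrame({g: [0, 1] for g in GenePanel().rf_genes})
        with pytest.raises(ValueError):
            TrainingSet(X, pd.Series(["CNL", "CNL"]))


class TestStratifiedSplit:
    def test_62_86_protocol_split(self):
        data = simulate_training_set(n=148, seed=3)
        train, val = stratified_split(data, n_train=62, seed=3)
        assert train.n == 62 and val.n == 86
        # proportions within one sample of the full-set proportion
        full = (data.y == "CNH").mean()
        assert abs((train.y == "CNH").sum() - full * 62) <= 1
        assert abs((val.y == "CNH").sum() - full * 86) <= 1

    def test_tiny_balanced_split_forced_by_stratification(self):
        X = pd.DataFrame({g: [0, 1, 0, 1] for g in GenePanel().rf_genes})
        y = pd.Series(["CNL", "CNL", "CNH", "CNH"])
        train, val = stratified_split(TrainingSet(X, y), n_train=2, seed=0)
        assert sorted(train.y) == sorted(val.y) == ["CNH", "CNL"]

    def test_determinism(self):
        data = simulate_training_set(n=148, seed=5)
        a = stratified_split(data, 62, seed=11)
        b = stratified_split(data, 62, seed=11)
        pd.testing.assert_frame_equal(a[0].X, b[0].X)
        pd.testing.assert_series_equal(a[0].y, b[0].y)


class TestTuning:
    def test_separable_data_reaches_high_cv_accuracy(self):
        best, trace = tune_mtry(_toy_set(60), seed=1, cv_n_trees=50)
        assert max(trace.values()) >= 0.9

    def test_single_value_grid(self):
        best, trace = tune_mtry(_toy_set(20), grid=[4], seed=0, cv_n_trees=25)
        assert best == 4 and list(trace) == [4]

    def test_tie_breaks_toward_smaller_mtry(self):
        # perfectly separable: every mtry that finds TP53 ties at accuracy 1
        best, trace = tune_mtry(_toy_set(40), grid=[12, 8], seed=0, cv_n_trees=50)
        ties = [m for m, a in trace.items() if a == max(trace.values())]
        assert best == min(ties)

    def test_grid_outside_feature_range_rejected(self):
        with pytest.raises(ValueError):
            tune_mtry(_toy_set(20), grid=[13])


class TestTraining:
    def test_separable_feature_gives_perfect_validation(self):
        data = _toy_set(60)
        model = train_rf(data, mtry=12, seed=0)
        pred, votes = model.predict(data.X)
        assert (pred == data.y.to_numpy()).all()
        assert (votes >= 0.5).all()

    def test_single_tree_oracle_equivalence(self):
        """A 1-tree mtry=12 forest on one separating feature is that
        feature."""
        genes = GenePanel().rf_genes
        y = pd.Series(["CNH", "CNL"] * 10)
        X = pd.DataFrame(0, index=range(20), columns=list(genes))
        X["TP53"] = (y == "CNH").astype(int)
        model = train_rf(TrainingSet(X, y), mtry=12, n_trees=1, seed=0)
        pred, _ = model.predict(X)
        assert (pred == np.where(X["TP53"] == 1, "CNH", "CNL")).all()

    def test_reproducibility(self):
        data = simulate_training_set(n=100, seed=9)
        m1 = train_rf(data, mtry=3, n_trees=100, seed=7)
        m2 = train_rf(data, mtry=3, n_trees=100, seed=7)
        p1, v1 = m1.predict(data.X)
        p2, v2 = m2.predict(data.X)
        assert (p1 == p2).all() and np.allclose(v1, v2)

    def test_feature_order_mismatch_refused(self):
        data = _toy_set(20)
        model = train_rf(data, mtry=3, n_trees=20, seed=0)
        scrambled = data.X[list(data.X.columns[::-1])]
        with pytest.raises(ValueError, match="feature order"):
            model.predict(scrambled)

    def test_save_load_round_trip(self, tmp_path):
        data = _toy_set(20)
        model = train_rf(data, mtry=3, n_trees=20, seed=0)
        model.save(tmp_path / "model.json")
        loaded = RfModel.load(tmp_path / "model.json")
        assert loaded.mtry == 3 and loaded.feature_names == model.feature_names
        p1, _ = model.predict(data.X)
        p2, _ = loaded.predict(data.X)
        assert (p1 == p2).all()


class TestMetricSuite:
    def test_reconstructed_validation_matrix(self):
        """The unique 2x2 matrix consistent with the published report:
        TP=31, FN=1, FP=1, TN=48, positive class CNH."""
        truth = ["CNH"] * 32 + ["CNL"] * 49
        pred = ["CNH"] * 31 + ["CNL"] + ["CNH"] + ["CNL"] * 48
        r = performance_metrics(truth, pred, positive_class="CNH")
        assert r.accuracy == pytest.approx(79 / 81)
        assert r.kappa == pytest.approx((79 / 81 - 0.52203) / (1 - 0.52203), abs=1e-4)
        assert r.sensitivity == pytest.approx(31 / 32)
        assert r.specificity == pytest.approx(48 / 49)
        assert r.no_information_rate == pytest.approx(49 / 81)
        assert r.balanced_accuracy == pytest.approx((31 / 32 + 48 / 49) / 2)
        assert r.mcnemar_p == 1.0
        assert r.prevalence == pytest.approx(32 / 81)
        assert r.detection_rate == pytest.approx(31 / 81)
        assert r.detection_prevalence == pytest.approx(32 / 81)

    def test_perfect_and_chance_level_identities(self):
        perfect = performance_metrics(["CNH", "CNL"] * 10, ["CNH", "CNL"] * 10)
        assert perfect.kappa == pytest.approx(1.0)
        assert perfect.mcnemar_p == 1.0
        constant = performance_metrics(["CNH"] * 4 + ["CNL"] * 6, ["CNL"] * 10)
        assert constant.accuracy == pytest.approx(constant.no_information_rate)
        assert constant.kappa == pytest.approx(0.0)

    def test_kappa_matches_sklearn(self):
        rng = np.random.default_rng(4)
        truth = rng.choice(["CNL", "CNH"], 200, p=[0.6, 0.4])
        pred = np.where(rng.random(200) < 0.8, truth,
                        np.where(truth == "CNL", "CNH", "CNL"))
        from sklearn.metrics import cohen_kappa_score

        r = performance_metrics(truth, pred)
        assert r.kappa == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)

    def test_metric_identities_on_random_predictions(self):
        rng = np.random.default_rng(11)
        truth = rng.choice(["CNL", "CNH"], 120)
        pred = rng.choice(["CNL", "CNH"], 120)
        r = performance_metrics(truth, pred)
        assert r.detection_prevalence >= r.detection_rate
        assert r.accuracy_ci[0] <= r.accuracy <= r.accuracy_ci[1]
        assert r.balanced_accuracy == pytest.approx((r.sensitivity + r.specificity) / 2)

    def test_foreign_label_rejected(self):
        with pytest.raises(ValueError):
            performance_metrics(["CNL", "XX"], ["CNL", "CNL"])


class TestGiniImportance:
    def test_unused_feature_scores_zero_and_dominant_ranks_first(self):
        genes = GenePanel().rf_genes
        y = pd.Series(["CNH", "CNL"] * 30)
        X = pd.DataFrame(0, index=range(60), columns=list(genes))
        X["TP53"] = (y == "CNH").astype(int)
        model = train_rf(TrainingSet(X, y), mtry=12, n_trees=50, seed=0)
        imp = gini_importance(model)
        assert imp.index[0] == "TP53"
        assert imp.drop("TP53").eq(0).all()  # constant features never split

    def test_duplicated_noise_feature_keeps_top_gene(self):
        data = _toy_set(80, seed=2, p_flip=0.1)
        base_top = gini_importance(train_rf(data, 3, 200, seed=5)).index[0]
        X2 = data.X.copy()
        X2["NOISE"] = data.X["KRAS"]  # duplicate a pure-noise column
        dup_top = gini_importance(
            train_rf(TrainingSet(X2, data.y), 3, 200, seed=5)).index[0]
        assert base_top == dup_top == "TP53"
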