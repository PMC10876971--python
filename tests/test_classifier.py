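import numpy as np
import pandas as pd
import pytest

from _oracles import ap_oracle, auroc_oracle
from focalamp import classifier as clf
from focalamp.feature_engineering import FEATURE_COLUMNS


class TestMetrics:
    def test_average_precision_worked_example(self):
        got = clf.average_precision([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert got == pytest.approx(0.8333, abs=1e-4)

    def test_average_precision_bounds_and_ties(self):
        assert clf.average_precision([0, 1, 1], [0.1, 0.8, 0.9]) == 1.0
        # one tied threshold: precision = prevalence at recall 1
        assert clf.average_precision([1, 0, 0, 1], [0.5] * 4) == pytest.approx(0.5)

    def test_auroc_worked_example(self):
        assert clf.auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)
        assert clf.auroc([1, 0], [0.9, 0.1]) == 1.0
        assert clf.auroc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_single_class_rejected(self):
        for fn in (clf.average_precision, clf.auroc):
            with pytest.raises(ValueError, match="both classes"):
                fn([1, 1, 1], [0.1, 0.2, 0.3])

    def test_metrics_equal_bruteforce_oracles_on_random_vectors(self, rng):
        """Exhaustive-threshold / pair-counting oracles match exactly."""
        for _ in range(300):
            n = int(rng.integers(2, 21))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert clf.average_precision(labels, scores) == pytest.approx(
                ap_oracle(labels, scores), abs=1e-12
            )
            assert clf.auroc(labels, scores) == pytest.approx(
                auroc_oracle(labels, scores), abs=1e-12
            )

    def test_threshold_metrics_confusion_table(self):
        prec, sens, spec = clf.threshold_metrics(
            [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1], 0.5
        )
        assert (prec, sens, spec) == (pytest.approx(2 / 3), 1.0, 0.5)

    def test_threshold_metrics_extreme_cutoffs(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]
        prec, sens, spec = clf.threshold_metrics(labels, scores, 1.1)
        assert np.isnan(prec) and sens == 0.0 and spec == 1.0
        _, sens, spec = clf.threshold_metrics(labels, scores, 0.0)
        assert sens == 1.0 and spec == 0.0


class TestGroupKFold:
    def test_partition(self):
        groups = ["a", "b", "c", "d"]
        fold = clf.stratified_group_kfold(groups, [1, 0, 1, 0], k=2, seed=0)
        assert set(fold) == set(groups)
        sizes = pd.Series(fold).value_counts()
        assert sorted(sizes) == [2, 2]

    def test_positive_groups_balanced(self):
        groups = [f"g{i}" for i in range(10)]
        labels = [1] * 5 + [0] * 5
        fold = clf.stratified_group_kfold(groups, labels, k=5, seed=3)
        pos_per_fold = pd.Series(
            [fold[g] for g, l in zip(groups, labels) if l]
        ).value_counts()
        assert sorted(pos_per_fold) == [1] * 5

    def test_deterministic_given_seed(self):
        groups = [f"g{i}" for i in range(17)]
        labels = [i % 3 == 0 for i in range(17)]
        a = clf.stratified_group_kfold(groups, labels, k=4, seed=9)
        b = clf.stratified_group_kfold(groups, labels, k=4, seed=9)
        assert a == b
        c = clf.stratified_group_kfold(groups, labels, k=4, seed=10)
        assert a != c  # different shuffle

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            clf.stratified_group_kfold(["a", "b"], [0, 1], k=3)

    def test_no_group_straddles_folds_randomized(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            groups = [f"g{i}" for i in range(n)]
            labels = rng.integers(0, 2, size=n).tolist()
            k = int(rng.integers(2, min(n, 8)))
            fold = clf.stratified_group_kfold(groups, labels, k, seed=int(rng.integers(1000)))
            rows = rng.choice(groups, size=200)
            per_group = pd.DataFrame({"g": rows, "fold": [fold[g] for g in rows]})
            assert (per_group.groupby("g")["fold"].nunique() == 1).all()


class TestTraining:
    def test_separable_cohort_reaches_high_cv_auprc(self, small_model):
        assert small_model.cv_auprc >= 0.95

    def test_permuted_labels_collapse_to_prevalence(self, small_features):
        shuffled = small_features.copy()
        rng = np.random.default_rng(5)
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        if shuffled["label"].sum() == 0:
            pytest.skip("permutation degenerate")
        model = clf.train(
            shuffled, clf.ModelConfig(k_folds=4, n_search=2, max_rounds=60, seed=5)
        )
        prevalence = shuffled["label"].mean()
        assert model.cv_auprc <= 3 * prevalence

    def test_training_is_deterministic(self, small_features):
        config = clf.ModelConfig(k_folds=3, n_search=2, max_rounds=40, seed=21)
        a = clf.train(small_features, config)
        b = clf.train(small_features, config)
        assert a.hyperparameters == b.hyperparameters
        pd.testing.assert_frame_equal(a.cv_history, b.cv_history)

    def test_single_class_labels_rejected(self, small_features):
        bad = small_features.copy()
        bad["label"] = 0
        with pytest.raises(ValueError, match="both classes"):
            clf.train(bad, clf.ModelConfig(k_folds=2, n_search=1))

    def test_predictions_in_unit_interval_and_reproducible(
        self, small_model, small_features
    ):
        p1 = clf.predict_gene_prob(small_model, small_features)
        p2 = clf.predict_gene_prob(small_model, small_features)
        assert np.all((p1 >= 0) & (p1 <= 1))
        np.testing.assert_array_equal(p1, p2)

    def test_all_missing_feature_row_still_scored(self, small_model):
        row = pd.DataFrame([{c: np.nan for c in FEATURE_COLUMNS}])
        (p,) = clf.predict_gene_prob(small_model, row)
        assert 0.0 <= p <= 1.0

    def test_schema_mismatch_names_missing_columns(self, small_model):
        with pytest.raises(ValueError, match="total_cn"):
            clf.predict_gene_prob(small_model, pd.DataFrame({"ploidy": [2.0]}))

    def test_model_roundtrips_through_file(self, small_model, small_features, tmp_path):
        path = tmp_path / "model.json"
        small_model.save(path)
        loaded = clf.TrainedClassifier.load(path)
        np.testing.assert_array_almost_equal(
            clf.predict_gene_prob(loaded, small_features),
            clf.predict_gene_prob(small_model, small_features),
        )
        assert loaded.hyperparameters == small_model.hyperparameters


class TestSampleLevel:
    def test_single_gene_samples_reduce_to_gene_metrics(self, small_model):
        rng = np.random.default_rng(3)
        n = 40
        features = pd.DataFrame(
            {c: rng.random(n) * 5 for c in FEATURE_COLUMNS}
        )
        features["sample_id"] = [f"S{i}" for i in range(n)]
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        metrics = clf.evaluate_sample_level(small_model, features, labels)
        probs = clf.predict_gene_prob(small_model, features)
        assert metrics.auPRC == pytest.approx(clf.average_precision(labels, probs))
        assert metrics.auROC == pytest.approx(clf.auroc(labels, probs))

    def test_default_cohort_metrics_sane(self, small_model, small_features):
        m = clf.evaluate_sample_level(small_model, small_features, small_features["label"])
        for v in (m.auPRC, m.auROC, m.sensitivity, m.specificity):
            assert 0.0 <= v <= 1.0
        assert m.auROC >= 0.5


class TestBaseline:
    def test_monotone_relation_gives_auroc_above_half(self):
        rng = np.random.default_rng(0)
        cn = rng.integers(1, 40, size=400).astype(float)
        label = (cn + rng.normal(0, 5, 400) > 25).astype(int)
        table = pd.DataFrame({"total_cn": cn, "label": label, "sample_id": "s"})
        base = clf.train_cn_only_baseline(table)
        assert clf.auroc(label, base.predict_prob(table)) > 0.5

    def test_constant_feature_rejected(self):
        table = pd.DataFrame(
            {"total_cn": [2.0] * 10, "label": [0, 1] * 5, "sample_id": "s"}
        )
        with pytest.raises(ValueError, match="constant"):
            clf.train_cn_only_baseline(table)

    def test_full_model_beats_baseline_on_simulated_cohort(self, small_features, small_model):
        baseline = clf.cv_baseline_auprc(small_features, k=4, seed=7)
        assert small_model.cv_auprc > baseline


class TestImportance:
    def test_importance_normalized_with_full_schema(self, small_model):
        imp = clf.feature_importance(small_model)
        assert set(imp) == set(FEATURE_COLUMNS)
        assert all(v >= 0 for v in imp.values())
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_informative_copy_number_ranks_first(self):
        rng = np.random.default_rng(8)
        n = 4000
        table = pd.DataFrame({c: rng.random(n) for c in FEATURE_COLUMNS})
        table["sample_id"] = [f"S{i % 50}" for i in range(n)]
        table["total_cn"] = rng.integers(1, 50, size=n).astype(float)
        table["label"] = (table["total_cn"] > 40).astype(int)
        model = clf.train(
            table, clf.ModelConfig(k_folds=3, n_search=2, max_rounds=50, seed=2)
        )
        imp = clf.feature_importance(model)
        assert max(imp, key=imp.get) == "total_cn"
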