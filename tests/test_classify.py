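"""CV scheme, ANOVA ranking, SVM label transfer, harmonization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omisurv as om
from omisurv.classify import anova_f
from omisurv.containers import RiskLabels


def _labels(groups, index):
    return RiskLabels(pd.Series(groups, index=index), risk_order=sorted(set(groups)))


class TestCvPartition:
    def test_ten_combinations(self):
        part = om.make_cv_partitions([f"s{i}" for i in range(100)], seed=0)
        assert len(part.combinations) == 10

    def test_fold_sizes_near_equal(self):
        part = om.make_cv_partitions([f"s{i}" for i in range(100)], seed=1)
        sizes = part.fold.value_counts()
        assert sizes.min() >= 19 and sizes.max() <= 21

    def test_same_seed_same_folds(self):
        ids = [f"s{i}" for i in range(37)]
        a = om.make_cv_partitions(ids, seed=3)
        b = om.make_cv_partitions(ids, seed=3)
        pd.testing.assert_series_equal(a.fold, b.fold)

    def test_sample_membership_counts(self):
        # a sample's fold sits in the 2-fold test set of C(4,1)=4 combinations
        # and in the 3-fold training set of the other C(4,2)=6
        part = om.make_cv_partitions([f"s{i}" for i in range(50)], seed=2)
        test_counts = {s: 0 for s in part.fold.index}
        train_counts = {s: 0 for s in part.fold.index}
        for idx in range(len(part.combinations)):
            train, test = part.split(idx)
            assert set(train).isdisjoint(test)
            assert len(train) + len(test) == 50
            for s in test:
                test_counts[s] += 1
            for s in train:
                train_counts[s] += 1
        assert set(test_counts.values()) == {4}
        assert set(train_counts.values()) == {6}

    def test_train_folds_must_be_smaller(self):
        with pytest.raises(ValueError):
            om.make_cv_partitions([f"s{i}" for i in range(20)], n_folds=5, train_folds=5)


class TestAnovaRank:
    def test_hand_example_f8(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        labels = _labels(["A", "A", "B", "B"], list("abcd"))
        ranking = om.anova_rank(X, labels, top_n=1)
        assert ranking.table.loc["f", "F"] == pytest.approx(8.0)

    def test_constant_feature_f_zero(self):
        X = pd.DataFrame({"f": [2.0] * 6}, index=[f"s{i}" for i in range(6)])
        labels = _labels(["A"] * 3 + ["B"] * 3, X.index)
        ranking = om.anova_rank(X, labels, top_n=1)
        assert ranking.table.loc["f", "F"] == 0.0

    def test_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 8))
        groups = np.array(["A"] * 15 + ["B"] * 15)
        F = anova_f(X, groups)
        t = stats.ttest_ind(X[:15], X[15:], equal_var=True).statistic
        assert np.allclose(F, t**2, rtol=1e-8)

    def test_top_n_clamped_with_warning(self):
        X = pd.DataFrame(
            np.random.default_rng(1).normal(size=(10, 3)),
            index=[f"s{i}" for i in range(10)],
            columns=list("xyz"),
        )
        labels = _labels(["A"] * 5 + ["B"] * 5, X.index)
        ranking = om.anova_rank(X, labels, top_n=10)
        assert len(ranking.top_features) == 3

    def test_zero_within_variance_ranked_first(self):
        X = pd.DataFrame(
            {"perfect": [0.0, 0.0, 1.0, 1.0], "noisy": [0.1, 0.9, 0.2, 0.8]},
            index=list("abcd"),
        )
        labels = _labels(["A", "A", "B", "B"], list("abcd"))
        ranking = om.anova_rank(X, labels, top_n=1)
        assert ranking.top_features == ["perfect"]


class TestSvmClassifier:
    @pytest.fixture()
    def separable(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.3, (25, 2)), rng.normal(4, 0.3, (25, 2))])
        idx = [f"s{i}" for i in range(50)]
        feats = pd.DataFrame(X, index=idx, columns=["u", "v"])
        labels = _labels(["G1"] * 25 + ["G2"] * 25, idx)
        return feats, labels

    def test_separable_training_accuracy(self, separable):
        feats, labels = separable
        model = om.fit_label_classifier(feats, labels, seed=0)
        pred = om.predict_labels(model, feats)
        assert (pred.labels == labels.labels).all()

    def test_prediction_carries_orientation(self, separable):
        feats, labels = separable
        model = om.fit_label_classifier(feats, labels, seed=0)
        pred = om.predict_labels(model, feats)
        assert pred.higher_risk == "G2"

    def test_permuted_labels_near_chance(self, separable):
        feats, labels = separable
        rng = np.random.default_rng(8)
        permuted = RiskLabels(
            pd.Series(rng.permutation(labels.labels.to_numpy()), index=feats.index),
            risk_order=["G1", "G2"],
        )
        model = om.fit_label_classifier(feats, permuted, seed=0)
        assert abs(model.cv_accuracy - 0.5) <= 0.15

    def test_grid_choice_deterministic(self, separable):
        feats, labels = separable
        m1 = om.fit_label_classifier(feats, labels, seed=3)
        m2 = om.fit_label_classifier(feats, labels, seed=3)
        assert m1.best_params == m2.best_params

    def test_missing_feature_named_in_error(self, separable):
        feats, labels = separable
        model = om.fit_label_classifier(feats, labels, seed=0)
        with pytest.raises(ValueError, match="v"):
            om.predict_labels(model, feats[["u"]])

    def test_single_class_rejected(self, separable):
        feats, _ = separable
        labels = _labels(["G1"] * 50, feats.index)
        with pytest.raises(ValueError, match="single class"):
            om.fit_label_classifier(feats, labels)


class TestHarmonize:
    def test_median_centering_by_hand(self):
        ref = pd.DataFrame(
            {"f": [1.0, 2.0, 3.0, 100.0], "g": [0.0, 1.0, 2.0, 3.0]}, index=list("abcd")
        )
        ext = ref * 1.0
        href, hext = om.harmonize_external(ref, ext)
        med = 2.5  # median of [1,2,3,100]; centered: [-1.5,-0.5,0.5,97.5]
        iqr = np.percentile([1, 2, 3, 100], 75) - np.percentile([1, 2, 3, 100], 25)
        expected = (np.array([1.0, 2.0, 3.0, 100.0]) - med) / iqr
        assert np.allclose(href["f"], expected)

    def test_identical_datasets_identical_transform(self):
        rng = np.random.default_rng(2)
        ref = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        href, hext = om.harmonize_external(ref, ref.copy())
        pd.testing.assert_frame_equal(href, hext)

    def test_affine_shift_invariance(self):
        """Per-feature shifts of the external cohort vanish after harmonization."""
        rng = np.random.default_rng(4)
        ref = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        ext = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        shift = pd.Series(rng.uniform(-50, 50, 6), index=ext.columns)
        _, h1 = om.harmonize_external(ref, ext)
        _, h2 = om.harmonize_external(ref, ext + shift)
        pd.testing.assert_frame_equal(h1, h2, check_exact=False, atol=1e-10)

    def test_disjoint_features_error(self):
        ref = pd.DataFrame({"a": [1.0, 2.0]})
        ext = pd.DataFrame({"b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="common"):
            om.harmonize_external(ref, ext)

    def test_zero_iqr_left_unscaled(self):
        ref = pd.DataFrame({"a": [1.0, 1.0, 1.0, 5.0], "b": [2.0, 2.0, 2.0, 2.0]})
        href, _ = om.harmonize_external(ref, ref.copy())
        assert np.allclose(href["b"], 0.0)  # centered, divided by 1
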