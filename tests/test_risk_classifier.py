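"""Larval-risk classifier: training, thresholding, CV, importance, and
recovery of a known generating process."""

import numpy as np
import pytest

from lsm_eval import synthetic_data as sd
from lsm_eval.core_io import (
    FEATURE_LEVELS,
    RecordValidationError,
    WaterbodyFeatures,
)
from lsm_eval.risk_classifier import (
    ClassifierConfig,
    cross_validate,
    feature_importance,
    field_validation,
    predict_risk,
    train,
    tune_recall_first,
)


def toy_features(n, rng):
    """Random features whose label is exactly 'very turbid'."""
    feats = []
    for _ in range(n):
        feats.append(WaterbodyFeatures(
            waterbody_type=rng.choice(FEATURE_LEVELS["waterbody_type"]),
            origin=rng.choice(FEATURE_LEVELS["origin"]),
            area_size_class=rng.choice(FEATURE_LEVELS["area_size_class"]),
            vegetation_inside=bool(rng.integers(2)),
            vegetation_around=bool(rng.integers(2)),
            visual_turbidity=rng.choice(FEATURE_LEVELS["visual_turbidity"]),
        ))
    labels = [int(f.visual_turbidity == "very turbid") for f in feats]
    return feats, labels


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(7)
    return toy_features(200, rng)


@pytest.fixture(scope="module")
def toy_model(toy):
    feats, labels = toy
    return train(feats, labels, ClassifierConfig(random_seed=7))


class TestTrainPredict:
    def test_separable_rule_learned_exactly(self, toy, toy_model):
        """A single-feature deterministic rule gives training precision
        and recall of 1."""
        feats, labels = toy
        preds = predict_risk(toy_model, feats)
        assert [p.label for p in preds] == labels

    def test_threshold_consistency_row_by_row(self, toy, toy_model):
        for p in predict_risk(toy_model, toy[0]):
            assert p.label == int(p.probability >= p.threshold)

    def test_threshold_monotonicity(self, toy, toy_model):
        """Raising the decision threshold never increases the number of
        high-risk calls; extreme thresholds give all-high / all-low."""
        feats, _ = toy
        probs = toy_model.predict_proba(feats)
        counts = [(probs >= t).sum() for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[0] == len(feats)
        assert (probs >= 1.0 + 1e-12).sum() == 0

    def test_determinism_given_seed(self, toy):
        feats, labels = toy
        m1 = train(feats, labels, ClassifierConfig(random_seed=11))
        m2 = train(feats, labels, ClassifierConfig(random_seed=11))
        assert np.array_equal(m1.predict_proba(feats), m2.predict_proba(feats))

    def test_duplicated_consistent_rows_reproduced(self):
        f = WaterbodyFeatures("reservoir", "natural", "large", False, False,
                              "clean")
        g = WaterbodyFeatures("puddle made by rain", "natural", "small", True,
                              True, "very turbid")
        feats = [f] * 30 + [g] * 30
        labels = [0] * 30 + [1] * 30
        model = train(feats, labels, ClassifierConfig(random_seed=0))
        assert [p.label for p in predict_risk(model, [f, g])] == [0, 1]

    def test_single_class_rejected(self, toy):
        feats, _ = toy
        with pytest.raises(ValueError):
            train(feats, [1] * len(feats), ClassifierConfig())

    def test_unknown_level_named_in_error(self, toy_model):
        bad = WaterbodyFeatures.__new__(WaterbodyFeatures)
        object.__setattr__(bad, "waterbody_type", "swimming pool")
        for name in ("origin", "area_size_class", "vegetation_inside",
                     "vegetation_around", "visual_turbidity"):
            object.__setattr__(bad, name, list(FEATURE_LEVELS[name])[0])
        with pytest.raises(RecordValidationError, match="swimming pool"):
            predict_risk(toy_model, [bad])


class TestCrossValidation:
    def test_separable_toy_recall_is_one(self, toy):
        feats, labels = toy
        metrics = cross_validate(feats, labels, ClassifierConfig(random_seed=7))
        assert metrics.recall == pytest.approx(1.0)
        assert metrics.accuracy == pytest.approx(1.0)

    def test_fold_structure(self, toy):
        feats, labels = toy
        cfg = ClassifierConfig(cv_folds=5, random_seed=7)
        metrics = cross_validate(feats, labels, cfg)
        assert len(metrics.fold_recall) == 5
        assert metrics.recall == pytest.approx(np.mean(metrics.fold_recall))

    def test_bayes_rule_recovery_on_synthetic_data(self, synth_waterbodies):
        """Held-out recall and precision land within 0.05 of the exact
        Bayes-rule values computed over the full 672-cell feature
        lattice — the classifier recovers the generating process."""
        _, features, labels, truth = synth_waterbodies
        metrics = cross_validate(features, labels,
                                 ClassifierConfig(random_seed=42))
        bayes = truth.bayes_metrics()
        assert metrics.recall == pytest.approx(bayes["recall"], abs=0.05)
        assert metrics.precision == pytest.approx(bayes["precision"], abs=0.05)
        assert metrics.accuracy == pytest.approx(bayes["accuracy"], abs=0.05)

    def test_label_permutation_null(self, synth_waterbodies):
        """With labels shuffled, CV accuracy falls to the base rate."""
        _, features, labels, _ = synth_waterbodies
        rng = np.random.default_rng(1)
        permuted = list(rng.permutation(labels))
        metrics = cross_validate(features[:2000], permuted[:2000],
                                 ClassifierConfig(random_seed=1))
        base = max(np.mean(permuted[:2000]), 1 - np.mean(permuted[:2000]))
        assert metrics.accuracy == pytest.approx(base, abs=0.05)

    def test_stratification_needs_enough_members(self, toy):
        feats, _ = toy
        labels = [1] * 3 + [0] * (len(feats) - 3)
        with pytest.raises(ValueError, match="cv_folds"):
            cross_validate(feats, labels, ClassifierConfig(cv_folds=5))


class TestFeatureImportance:
    def test_single_informative_feature_dominates(self, toy, toy_model):
        feats, labels = toy
        report = feature_importance(toy_model, feats, labels)
        assert report.rfi["visual_turbidity"] > 90.0

    def test_rfi_sums_to_100(self, toy, toy_model):
        feats, labels = toy
        report = feature_importance(toy_model, feats, labels)
        assert sum(report.rfi.values()) == pytest.approx(100.0)

    def test_generator_ordering_recovered(self, synth_waterbodies):
        """The two heaviest generator weights (turbidity, waterbody type)
        are the top-2 ranked features."""
        _, features, labels, _ = synth_waterbodies
        model = train(features, labels, ClassifierConfig(random_seed=42))
        report = feature_importance(model, features, labels)
        top2 = {name for name, _ in report.ranked()[:2]}
        assert top2 == {"visual_turbidity", "waterbody_type"}


class TestFieldValidation:
    def test_all_correct(self, toy, toy_model):
        feats, labels = toy
        out = field_validation(predict_risk(toy_model, feats), labels)
        assert out["accuracy"] == 1.0
        assert out["fp"] == out["fn"] == 0

    def test_degenerate_all_high_classifier(self):
        from lsm_eval.core_io import RiskLabel
        preds = [RiskLabel(probability=1.0)] * 10
        obs = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        out = field_validation(preds, obs)
        assert out["recall"] == 1.0
        assert out["precision"] == pytest.approx(0.3)

    def test_counts_match_loop_oracle(self):
        from lsm_eval.core_io import RiskLabel
        rng = np.random.default_rng(3)
        probs = rng.random(50)
        obs = list(rng.integers(0, 2, 50))
        preds = [RiskLabel(probability=float(p)) for p in probs]
        out = field_validation(preds, obs)
        tp = sum(1 for p, o in zip(preds, obs) if p.label == 1 and o == 1)
        fp = sum(1 for p, o in zip(preds, obs) if p.label == 1 and o == 0)
        fn = sum(1 for p, o in zip(preds, obs) if p.label == 0 and o == 1)
        tn = sum(1 for p, o in zip(preds, obs) if p.label == 0 and o == 0)
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (tp, fp, fn, tn)
        assert tp + fp + fn + tn == 50

    def test_length_mismatch_rejected(self):
        from lsm_eval.core_io import RiskLabel
        with pytest.raises(ValueError):
            field_validation([RiskLabel(probability=0.9)], [1, 0])


class TestRecallFirstTuning:
    def test_selected_model_clears_precision_floor(self, synth_waterbodies):
        _, features, labels, _ = synth_waterbodies
        cfg, metrics = tune_recall_first(
            features[:1500], labels[:1500],
            ClassifierConfig(random_seed=42), depth_grid=(4, 10),
        )
        assert metrics.precision >= 0.3
        assert cfg.max_tree_depth in (4, 10)
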