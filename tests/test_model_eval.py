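import numpy as np
import pandas as pd
import pytest

from facepulse.errors import ClassMissingError, SchemaError
from facepulse.labeling import LabeledDataset
from facepulse.model_eval import (
    ConfusionMatrix,
    confusion_from_predictions,
    cross_validate_10fold,
    evaluate_holdout,
    feature_importance,
    feature_matrix,
    load_model,
    metrics_from_confusion,
    save_model,
    train_classifier,
)

# Printed 10-fold-CV confusion counts and metrics for the four subjects.
# Precision for subjects 2 and 3 is printed with one decimal only.
TABLE4_CV = [
    dict(tp=3584, fn=717, fp=1213, tn=3088, accuracy=(0.78, 2), precision=(0.75, 2),
         recall=(0.83, 2), f1=(0.79, 2)),
    dict(tp=1914, fn=649, fp=499, tn=2064, accuracy=(0.78, 2), precision=(0.8, 1),
         recall=(0.75, 2), f1=(0.77, 2)),
    dict(tp=6499, fn=2459, fp=1652, tn=7309, accuracy=(0.77, 2), precision=(0.8, 1),
         recall=(0.73, 2), f1=(0.76, 2)),
    dict(tp=1850, fn=175, fp=342, tn=1683, accuracy=(0.87, 2), precision=(0.84, 2),
         recall=(0.91, 2), f1=(0.88, 2)),
]


def iid_dataset(n=300, informative=1, noise=9, shift=2.0, seed=0) -> LabeledDataset:
    """Balanced iid rows: `informative` shifted features + pure-noise features."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    cols = {}
    for j in range(informative):
        cols[f"sig{j}"] = rng.normal(size=n) + shift * labels
    for j in range(noise):
        cols[f"noise{j}"] = rng.normal(size=n)
    features = pd.DataFrame(cols)
    features.insert(0, "frame", np.arange(n))
    return LabeledDataset(
        features=features,
        labels=labels.astype(np.int8),
        provenance=np.full(n, -1, dtype=np.int64),
        fps=30.0,
    )


class TestMetricsFromConfusion:
    def test_subject1_worked_example(self):
        report = metrics_from_confusion(ConfusionMatrix(tp=3584, fn=717, fp=1213, tn=3088))
        rounded = report.rounded(2)
        assert rounded == {"accuracy": 0.78, "precision": 0.75, "recall": 0.83, "f1": 0.79}

    @pytest.mark.parametrize("row", TABLE4_CV)
    def test_all_printed_cv_cells(self, row):
        report = metrics_from_confusion(
            ConfusionMatrix(tp=row["tp"], fp=row["fp"], fn=row["fn"], tn=row["tn"])
        )
        for metric in ("accuracy", "precision", "recall", "f1"):
            printed, ndigits = row[metric]
            assert round(getattr(report, metric), ndigits) == printed, metric

    def test_perfect_prediction(self):
        report = metrics_from_confusion(ConfusionMatrix(tp=1, fp=0, fn=0, tn=1))
        assert report.accuracy == report.precision == report.recall == report.f1 == 1.0

    def test_zero_denominator_is_missing_not_zero(self):
        report = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert report.precision is None
        assert report.f1 is None
        assert report.recall == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)

    def test_f1_is_harmonic_mean(self):
        report = metrics_from_confusion(ConfusionMatrix(tp=30, fp=10, fn=20, tn=40))
        expected = 2 * report.precision * report.recall / (report.precision + report.recall)
        assert report.f1 == pytest.approx(expected)


class TestTrainClassifier:
    def test_separable_data_fits_perfectly(self):
        dataset = iid_dataset(shift=10.0)
        X, y = feature_matrix(dataset)
        model = train_classifier(X, y, seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_deterministic_under_seed(self):
        dataset = iid_dataset(seed=3)
        X, y = feature_matrix(dataset)
        p1 = train_classifier(X, y, seed=5).predict(X)
        p2 = train_classifier(X, y, seed=5).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        with pytest.raises(ClassMissingError):
            train_classifier(X, np.ones(20), seed=0)

    def test_pure_noise_is_chance_level(self):
        # iid rows: CV accuracy should hover around 0.5 over seeds
        accs = []
        for seed in range(10):
            dataset = iid_dataset(n=200, informative=0, noise=5, seed=seed)
            cv = cross_validate_10fold(dataset, seed=seed)
            accs.append(cv.pooled_metrics.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.05


class TestCrossValidate:
    def test_fold_bookkeeping(self):
        dataset = iid_dataset(n=100)
        cv = cross_validate_10fold(dataset, seed=0)
        assert len(cv.fold_matrices) == 10
        assert all(m.total == 10 for m in cv.fold_matrices)
        assert cv.pooled_matrix.total == 100

    def test_stratification_within_one_row(self):
        dataset = iid_dataset(n=200)
        cv = cross_validate_10fold(dataset, seed=1)
        for m in cv.fold_matrices:
            assert abs((m.tp + m.fn) - (m.fp + m.tn)) <= 1

    def test_fold_average_close_to_pooled(self):
        dataset = iid_dataset(n=500, shift=1.5, seed=2)
        cv = cross_validate_10fold(dataset, seed=2)
        fold_mean = np.mean([m.accuracy for m in cv.fold_metrics])
        assert abs(fold_mean - cv.pooled_metrics.accuracy) < 0.02

    def test_too_few_rows_rejected(self):
        dataset = iid_dataset(n=18)
        with pytest.raises(ValueError):
            cross_validate_10fold(dataset, seed=0)

    def test_grouped_mode_requires_groups(self):
        dataset = iid_dataset(n=100)
        with pytest.raises(ValueError):
            cross_validate_10fold(dataset, seed=0, fold_mode="grouped")

    def test_grouped_mode_keeps_groups_intact(self):
        dataset = iid_dataset(n=200, seed=4)
        groups = np.arange(200) // 5
        cv = cross_validate_10fold(dataset, seed=4, fold_mode="grouped", groups=groups)
        assert cv.pooled_matrix.total == 200


class TestEvaluateHoldout:
    def test_train_equals_test_on_separable(self):
        dataset = iid_dataset(shift=10.0)
        X, y = feature_matrix(dataset)
        model = train_classifier(X, y, seed=0)
        cm, metrics = evaluate_holdout(model, dataset)
        assert metrics.accuracy == 1.0
        assert cm.total == len(X)

    def test_label_permutation_is_chance_level(self):
        accs = []
        for seed in range(5):
            dataset = iid_dataset(n=400, shift=3.0, seed=seed)
            X, y = feature_matrix(dataset)
            model = train_classifier(X, y, seed=seed)
            rng = np.random.default_rng(seed)
            permuted = LabeledDataset(
                features=dataset.features,
                labels=rng.permutation(dataset.labels),
                provenance=dataset.provenance,
                fps=30.0,
            )
            accs.append(evaluate_holdout(model, permuted)[1].accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_schema_mismatch_rejected(self):
        dataset = iid_dataset()
        X, y = feature_matrix(dataset)
        model = train_classifier(X, y, seed=0)
        other = iid_dataset()
        other.features = other.features.rename(columns={"sig0": "renamed"})
        with pytest.raises(SchemaError):
            evaluate_holdout(model, other)


class TestFeatureImportance:
    def test_informative_feature_ranks_first(self):
        wins = 0
        for seed in range(10):
            dataset = iid_dataset(n=300, informative=1, noise=9, shift=2.0, seed=seed)
            X, y = feature_matrix(dataset)
            model = train_classifier(X, y, seed=seed)
            ranking = feature_importance([model], list(X.columns))
            wins += ranking.ranking[0][0] == "sig0"
        assert wins >= 9

    def test_all_noise_importance_is_flat(self):
        for seed in range(10):
            dataset = iid_dataset(n=300, informative=0, noise=10, seed=seed)
            X, y = feature_matrix(dataset)
            model = train_classifier(X, y, seed=seed)
            ranking = feature_importance([model], list(X.columns))
            weights = [w for _, w in ranking.ranking]
            assert max(weights) < 3 * np.mean(weights)

    def test_weights_sum_to_one_and_sorted(self):
        dataset = iid_dataset()
        X, y = feature_matrix(dataset)
        models = [train_classifier(X, y, seed=s) for s in range(3)]
        ranking = feature_importance(models, list(X.columns))
        weights = [w for _, w in ranking.ranking]
        assert sum(weights) == pytest.approx(1.0, abs=1e-9)
        assert weights == sorted(weights, reverse=True)

    def test_untrained_model_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(ValueError):
            feature_importance([RandomForestClassifier()], ["a"])


def test_confusion_from_predictions():
    cm = confusion_from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 1)


def test_model_save_load_round_trip(tmp_path):
    dataset = iid_dataset()
    X, y = feature_matrix(dataset)
    model = train_classifier(X, y, seed=0)
    path = tmp_path / "model.joblib"
    save_model(model, list(X.columns), path)
    loaded, names = load_model(path)
    np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
    assert names == list(X.columns)


@pytest.fixture(scope="module")
def roleplay_trained():
    from facepulse.labeling import label_dataset
    from facepulse.pipeline import temporal_groups
    from facepulse.preprocess import preprocess
    from facepulse.synth_data import SynthConfig, simulate_session
    from facepulse.temporal_features import build_feature_table

    cfg = SynthConfig(seed=31, duration_s=300, n_utterances=16)
    session, _ = simulate_session(cfg)
    labeled = label_dataset(build_feature_table(session), session.annotations)
    clean, _ = preprocess(labeled, seed=0)
    groups = temporal_groups(clean)
    cv = cross_validate_10fold(clean, seed=0, fold_mode="grouped", groups=groups)
    X, y = feature_matrix(clean)
    model = train_classifier(X, y, seed=0)
    return cfg, model, cv


class TestRolePlayHoldout:
    """Cross-session generalization: train on one synthetic session, score a
    role-play session drawn from the same (or perturbed) generator parameters."""

    def _holdout(self, cfg, model, shift):
        from facepulse.labeling import label_dataset
        from facepulse.preprocess import preprocess
        from facepulse.synth_data import make_role_play_set
        from facepulse.temporal_features import build_feature_table

        session, _ = make_role_play_set(cfg, shift=shift)
        labeled = label_dataset(build_feature_table(session), session.annotations)
        clean, _ = preprocess(labeled, seed=1)
        _, metrics = self._evaluate(model, clean)
        return metrics

    @staticmethod
    def _evaluate(model, dataset):
        return evaluate_holdout(model, dataset)

    def test_same_parameters_generalize(self, roleplay_trained):
        cfg, model, cv = roleplay_trained
        metrics = self._holdout(cfg, model, shift=0.0)
        assert metrics.accuracy >= 0.75
        # grouped CV is slightly pessimistic (few groups per session), so the
        # distribution-match band is wider than the fold-level noise alone
        assert abs(metrics.accuracy - cv.pooled_metrics.accuracy) < 0.15

    def test_zeroed_effects_degrade_to_chance(self, roleplay_trained):
        cfg, model, _ = roleplay_trained
        metrics = self._holdout(cfg, model, shift=-1.0)
        assert abs(metrics.accuracy - 0.5) < 0.1
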