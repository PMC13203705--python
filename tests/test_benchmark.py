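import numpy as np
import pandas as pd
import pytest
from scipy import stats

from specmap.benchmark import (
    ClassifierConfig,
    LabelledDataset,
    build_classifier,
    compare_modalities,
    default_configs,
    make_patient_folds,
    render_classification_map,
    train_eval,
)
from specmap.benchmark import BenchmarkReport

from conftest import make_cube


def toy_dataset(rng, n_patients=10, per_patient=40, n_classes=4, sep=4.0, bands=6):
    """Gaussian blobs per class, every patient contributing all classes."""
    xs, ys, ps, ims = [], [], [], []
    centers = rng.normal(0, 1, (n_classes, bands)) * sep
    for p in range(n_patients):
        for _ in range(per_patient):
            c = int(rng.integers(0, n_classes))
            xs.append(centers[c] + rng.normal(0, 1, bands))
            ys.append(c + 1)
            ps.append(f"patient-{p:02d}")
            ims.append(f"image-{p:02d}-0")
    return LabelledDataset(
        samples=np.array(xs), labels=np.array(ys),
        patient_ids=np.array(ps), image_ids=np.array(ims),
    )


def report_from(scores: dict[str, list[float]], metric="macro_f1") -> BenchmarkReport:
    rows = [
        {"classifier": clf, "fold": k, metric: v}
        for clf, vals in scores.items()
        for k, v in enumerate(vals)
    ]
    n = len(next(iter(scores.values())))
    return BenchmarkReport(scores=pd.DataFrame(rows), class_names=("a",), n_folds=n)


class TestPatientFolds:
    def test_balanced_partition(self, rng):
        ds = toy_dataset(rng, n_patients=10)
        folds = make_patient_folds(ds, k=5, seed=0)
        per_fold_patients = [
            set(ds.patient_ids[folds == f]) for f in range(5)
        ]
        assert all(len(s) == 2 for s in per_fold_patients)
        assert set().union(*per_fold_patients) == set(ds.patients)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not per_fold_patients[i] & per_fold_patients[j]

    def test_no_patient_split_across_folds(self, rng):
        ds = toy_dataset(rng, n_patients=7)
        folds = make_patient_folds(ds, k=5, seed=3)
        for p in ds.patients:
            assert np.unique(folds[ds.patient_ids == p]).size == 1

    def test_deterministic_for_fixed_seed(self, rng):
        ds = toy_dataset(rng)
        np.testing.assert_array_equal(
            make_patient_folds(ds, 5, seed=9), make_patient_folds(ds, 5, seed=9)
        )

    def test_fewer_patients_than_folds_rejected(self, rng):
        ds = toy_dataset(rng, n_patients=3)
        with pytest.raises(ValueError, match="patients"):
            make_patient_folds(ds, k=5)

    def test_cohort_scale_partition(self, rng):
        """34 patients / 61 images: valid 5-fold partition, no patient split."""
        from specmap.synthdata import make_brain_cohort
        from specmap.experiments import cohort_datasets  # noqa: F401  (API smoke)

        scenes = make_brain_cohort(34, 61, geometry=(10, 10), seed=0,
                                   labelled_per_class=5)
        pids = np.concatenate(
            [np.repeat(ann.patient_id, (ann.labels > 0).sum()) for _, ann in scenes]
        )
        ds = LabelledDataset(
            samples=np.zeros((pids.size, 3)),
            labels=np.concatenate([ann.labels[ann.labels > 0] for _, ann in scenes]),
            patient_ids=pids,
            image_ids=np.concatenate(
                [np.repeat(ann.image_id, (ann.labels > 0).sum()) for _, ann in scenes]
            ),
        )
        folds = make_patient_folds(ds, k=5, seed=1)
        for p in ds.patients:
            assert np.unique(folds[ds.patient_ids == p]).size == 1
        assert np.unique(folds).size == 5


class TestClassifierConfigs:
    def test_six_defaults_with_stated_hyperparameters(self):
        configs = {c.name: c.resolved() for c in default_configs()}
        assert configs["svm_linear"]["cost"] == 24.0
        assert configs["svm_rbf"]["gamma"] == 20.0
        assert configs["rf"]["n_trees"] == 50
        assert configs["knn_e"]["k"] == 20
        assert configs["mlp"]["learning_rate"] == 0.01
        assert configs["mlp"]["hidden_units"] == 100

    def test_exponent_reading_is_expressible(self):
        cfg = ClassifierConfig("svm_rbf", {"cost": 2.0**4, "gamma": 2.0**0})
        assert cfg.resolved()["cost"] == 16.0 and cfg.resolved()["gamma"] == 1.0

    def test_unknown_names_and_keys_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig("deep_net")
        with pytest.raises(ValueError):
            ClassifierConfig("rf", {"depth": 3})


class TestTrainEval:
    def test_separable_classes_reach_perfect_f1(self, rng):
        ds = toy_dataset(rng, sep=12.0)
        folds = make_patient_folds(ds, 5, seed=0)
        rep = train_eval(ds, folds, [ClassifierConfig("svm_rbf", {"gamma": 0.1})], seed=0)
        assert rep.summary.loc["svm_rbf", "macro_f1_mean"] == pytest.approx(1.0)

    def test_shuffled_labels_score_at_chance(self, rng):
        ds = toy_dataset(rng, n_patients=10, per_patient=60, sep=8.0)
        shuffled = LabelledDataset(
            samples=ds.samples, labels=rng.permutation(ds.labels),
            patient_ids=ds.patient_ids, image_ids=ds.image_ids,
        )
        folds = make_patient_folds(shuffled, 5, seed=0)
        rep = train_eval(shuffled, folds, [ClassifierConfig("knn_e")], seed=0)
        # chance oracle: 4 balanced classes -> expected macro F1 ~ 0.25
        assert abs(rep.summary.loc["knn_e", "macro_f1_mean"] - 0.25) < 0.1

    def test_macro_f1_is_unweighted_mean_of_class_f1(self, rng):
        from sklearn.metrics import f1_score

        y_true = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        y_pred = np.array([1, 2, 2, 2, 3, 1, 4, 4])
        per_class = f1_score(y_true, y_pred, labels=[1, 2, 3, 4], average=None)
        macro = f1_score(y_true, y_pred, labels=[1, 2, 3, 4], average="macro")
        assert macro == pytest.approx(per_class.mean())

    def test_precision_recall_confusion_arithmetic(self, rng):
        """TP=2, FP=1, FN=1 for the tumour class -> precision=recall=F1=2/3."""
        from specmap.benchmark import _fold_metrics

        y_true = np.array([2, 2, 2, 1, 1, 1])
        y_pred = np.array([2, 2, 1, 2, 1, 1])
        row = _fold_metrics(y_true, y_pred, np.array([1, 2]), ("normal", "tumour"))
        assert row["tumour_precision"] == pytest.approx(2 / 3)
        assert row["tumour_recall"] == pytest.approx(2 / 3)

    def test_missing_class_in_training_fold_rejected(self, rng):
        ds = toy_dataset(rng, n_patients=5)
        # confine class 1 to a single patient so some training split lacks it
        labels = ds.labels.copy()
        labels[(labels == 1) & (ds.patient_ids != "patient-00")] = 2
        labels[ds.patient_ids == "patient-00"] = 1
        bad = LabelledDataset(ds.samples, labels, ds.patient_ids, ds.image_ids)
        folds = make_patient_folds(bad, 5, seed=0)
        with pytest.raises(ValueError, match="absent"):
            train_eval(bad, folds, [ClassifierConfig("knn_e", {"k": 1})])


class TestCompareModalities:
    def test_identical_scores_give_no_rejections(self):
        a = report_from({"rf": [0.7, 0.8, 0.75, 0.72, 0.77]})
        out = compare_modalities(a, report_from({"rf": [0.7, 0.8, 0.75, 0.72, 0.77]}))
        assert not out["reject"].any()
        assert (out["p"] == 1.0).all()

    def test_paired_t_matches_distribution_oracle(self):
        b_scores = [0.5, 0.5, 0.5, 0.5, 0.5]
        a_scores = [0.5 + d for d in (1, 2, 3, 4, 5)]
        out = compare_modalities(report_from({"rf": a_scores}), report_from({"rf": b_scores}))
        # oracle: t = mean/ (sd/sqrt(n)); p from the Student-t survival function
        d = np.array([1.0, 2, 3, 4, 5])
        t_want = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_want = 2 * stats.t.sf(t_want, df=4)
        assert out["t"].iloc[0] == pytest.approx(t_want, abs=1e-4)
        assert t_want == pytest.approx(4.2426, abs=1e-4)
        assert out["p"].iloc[0] == pytest.approx(p_want, abs=1e-6)
        assert p_want == pytest.approx(0.0132, abs=5e-4)

    def test_holm_ladder_arithmetic(self):
        # p-values (0.01, 0.02, 0.04), family of 3, alpha 0.05:
        # thresholds 0.05/3, 0.05/2, 0.05 -> all three rejected
        a = report_from({"rf": [0.7] * 5, "knn_e": [0.7] * 5, "mlp": [0.7] * 5})
        out = compare_modalities(a, report_from(
            {"rf": [0.7] * 5, "knn_e": [0.7] * 5, "mlp": [0.7] * 5}
        ))
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests([0.01, 0.02, 0.04], alpha=0.05, method="holm")
        assert reject.all()
        assert (out["p_holm"] >= out["p"]).all()  # adjusted p never below raw

    def test_unpaired_reports_rejected(self):
        a = report_from({"rf": [0.7] * 5})
        with pytest.raises(ValueError, match="fold"):
            compare_modalities(a, report_from({"rf": [0.7] * 4}))
        with pytest.raises(ValueError, match="classifiers"):
            compare_modalities(a, report_from({"mlp": [0.7] * 5}))

    def test_rejections_shrink_with_alpha(self, rng):
        scores_a = {c: list(rng.uniform(0.6, 0.9, 5)) for c in ("rf", "mlp", "knn_e")}
        scores_b = {c: [v + 0.05 for v in vals] for c, vals in scores_a.items()}
        a, b = report_from(scores_a), report_from(scores_b)
        loose = compare_modalities(a, b, alpha=0.2)
        tight = compare_modalities(a, b, alpha=0.01)
        assert set(np.flatnonzero(tight["reject"])) <= set(np.flatnonzero(loose["reject"]))


class TestClassificationMap:
    def test_map_geometry_and_consistency(self, rng):
        ds = toy_dataset(rng, n_patients=4, per_patient=50, bands=5, sep=8.0)
        clf = build_classifier(ClassifierConfig("rf"), seed=0)
        clf.fit(ds.samples, ds.labels)
        cube = make_cube(np.abs(rng.normal(0, 4, (6, 7, 5))), state="normalized")
        pred, rgb = render_classification_map(cube, clf)
        assert pred.shape == (6, 7) and rgb.shape == (6, 7, 3)
        flat_pred = clf.predict(cube.values.reshape(-1, 5)).reshape(6, 7)
        np.testing.assert_array_equal(pred, flat_pred)

    def test_band_mismatch_rejected(self, rng):
        ds = toy_dataset(rng, n_patients=4, bands=5)
        clf = build_classifier(ClassifierConfig("rf"), seed=0)
        clf.fit(ds.samples, ds.labels)
        cube = make_cube(rng.uniform(0, 1, (3, 3, 7)), state="normalized")
        with pytest.raises(ValueError, match="bands"):
            render_classification_map(cube, clf)

    def test_single_class_model_gives_uniform_map(self, rng):
        from sklearn.dummy import DummyClassifier

        clf = DummyClassifier(strategy="constant", constant=4)
        clf.fit(rng.uniform(0, 1, (10, 3)), np.full(10, 4))
        cube = make_cube(rng.uniform(0, 1, (4, 4, 3)), state="normalized")
        pred, rgb = render_classification_map(cube, clf)
        assert (pred == 4).all()
        np.testing.assert_allclose(rgb, 0.0)  # background is black
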