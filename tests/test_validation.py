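"""Confusion metrics, the two resampling schemes, and the six learners."""
import numpy as np
import pandas as pd
import pytest

from eegcv.features import FeatureTable
from eegcv.validation import (
    CLASSIFIER_KINDS,
    ClassifierSpec,
    ConfusionCounts,
    CVSummary,
    FoldResult,
    confusion_metrics,
    fit_predict,
    lopo_cv,
    lopo_iterations,
    pooled_kfold_cv,
    population_sd,
    positive_class,
)


def toy_table(n_per_subject=20, subjects=("AD-1", "AD-2", "CN-1", "CN-2"),
              separation=5.0, noise=1.0, seed=0, n_features=3):
    """Gaussian blobs: class effect `separation` on the first feature."""
    rng = np.random.default_rng(seed)
    rows, labels, sids = [], [], []
    for sid in subjects:
        cls = sid.split("-")[0]
        shift = separation if cls == "AD" else 0.0
        x = rng.normal(0, noise, size=(n_per_subject, n_features))
        x[:, 0] += shift
        rows.append(x)
        labels += [cls] * n_per_subject
        sids += [sid] * n_per_subject
    data = pd.DataFrame(np.vstack(rows), columns=[f"f{i}" for i in range(n_features)])
    data["class"] = labels
    return FeatureTable(data, pd.Series(sids, name="subject_id"))


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        acc, sens, spec = confusion_metrics(ConfusionCounts(tp=3, tn=1, fp=1, fn=0))
        assert (acc, sens, spec) == (0.8, 1.0, 0.5)

    def test_no_positives_leaves_sensitivity_undefined(self):
        acc, sens, spec = confusion_metrics(ConfusionCounts(tp=0, tn=7, fp=0, fn=0))
        assert acc == 1.0
        assert np.isnan(sens)
        assert spec == 1.0

    def test_perfect_classifier(self):
        assert confusion_metrics(ConfusionCounts(10, 10, 0, 0)) == (1.0, 1.0, 1.0)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_counts_from_labels(self):
        c = ConfusionCounts.from_labels(
            ["AD", "AD", "CN", "CN"], ["AD", "CN", "CN", "AD"], positive="AD")
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)


def test_positive_class_is_the_patient_class():
    assert positive_class(("AD", "CN")) == "AD"
    assert positive_class(("CN", "FTD")) == "FTD"
    assert positive_class(("AD", "FTD")) == "AD"
    with pytest.raises(ValueError):
        positive_class(("AD", "FTD", "CN"))


class TestDispersion:
    def test_population_sd_hand_example(self):
        # mean 5; squared deviations sum 32; divisor N=8 -> sd 2 exactly
        assert population_sd([2, 4, 4, 4, 5, 5, 7, 9]) == 2.0

    def test_cv_summary_uses_divisor_n(self):
        accs = [0.6, 0.8, 1.0]
        folds = [
            FoldResult("a", ConfusionCounts(6, 0, 0, 4), 0.6, 1.0, np.nan),
            FoldResult("b", ConfusionCounts(8, 0, 0, 2), 0.8, 1.0, np.nan),
            FoldResult("c", ConfusionCounts(10, 0, 0, 0), 1.0, 1.0, np.nan),
        ]
        s = CVSummary("lopo", "knn", folds)
        assert s.mean_accuracy == pytest.approx(0.8)
        assert s.sd_accuracy == pytest.approx(population_sd(accs))
        assert s.sd_accuracy == pytest.approx(np.sqrt(np.mean((np.array(accs) - 0.8) ** 2)))

    def test_fold_metrics_recomputable_from_counts(self):
        table = toy_table()
        summary = pooled_kfold_cv(table, ClassifierSpec("naive_bayes"), k=5, seed=1)
        for fold in summary.folds:
            acc, sens, spec = confusion_metrics(fold.counts)
            assert fold.accuracy == pytest.approx(acc)
            assert fold.sensitivity == pytest.approx(sens)
            assert fold.specificity == pytest.approx(spec)
            assert fold.counts.total == len(table) // 5


class TestPooledKFold:
    def test_separable_classes_reach_full_accuracy(self):
        table = toy_table(separation=50.0, noise=0.1)
        s = pooled_kfold_cv(table, ClassifierSpec("decision_tree"), k=5, seed=0)
        assert s.mean_accuracy == 1.0

    def test_random_labels_score_at_chance(self):
        """With labels carrying no signal, accuracy stays within the binomial
        band around 0.5 (3 SE at n=400 is ~0.075)."""
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("abcd"))
        data["class"] = rng.permutation(["AD"] * 200 + ["CN"] * 200)
        table = FeatureTable(data, pd.Series([f"S{i}" for i in range(400)], name="subject_id"))
        s = pooled_kfold_cv(table, ClassifierSpec("naive_bayes"), k=10, seed=2)
        assert abs(s.mean_accuracy - 0.5) < 3 * np.sqrt(0.25 / 400) + 0.02

    def test_deterministic_given_seed(self):
        table = toy_table(separation=1.0)
        a = pooled_kfold_cv(table, ClassifierSpec("random_forest"), k=5, seed=3)
        b = pooled_kfold_cv(table, ClassifierSpec("random_forest"), k=5, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pooled_kfold_cv(toy_table(n_per_subject=2), ClassifierSpec("knn"), k=10)


class TestLopo:
    def test_two_subjects_per_class_gives_two_iterations(self):
        groups = {"AD-1": "AD", "AD-2": "AD", "CN-1": "CN", "CN-2": "CN"}
        its = lopo_iterations(groups)
        assert len(its) == 2
        for held in its:
            assert len(held) == 2
            assert {g[:2] for g in held} == {"AD", "CN"}

    def test_unequal_classes_round_robin(self):
        """10 vs 8 subjects: 10 iterations, smaller class reused i mod 8,
        and every subject of both classes is tested at least once."""
        groups = {f"AD-{i:02d}": "AD" for i in range(10)}
        groups.update({f"CN-{i:02d}": "CN" for i in range(8)})
        its = lopo_iterations(groups)
        assert len(its) == 10
        tested = {s for held in its for s in held}
        assert tested == set(groups)

    def test_train_test_subjects_disjoint_every_iteration(self):
        table = toy_table(separation=1.0)
        groups = table.groups()
        for held in lopo_iterations(groups):
            train_subjects = set(groups) - set(held)
            assert train_subjects.isdisjoint(held)
            assert train_subjects | set(held) == set(groups)

    def test_single_subject_class_rejected(self):
        with pytest.raises(ValueError, match="single subject"):
            lopo_iterations({"AD-1": "AD", "CN-1": "CN", "CN-2": "CN"})

    def test_lopo_on_separable_table(self):
        table = toy_table(separation=50.0, noise=0.1)
        s = lopo_cv(table, table.groups(), ClassifierSpec("decision_tree"), seed=0)
        assert s.scheme == "lopo"
        assert s.n_iterations == 2
        assert s.mean_accuracy == 1.0


class TestFitPredict:
    def test_decision_tree_memorizes_separable_training_set(self):
        table = toy_table(separation=50.0, noise=0.1)
        pred = fit_predict(ClassifierSpec("decision_tree"), table, table, seed=0)
        assert (pred == table.y).all()

    def test_1nn_returns_label_of_identical_training_point(self):
        table = toy_table(n_per_subject=5, separation=3.0)
        probe = table.subset(np.arange(len(table)) == 0)
        pred = fit_predict(ClassifierSpec("knn"), table, probe, seed=0)
        assert pred[0] == table.y[0]

    def test_naive_bayes_symmetry_under_class_swap(self):
        """Mirrored data with swapped labels yields mirrored predictions."""
        table = toy_table(separation=4.0, noise=0.5, seed=8)
        mirrored = table.data.copy()
        mirrored[table.feature_columns] = -mirrored[table.feature_columns]
        mirrored["class"] = table.data["class"].map({"AD": "CN", "CN": "AD"})
        mtable = FeatureTable(mirrored, table.subject_ids)
        p1 = fit_predict(ClassifierSpec("naive_bayes"), table, table)
        p2 = fit_predict(ClassifierSpec("naive_bayes"), mtable, mtable)
        assert (pd.Series(p1).map({"AD": "CN", "CN": "AD"}).to_numpy() == p2).all()

    def test_single_class_training_rejected(self):
        table = toy_table()
        ad_only = table.restrict_classes(("AD",))
        with pytest.raises(ValueError, match="both classes"):
            fit_predict(ClassifierSpec("knn"), ad_only, table)

    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_every_learner_fits_and_predicts(self, kind):
        table = toy_table(separation=8.0, noise=1.0)
        pred = fit_predict(ClassifierSpec(kind), table, table, seed=0)
        assert set(pred) <= {"AD", "CN"}
        assert (pred == table.y).mean() > 0.9

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("perceptron")
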