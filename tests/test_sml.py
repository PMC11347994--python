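"""K-means curation, stratified splits, classifier families and ROC/AUC."""
import numpy as np
import pytest

from serspen import (
    CLASSIFIER_FAMILIES,
    EndmemberSet,
    SpectraDataset,
    curate_training_set,
    evaluate,
    kmeans_cluster,
    roc_auc,
    split_dataset,
    train_classifier,
)
from serspen.errors import DomainError, EmptyDatasetError


class TestKmeans:
    def test_k1_gives_global_mean_and_total_inertia(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (50, 4))
        _, centroids, inertia = kmeans_cluster(X, 1, seed=0)
        assert np.allclose(centroids[0], X.mean(axis=0))
        assert inertia == pytest.approx(np.sum((X - X.mean(axis=0)) ** 2))

    def test_well_separated_blobs_perfectly_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (60, 3))
        b = rng.normal(20, 1, (60, 3))
        X = np.vstack([a, b])
        labels, _, _ = kmeans_cluster(X, 2, seed=0)
        # adjusted Rand = 1 <=> each blob maps to one cluster
        assert len(set(labels[:60])) == 1 and len(set(labels[60:])) == 1
        assert labels[0] != labels[60]

    def test_k_equals_n_zero_inertia(self):
        X = np.arange(12.0).reshape(6, 2)
        _, _, inertia = kmeans_cluster(X, 6, seed=0)
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_restarts_never_hurt(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (80, 5))
        _, _, single = kmeans_cluster(X, 4, seed=0, n_init=1)
        _, _, multi = kmeans_cluster(X, 4, seed=0, n_init=10)
        assert multi <= single + 1e-9

    def test_k_too_large_rejected(self):
        with pytest.raises(DomainError):
            kmeans_cluster(np.ones((3, 2)), 4, seed=0)


def _labeled_endmembers(three_refs):
    S = np.vstack([r.spectrum.intensities for r in three_refs[:2]])
    return EndmemberSet(S=S, names=[three_refs[0].name, three_refs[1].name])


class TestCuration:
    def test_pure_classes_fully_retained(self, three_refs):
        rng = np.random.default_rng(5)
        a = three_refs[0].spectrum.intensities
        n = 80
        X = np.vstack([
            np.outer(rng.uniform(0.9, 1.1, n), a) + rng.normal(0, 5, (n, a.size)),
            rng.normal(0, 5, (n, a.size)),
        ])
        E = EndmemberSet(S=a[None, :], names=[three_refs[0].name])
        ds = curate_training_set(X, E, k=2, seed=0)
        assert len(ds) == 2 * n  # zero discards
        assert set(ds.labels) == {three_refs[0].name, "background"}
        assert ds.labels.count(three_refs[0].name) == n

    def test_intermediate_band_raises_empty(self, three_refs):
        """Every centroid lands in the ambiguous (0.5, 0.8] band -> error."""
        rng = np.random.default_rng(6)
        a = three_refs[0].spectrum.intensities
        b = three_refs[1].spectrum.intensities
        # mixtures correlate moderately with the endmember, never > 0.8
        mix = 0.55 * a / np.linalg.norm(a) + 0.45 * b / np.linalg.norm(b)
        X = np.outer(rng.uniform(0.9, 1.1, 40), mix)
        E = EndmemberSet(S=a[None, :], names=[three_refs[0].name])
        sim = np.corrcoef(mix, a)[0, 1]
        assert 0.5 < sim <= 0.8  # fixture sits in the discard band
        with pytest.raises(EmptyDatasetError):
            curate_training_set(X, E, k=1, seed=0)

    def test_never_labels_below_threshold_as_pesticide(self, three_refs):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (100, 128))
        E = _labeled_endmembers(three_refs)
        ds = curate_training_set(X, E, k=4, seed=0)
        assert set(ds.labels) == {"background"}

    def test_unlabeled_endmembers_rejected(self, three_refs):
        E = EndmemberSet(S=three_refs[0].spectrum.intensities[None, :])
        with pytest.raises(DomainError):
            curate_training_set(np.ones((10, 128)), E)


class TestSplit:
    def _ds(self, counts):
        X, labels = [], []
        for cls, n in counts.items():
            X.append(np.full((n, 3), hash(cls) % 7, dtype=float))
            labels += [cls] * n
        return SpectraDataset(X=np.vstack(X), labels=labels)

    def test_70_30_split_counts(self):
        train, test = split_dataset(self._ds({"a": 100, "b": 100}), 0.7, seed=0)
        assert train.labels.count("a") == 70 and test.labels.count("a") == 30
        assert train.labels.count("b") == 70 and test.labels.count("b") == 30

    def test_round_half_up(self):
        train, test = split_dataset(self._ds({"a": 5, "b": 5}), 0.5, seed=0)
        assert train.labels.count("a") == 3 and test.labels.count("a") == 2

    def test_deterministic_and_disjoint(self):
        rng = np.random.default_rng(8)
        ds = SpectraDataset(X=rng.normal(0, 1, (60, 4)),
                            labels=["a"] * 30 + ["b"] * 30)
        t1, s1 = split_dataset(ds, 0.7, seed=1)
        t2, s2 = split_dataset(ds, 0.7, seed=1)
        assert np.array_equal(t1.X, t2.X) and np.array_equal(s1.X, s2.X)
        t3, _ = split_dataset(ds, 0.7, seed=2)
        assert not np.array_equal(t1.X, t3.X)
        assert len(t1) + len(s1) == len(ds)

    def test_tiny_class_rejected(self):
        with pytest.raises(DomainError):
            split_dataset(self._ds({"a": 1, "b": 10}), 0.7, seed=0)


def _separable_dataset(n=60, seed=9):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.5, (n, 6)) + np.r_[5, 0, 0, 0, 0, 0]
    b = rng.normal(0, 0.5, (n, 6)) + np.r_[0, 5, 0, 0, 0, 0]
    return SpectraDataset(X=np.vstack([a, b]), labels=["a"] * n + ["b"] * n)


class TestClassifiers:
    @pytest.mark.parametrize("family", ["lda", "logistic", "linear_svm"])
    def test_separable_fixture_perfect_training_accuracy(self, family):
        ds = _separable_dataset()
        model = train_classifier(ds, family, seed=0)
        assert model.predict(ds.X) == ds.labels

    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_deterministic_given_seed(self, family):
        ds = _separable_dataset()
        m1 = train_classifier(ds, family, seed=0)
        m2 = train_classifier(ds, family, seed=0)
        assert np.array_equal(m1.scores(ds.X), m2.scores(ds.X))

    def test_shuffled_labels_give_chance_auc(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ds = _separable_dataset(n=100, seed=seed)
            shuffled = SpectraDataset(
                X=ds.X, labels=[ds.labels[i] for i in rng.permutation(len(ds))]
            )
            train, test = split_dataset(shuffled, 0.7, seed=seed)
            model = train_classifier(train, "logistic", seed=seed)
            report = evaluate(model, test)
            aucs.extend(report.auc.values())
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_rejected(self):
        ds = SpectraDataset(X=np.ones((10, 3)), labels=["a"] * 10)
        with pytest.raises(DomainError):
            train_classifier(ds, "lda", seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        _, _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_anti_ordered(self):
        _, _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([1, 1, 0, 0]))
        assert auc == 0.0

    def test_matches_pairwise_oracle_with_ties(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.integers(0, 10, 50).astype(float)  # many ties
            y = rng.integers(0, 2, 50).astype(bool)
            if y.all() or not y.any():
                continue
            fpr, tpr, auc = roc_auc(scores, y)
            pos, neg = scores[y], scores[~y]
            wins = np.sum(pos[:, None] > neg[None, :])
            ties = np.sum(pos[:, None] == neg[None, :])
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc == pytest.approx(oracle, abs=1e-12)
            assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
            assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DomainError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestEvaluate:
    def test_perfect_model_diagonal_confusion(self):
        ds = _separable_dataset()
        model = train_classifier(ds, "lda", seed=0)
        report = evaluate(model, ds)
        assert report.confusion.loc["a", "a"] == 60
        assert report.confusion.loc["b", "b"] == 60
        assert report.confusion.loc["a", "b"] == 0
        assert all(a == pytest.approx(1.0, abs=1e-9) for a in report.auc.values())

    def test_proportional_scores_are_fractions(self):
        ds = _separable_dataset(n=20)
        model = train_classifier(ds, "lda", seed=0)
        mixed = SpectraDataset(X=ds.X, labels=ds.labels, group=["g1"] * 40)
        report = evaluate(model, mixed)
        row = report.proportional_scores.loc["g1"]
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
        assert row["a"] == pytest.approx(0.5) and row["b"] == pytest.approx(0.5)

    def test_confusion_row_sums_equal_class_counts(self):
        ds = _separable_dataset(n=25, seed=10)
        train, test = split_dataset(ds, 0.7, seed=0)
        model = train_classifier(train, "logistic", seed=0)
        report = evaluate(model, test)
        for cls in test.classes:
            assert report.confusion.loc[cls].sum() == test.labels.count(cls)

    def test_unknown_class_rejected(self):
        ds = _separable_dataset()
        model = train_classifier(ds, "lda", seed=0)
        bad = SpectraDataset(X=np.ones((2, 6)), labels=["zz", "zz"])
        with pytest.raises(DomainError):
            evaluate(model, bad)
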