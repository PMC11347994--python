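"""Spatial machine learning: K-means curation, stratified splitting,
classifier families, ROC/AUC, confusion matrices and proportional scores.

The curation step mirrors how a large unlabeled corpus of imaging spectra
is turned into a training set without manual annotation: over-cluster with
K-means, compare each cluster centroid to the labeled VCA endmembers, and
keep only clusters that are confidently a pesticide (centroid similarity
above the pesticide threshold) or confidently background (below the
suspected threshold); ambiguous clusters are discarded rather than trained
on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import DomainError, EmptyDatasetError
from .types import PipelineConfig
from .unmix import BACKGROUND_LABEL, EndmemberSet

__all__ = [
    "SpectraDataset",
    "ClassifierReport",
    "FittedClassifier",
    "CLASSIFIER_FAMILIES",
    "kmeans_cluster",
    "curate_training_set",
    "split_dataset",
    "train_classifier",
    "roc_auc",
    "evaluate",
]

CLASSIFIER_FAMILIES = ("lda", "logistic", "linear_svm", "random_forest")


@dataclass
class SpectraDataset:
    """Labeled spectra (rows of ``X``) with optional per-spectrum group ids."""

    X: np.ndarray
    labels: list[str]
    group: list[str] | None = None
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = [str(label) for label in self.labels]
        if len(self.labels) != self.X.shape[0]:
            raise DomainError("one label per spectrum required")
        if self.group is not None and len(self.group) != self.X.shape[0]:
            raise DomainError("one group id per spectrum required")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, idx: np.ndarray) -> "SpectraDataset":
        return SpectraDataset(
            X=self.X[idx],
            labels=[self.labels[i] for i in idx],
            group=None if self.group is None else [self.group[i] for i in idx],
            provenance=self.provenance,
        )


@dataclass
class ClassifierReport:
    """Evaluation bundle: per-class ROC/AUC, confusion matrix, scores."""

    roc: dict  # class -> (fpr, tpr) arrays
    auc: dict  # class -> float
    confusion: pd.DataFrame  # true x predicted counts
    proportional_scores: pd.DataFrame  # group x class fractions
    split_seed: int | None = None
    train_fraction: float | None = None


def kmeans_cluster(
    X: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` K-means (k-means++ seeding, Lloyd iterations)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not (1 <= k <= X.shape[0]):
        raise DomainError(f"k must lie in [1, n={X.shape[0]}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    assignments = km.fit_predict(X)
    return assignments, km.cluster_centers_, float(km.inertia_)


def _centroid_similarity(centroid: np.ndarray, endmember: np.ndarray) -> float:
    c = centroid - centroid.mean()
    e = endmember - endmember.mean()
    denom = np.linalg.norm(c) * np.linalg.norm(e)
    if denom == 0:
        return 0.0
    return float(np.dot(c, e) / denom)


def curate_training_set(
    X: np.ndarray,
    endmembers: EndmemberSet,
    cfg: PipelineConfig | None = None,
    k: int | None = None,
    seed: int = 0,
) -> SpectraDataset:
    """Label spectra by clustering against labeled VCA endmembers.

    Clusters whose centroid's best Pearson similarity to a pesticide
    endmember exceeds the pesticide threshold inherit that label; clusters
    below the suspected threshold become background; intermediate clusters
    are discarded.  Labels depend only on the centroid, so they are
    invariant to cluster index permutation.
    """
    cfg = cfg or PipelineConfig()
    if endmembers.names is None:
        raise DomainError("endmembers must be labeled (run match_endmembers first)")
    pesticide_idx = [i for i, n in enumerate(endmembers.names) if n != BACKGROUND_LABEL]
    if not pesticide_idx:
        raise DomainError("no pesticide-labeled endmember to curate against")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_expected = len(set(endmembers.names)) + (0 if BACKGROUND_LABEL in endmembers.names else 1)
    if k is None:
        k = 2 * n_expected  # over-cluster, then label
    assignments, centroids, _ = kmeans_cluster(X, k, seed)
    keep = np.zeros(X.shape[0], dtype=bool)
    labels = np.empty(X.shape[0], dtype=object)
    for c_idx in range(k):
        sims = [
            _centroid_similarity(centroids[c_idx], endmembers.S[i]) for i in pesticide_idx
        ]
        best = int(np.argmax(sims))
        members = assignments == c_idx
        if sims[best] > cfg.pesticide_threshold:
            keep |= members
            labels[members] = endmembers.names[pesticide_idx[best]]
        elif sims[best] < cfg.suspected_threshold:
            keep |= members
            labels[members] = BACKGROUND_LABEL
        # intermediate band: discarded
    if not np.any(keep):
        raise EmptyDatasetError(
            "no cluster passed the curation thresholds; nothing to train on"
        )
    idx = np.nonzero(keep)[0]
    return SpectraDataset(
        X=X[idx], labels=[labels[i] for i in idx], provenance="curated"
    )


def split_dataset(
    ds: SpectraDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[SpectraDataset, SpectraDataset]:
    """Stratified split: per class, round-half-up of ``fraction * n`` to train."""
    if not (0 < train_fraction < 1):
        raise DomainError("train_fraction must lie in (0, 1)")
    labels = np.asarray(ds.labels, dtype=object)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in ds.classes:
        members = np.nonzero(labels == cls)[0]
        if members.size < 2:
            raise DomainError(f"class {cls!r} has fewer than 2 members")
        perm = rng.permutation(members)
        n_train = int(np.floor(train_fraction * members.size + 0.5))
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


@dataclass
class FittedClassifier:
    """One-vs-rest scorer: per-class continuous scores + argmax prediction."""

    family: str
    classes: list[str]
    _model: object = field(repr=False)

    def scores(self, X: np.ndarray) -> np.ndarray:
        model = self._model
        if hasattr(model, "predict_proba"):
            s = model.predict_proba(X)
        else:
            s = model.decision_function(X)
            if s.ndim == 1:  # binary: expand to per-class columns
                s = np.column_stack([-s, s])
        return np.asarray(s, dtype=float)

    def predict(self, X: np.ndarray) -> list[str]:
        s = self.scores(X)
        return [self.classes[i] for i in np.argmax(s, axis=1)]


def train_classifier(
    train: SpectraDataset, family: str = "logistic", seed: int = 0
) -> FittedClassifier:
    """Fit one of the supported families as a one-vs-rest scorer."""
    if family not in CLASSIFIER_FAMILIES:
        raise DomainError(f"family must be one of {CLASSIFIER_FAMILIES}")
    classes = train.classes
    if len(classes) < 2:
        raise DomainError("training set must contain at least 2 classes")
    if family == "lda":
        base = LinearDiscriminantAnalysis()
    elif family == "logistic":
        base = make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    elif family == "linear_svm":
        base = make_pipeline(StandardScaler(), LinearSVC(random_state=seed))
    else:
        base = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    model = OneVsRestClassifier(base)
    model.fit(train.X, np.asarray(train.labels, dtype=object))
    fitted_classes = [str(c) for c in model.classes_]
    return FittedClassifier(family=family, classes=fitted_classes, _model=model)


def roc_auc(scores: np.ndarray, positives: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over unique scores; trapezoidal AUC.

    Tied scores collapse into a single ROC step, so the AUC equals the
    pairwise statistic P(score+ > score-) + 1/2 P(tie).  Returns
    ``(fpr, tpr, auc)`` with the curve anchored at (0,0) and (1,1).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(positives).astype(bool).ravel()
    if scores.size != y.size:
        raise DomainError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DomainError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    ys = y[order]
    last_of_group = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(ys)[last_of_group]
    fp = np.cumsum(~ys)[last_of_group]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate(model: FittedClassifier, test: SpectraDataset) -> ClassifierReport:
    """Held-out evaluation: one-vs-rest ROC/AUC per class, confusion matrix
    of argmax predictions, and per-group proportional scores."""
    if len(test) == 0:
        raise DomainError("test set is empty")
    unknown = set(test.labels) - set(model.classes)
    if unknown:
        raise DomainError(f"test contains classes unknown to the model: {sorted(unknown)}")
    S = model.scores(test.X)
    y = np.asarray(test.labels, dtype=object)
    roc: dict = {}
    auc: dict = {}
    for j, cls in enumerate(model.classes):
        pos = y == cls
        if pos.any() and (~pos).any():
            fpr, tpr, a = roc_auc(S[:, j], pos)
            roc[cls] = (fpr, tpr)
            auc[cls] = a
    preds = model.predict(test.X)
    confusion = pd.crosstab(
        pd.Series(list(y), name="true"),
        pd.Series(preds, name="predicted"),
        dropna=False,
    ).reindex(index=model.classes, columns=model.classes, fill_value=0)
    groups = test.group if test.group is not None else ["all"] * len(test)
    prop = pd.crosstab(
        pd.Series(groups, name="group"), pd.Series(preds, name="predicted")
    ).reindex(columns=model.classes, fill_value=0)
    prop = prop.div(prop.sum(axis=1), axis=0)
    return ClassifierReport(
        roc=roc, auc=auc, confusion=confusion, proportional_scores=prop
    )
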