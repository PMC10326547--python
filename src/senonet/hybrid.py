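"""Hybrid transfer-learning / machine-learning classifier.

Each of the backbones is used purely off-the-shelf: it turns an image into
a fixed 1-D feature vector (no retraining). Per backbone, the training-set
features pass through a PCA fitted on training rows only, then a
polynomial-kernel SVM whose hyperparameters are chosen by cross-validated
grid search. Each backbone therefore yields an independent label, and the
final call for an image is the majority among the per-backbone votes (hard
voting). The vote count doubles as an ordinal score: sweeping the threshold
"at least t of n backbones say senescent" traces a ROC curve for this
otherwise label-only classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from ._rng import mix_seed
from .architectures import BackboneHandle
from .data_io import DatasetBundle, Label
from .evaluation import ROCCurve

DEFAULT_SVM_GRID: dict[str, list] = {"degree": [2, 3], "C": [0.1, 1.0, 10.0]}
DEFAULT_VARIANCE_TARGET = 0.95


@dataclass
class FeatureMatrix:
    """One off-the-shelf feature vector per image, with aligned labels."""

    features: np.ndarray  # (n_images, dim)
    labels: np.ndarray  # (n_images,) binary, senescent = 1

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be (n, d) with aligned labels")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass
class VoteRecord:
    """Per-learner predicted labels for one image."""

    votes: list[Label]

    @property
    def vote_count_senescent(self) -> int:
        return sum(1 for v in self.votes if v is Label.SENESCENT)

    @property
    def n_learners(self) -> int:
        return len(self.votes)


def extract_features(backbone: BackboneHandle, ds: DatasetBundle,
                     batch_size: int = 32) -> FeatureMatrix:
    """Deterministic off-the-shelf features for every image of a bundle."""
    x, y = ds.to_arrays()
    feats = [backbone.feature_vector_fn(x[i:i + batch_size].astype(np.float32))
             for i in range(0, len(x), batch_size)]
    return FeatureMatrix(np.concatenate(feats), y)


def reduce_pca(fm: FeatureMatrix, variance_target: float = DEFAULT_VARIANCE_TARGET
               ) -> tuple[FeatureMatrix, PCA]:
    """Project features onto the leading principal components.

    Components are kept up to ``variance_target`` cumulative explained
    variance (1.0 keeps all min(n-1, d) informative components). The fitted
    PCA is returned so held-out rows are *transformed* with it, never
    refitted — the leakage guard of this pipeline.
    """
    if len(fm.features) < 2:
        raise ValueError("PCA needs at least two rows")
    n, d = fm.features.shape
    if variance_target >= 1.0:
        pca = PCA(n_components=min(n - 1, d), svd_solver="full")
    else:
        pca = PCA(n_components=variance_target, svd_solver="full")
    reduced = pca.fit_transform(fm.features)
    return FeatureMatrix(reduced, fm.labels), pca


def apply_pca(pca: PCA, fm: FeatureMatrix) -> FeatureMatrix:
    return FeatureMatrix(pca.transform(fm.features), fm.labels)


def fit_svm_cv(fm: FeatureMatrix, grid: dict[str, list] | None = None, cv: int = 5,
               seed: int = 0) -> GridSearchCV:
    """Polynomial-kernel SVM with cross-validated hyperparameter search.

    Grid: degree in {2, 3}, C in {0.1, 1, 10}; stratified k-fold CV scored
    by accuracy, on training rows only. Raises on single-class labels.
    """
    y = np.asarray(fm.labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM training requires both classes present")
    cv = min(cv, int(np.bincount(y).min()))
    splitter = StratifiedKFold(n_splits=max(2, cv), shuffle=True, random_state=seed)
    search = GridSearchCV(SVC(kernel="poly", gamma="scale"), grid or DEFAULT_SVM_GRID,
                          cv=splitter, scoring="accuracy")
    search.fit(fm.features, y)
    return search


def hard_vote(record: VoteRecord) -> Label:
    """Majority label; an exact tie (even ensembles only) goes to SENESCENT.

    With the canonical seven learners the count is odd and ties cannot
    occur.
    """
    if record.n_learners < 1:
        raise ValueError("need at least one vote")
    k = record.vote_count_senescent
    return Label.SENESCENT if k >= record.n_learners - k else Label.CONTROL


def roc_by_vote_count(records: Sequence[VoteRecord], truth: Sequence) -> ROCCurve:
    """ROC traced by thresholding the senescent vote count.

    For every t in {0, ..., n+1}: call senescent iff at least t learners
    voted senescent. t = 0 marks everything positive (FPR, TPR) = (1, 1);
    t = n+1 nothing (0, 0). AUC by the trapezoidal rule.
    """
    if not records:
        raise ValueError("no vote records")
    n = records[0].n_learners
    counts = np.array([r.vote_count_senescent for r in records])
    t_bin = np.array([1 if (v is Label.SENESCENT if isinstance(v, Label) else int(v)) else 0
                      for v in truth])
    n_pos, n_neg = int(t_bin.sum()), int((1 - t_bin).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined with a single-class truth")
    thresholds = np.arange(0, n + 2)
    tpr = np.array([np.sum((counts >= t) & (t_bin == 1)) / n_pos for t in thresholds])
    fpr = np.array([np.sum((counts >= t) & (t_bin == 0)) / n_neg for t in thresholds])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return ROCCurve(fpr[order], tpr[order], thresholds[order].astype(float), auc)


# ---------------------------------------------------------------------------
# end-to-end hybrid model


@dataclass
class HybridVotingModel:
    """Per-backbone (PCA, SVM) pairs combined by hard voting."""

    backbones: list[BackboneHandle]
    pcas: list[PCA] = field(default_factory=list)
    svms: list[GridSearchCV] = field(default_factory=list)

    @property
    def n_learners(self) -> int:
        return len(self.backbones)


def fit_hybrid(backbones: Sequence[BackboneHandle], train: DatasetBundle,
               variance_target: float = DEFAULT_VARIANCE_TARGET,
               grid: dict[str, list] | None = None, seed: int = 0) -> HybridVotingModel:
    """Fit the PCA + polynomial SVM stack for every backbone on training rows."""
    model = HybridVotingModel(list(backbones))
    for i, bb in enumerate(model.backbones):
        fm = extract_features(bb, train)
        reduced, pca = reduce_pca(fm, variance_target)
        svm = fit_svm_cv(reduced, grid=grid, seed=mix_seed(seed, i))
        model.pcas.append(pca)
        model.svms.append(svm)
    return model


def predict_hybrid(model: HybridVotingModel, ds: DatasetBundle) -> tuple[list[Label], list[VoteRecord]]:
    """Hard-voted labels and the underlying per-backbone vote records."""
    if not model.svms:
        raise RuntimeError("hybrid model is not fitted")
    per_learner = []
    for bb, pca, svm in zip(model.backbones, model.pcas, model.svms):
        fm = apply_pca(pca, extract_features(bb, ds))
        pred = svm.predict(fm.features)
        per_learner.append([Label.SENESCENT if v else Label.CONTROL for v in pred])
    records = [VoteRecord([per_learner[i][j] for i in range(model.n_learners)])
               for j in range(len(ds))]
    return [hard_vote(r) for r in records], records
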