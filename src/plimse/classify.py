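"""Group classification: PCA dimensionality reduction, linear SVM, 5-fold CV.

The decision pipeline mirrors common EEG feature classification: principal
components are kept in order of explained variance until at least 90% of the
variance is covered, a linear support vector machine is trained on the scores,
and performance is summarised by pooled held-out accuracy and the area under
the ROC curve of the pooled held-out decision scores.

Two PCA scopes are provided.  ``per_fold`` (default) fits the standardiser and
PCA inside each training fold, so no information leaks from the held-out
subjects.  ``global`` fits a single centering-only PCA on the full feature
matrix before the cross-validation split — the classical pre-processing order
in much of the applied literature — and is kept for comparability; its mild
optimism is documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class ClassifierConfig:
    variance_threshold: float = 0.90
    n_folds: int = 5
    svm_c: float = 1.0
    pca_scope: str = "per_fold"  # or "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.pca_scope not in ("per_fold", "global"):
            raise ValueError("pca_scope must be 'per_fold' or 'global'")


@dataclass
class ClassifierReport:
    """Cross-validated classification summary for one feature set."""

    feature_set: str
    accuracy_pct: float
    auc: float
    n_components: int
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    fold_assignments: np.ndarray
    scores: np.ndarray
    config: ClassifierConfig = field(repr=False, default=None)  # type: ignore

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "accuracy_pct": self.accuracy_pct,
            "auc": self.auc,
            "n_components": self.n_components,
            "n_folds": int(self.fold_assignments.max()) + 1,
            "pca_scope": self.config.pca_scope if self.config else None,
            "seed": self.config.seed if self.config else None,
        }


def pca_components(x: np.ndarray, threshold: float = 0.90
                   ) -> tuple[np.ndarray, int, np.ndarray]:
    """Mean-centered principal-component scores keeping >= ``threshold`` variance.

    Returns (scores, n_components, explained_variance_ratio); components are
    ordered by decreasing variance and the smallest count whose cumulative
    explained-variance ratio reaches the threshold is retained.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two subjects")
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("zero total variance: PCA undefined")
    pca = PCA(n_components=None)
    scores = pca.fit_transform(x)
    ratios = pca.explained_variance_ratio_
    n = int(np.searchsorted(np.cumsum(ratios), threshold - 1e-12) + 1)
    n = min(n, scores.shape[1])
    return scores[:, :n], n, ratios


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and its trapezoidal area.

    ``labels`` are binary (positive class = 1).  Tied scores enter the curve
    simultaneously, which is equivalent to counting tied positive/negative
    pairs one half each.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels).tolist()) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def _fit_predict_fold(x_train, y_train, x_test, config: ClassifierConfig
                      ) -> tuple[np.ndarray, int]:
    if config.pca_scope == "per_fold":
        scaler = StandardScaler().fit(x_train)
        x_train = scaler.transform(x_train)
        x_test = scaler.transform(x_test)
    pca = PCA(n_components=None).fit(x_train)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n = int(np.searchsorted(cum, config.variance_threshold - 1e-12) + 1)
    n = min(n, pca.n_components_)
    svm = SVC(kernel="linear", C=config.svm_c)
    svm.fit(pca.transform(x_train)[:, :n], y_train)
    return svm.decision_function(pca.transform(x_test)[:, :n]), n


def svm_cv(x: np.ndarray, y: np.ndarray, config: ClassifierConfig | None = None,
           feature_set: str = "features") -> ClassifierReport:
    """Stratified k-fold linear-SVM classification of a subject x feature table.

    ``y`` holds binary labels (1 = positive class).  Pooled held-out decision
    scores give the accuracy (sign of the decision score) and the ROC/AUC.
    """
    config = config or ClassifierConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    if x.shape[0] != y.shape[0]:
        raise ValueError("one label per subject row required")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    if np.bincount(y).min() < config.n_folds:
        raise ValueError(
            f"smallest class has fewer than {config.n_folds} members; "
            "stratified folds would miss a class")

    if config.pca_scope == "global":
        scores_all, n_comp, _ = pca_components(x, config.variance_threshold)
        feature_matrix = scores_all
    else:
        feature_matrix = x
        n_comp = 0  # reported as the maximum over folds below

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    decision = np.zeros(x.shape[0])
    folds = np.zeros(x.shape[0], dtype=int)
    fold_components = []
    for k, (train, test) in enumerate(skf.split(feature_matrix, y)):
        if config.pca_scope == "global":
            svm = SVC(kernel="linear", C=config.svm_c)
            svm.fit(feature_matrix[train], y[train])
            decision[test] = svm.decision_function(feature_matrix[test])
        else:
            decision[test], n_fold = _fit_predict_fold(
                feature_matrix[train], y[train], feature_matrix[test], config)
            fold_components.append(n_fold)
        folds[test] = k
    if config.pca_scope == "per_fold":
        n_comp = int(max(fold_components))

    predicted = (decision > 0).astype(int)
    accuracy = 100.0 * float(np.mean(predicted == y))
    fpr, tpr, auc = roc_auc(decision, y)
    return ClassifierReport(
        feature_set=feature_set,
        accuracy_pct=accuracy,
        auc=auc,
        n_components=n_comp,
        roc_fpr=fpr,
        roc_tpr=tpr,
        fold_assignments=folds,
        scores=decision,
        config=config,
    )
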