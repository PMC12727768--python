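"""Cross-validated classification of feature matrices.

The benchmark harness: stratified 10-fold cross-validation of a feature
matrix with one of four classifiers (SVM with a Gaussian kernel and box
constraint 1; KNN with the neighbour count chosen by inner CV; a decision
tree tuned over a small depth/split grid; a 146-tree random forest), plus
accuracy/coefficient-of-variation reporting and the varied-mode-count sweep.

Features are z-scored with statistics fit on the training folds only.
Classifier backends are scikit-learn estimators; this module owns the fold
bookkeeping, aggregation and the experiment designs around them.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_extraction import FeatureMatrix, extract_vmd_svd
from .signal_io import EmgRecording
from .vmd_core import VmdConfig

logger = logging.getLogger("emgvmd")

__all__ = [
    "ClassifierSpec",
    "CvResult",
    "kfold_split",
    "accuracy",
    "cross_validate",
    "coefficient_of_variation",
    "vmf_sweep",
    "KNN_GRID",
]

KNN_GRID = (1, 3, 5, 7, 9, 11)
DT_DEPTH_GRID = (3, 5, 10, None)
DT_SPLIT_GRID = (2, 5, 10)


@dataclass
class ClassifierSpec:
    """Which classifier to run and how.

    kind    'SVM' | 'KNN' | 'DT' | 'RF'.
    params  overrides: RF 'n_trees' (default 146); SVM 'C' (default 1.0)
            and 'gamma'; KNN 'K' (an int, or 'search' for the inner-CV
            grid); DT 'max_depth'/'min_samples_split' grids.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("SVM", "KNN", "DT", "RF"):
            raise ValueError("kind must be one of SVM, KNN, DT, RF")


@dataclass
class CvResult:
    """Per-fold accuracies, their mean/std, pooled confusion counts and the
    seed that produced the fold assignment."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    confusion: np.ndarray
    classes: np.ndarray
    seed: int


def _build_estimator(
    spec: ClassifierSpec, seed: int, inner_cv: int = 3, n_train: int | None = None
):
    p = spec.params
    if spec.kind == "SVM":
        clf = SVC(kernel="rbf", C=p.get("C", 1.0), gamma=p.get("gamma", "scale"))
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if spec.kind == "RF":
        clf = RandomForestClassifier(
            n_estimators=p.get("n_trees", 146), random_state=seed
        )
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if spec.kind == "KNN":
        k = p.get("K", "search")
        if k == "search":
            grid = list(p.get("grid", KNN_GRID))
            if n_train is not None:
                # neighbour counts must fit inside the inner-CV training folds
                cap = max(1, n_train * (inner_cv - 1) // inner_cv)
                grid = [g for g in grid if g <= cap] or [1]
            pipe = Pipeline(
                [("scale", StandardScaler()), ("clf", KNeighborsClassifier())]
            )
            return GridSearchCV(pipe, {"clf__n_neighbors": grid}, cv=inner_cv)
        return Pipeline(
            [("scale", StandardScaler()), ("clf", KNeighborsClassifier(n_neighbors=k))]
        )
    # DT: small deterministic grid in place of black-box tuning
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", DecisionTreeClassifier(random_state=seed)),
        ]
    )
    return GridSearchCV(
        pipe,
        {
            "clf__max_depth": list(p.get("max_depth", DT_DEPTH_GRID)),
            "clf__min_samples_split": list(p.get("min_samples_split", DT_SPLIT_GRID)),
        },
        cv=inner_cv,
    )


def kfold_split(
    n: int,
    k: int = 10,
    labels: np.ndarray | None = None,
    seed: int = 0,
    stratified: bool = True,
) -> list[np.ndarray]:
    """Disjoint, exhaustive test-index folds.

    Stratified by label when possible; a class with fewer than ``k``
    members triggers a fall-back to unstratified folds (logged).
    """
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    use_strat = stratified and labels is not None
    if use_strat:
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            logger.warning(
                "class with %d < %d members; falling back to unstratified folds",
                counts.min(),
                k,
            )
            use_strat = False
    if use_strat:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), labels)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


def accuracy(confusion: np.ndarray) -> float:
    """Correct predictions over total tested samples."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def cross_validate(
    features: FeatureMatrix,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CvResult:
    """k-fold cross-validation; metrics averaged across folds, confusion
    counts pooled."""
    if features.row_labels is None:
        raise ValueError("feature matrix has no row labels")
    X = features.values
    y = features.row_labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if features.n_rows < k:
        raise ValueError("fewer rows than folds")

    folds = kfold_split(features.n_rows, k, y, seed, stratified)
    min_train = features.n_rows - max(len(f) for f in folds)
    est = _build_estimator(spec, seed, n_train=min_train)
    fold_acc = np.empty(len(folds))
    conf = np.zeros((classes.size, classes.size), dtype=int)
    all_idx = np.arange(features.n_rows)
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=False)
        model = clone(est)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        fold_conf = confusion_matrix(y[test_idx], pred, labels=classes)
        conf += fold_conf
        fold_acc[i] = accuracy(fold_conf)
    return CvResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(fold_acc.mean()),
        std_accuracy=float(fold_acc.std(ddof=1)) if len(folds) > 1 else 0.0,
        confusion=conf,
        classes=classes,
        seed=seed,
    )


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample standard deviation over mean, in percent (dispersion of
    per-subject accuracies)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean is zero")
    return float(v.std(ddof=1) / mean * 100.0)


def vmf_sweep(
    rec: EmgRecording,
    K_values: tuple[int, ...] = (2, 4, 6, 8, 10, 12),
    spec: ClassifierSpec | None = None,
    window_ms: float = 250.0,
    overlap_frac: float = 0.10,
    seed: int = 0,
    k_folds: int = 10,
    vmd_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Re-extract VMD-SVD features from the raw signal for each mode count
    K and cross-validate each feature set.

    Returns a table with columns K, M (= channels x K), N (rows),
    mean/std accuracy and the feature-extraction wall time in seconds
    (reported, never asserted).
    """
    spec = spec or ClassifierSpec("RF")
    vmd_kwargs = vmd_kwargs or {}
    rows = []
    for K in K_values:
        cfg = VmdConfig(K=K, **vmd_kwargs)
        t0 = time.perf_counter()
        fm = extract_vmd_svd(
            rec, K=K, window_ms=window_ms, overlap_frac=overlap_frac, vmd_config=cfg
        )
        dt = time.perf_counter() - t0
        cv = cross_validate(fm, spec, k=k_folds, seed=seed)
        rows.append(
            {
                "K": K,
                "M": fm.n_cols,
                "N": fm.n_rows,
                "mean_accuracy": cv.mean_accuracy,
                "std_accuracy": cv.std_accuracy,
                "extract_time_s": dt,
            }
        )
    return pd.DataFrame(rows)
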