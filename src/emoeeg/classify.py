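"""Cross-validated group classification of entropy features.

The protocol being reproduced feeds one condition cell's feature matrix
(subjects × 15 entropy values) into PCA retaining 95% of variance and a
quadratic-kernel SVM, scored by 27-fold cross-validation.  With the
27-subject control-vs-patient comparisons this is exactly leave-one-out;
with the 34-subject moderate-vs-marked comparison folds hold one or two
subjects.  All preprocessing (z-scoring, PCA) is fit on training folds
only — fitting it on the full matrix leaks test information and inflates
accuracy on pure noise, which the test suite demonstrates explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import METHODS, FeatureTable
from .preprocess import EMOTIONS

__all__ = [
    "ClassifierConfig",
    "ClassificationResult",
    "PCAReducer",
    "pca_reduce",
    "svm_cv",
    "grid_classification",
    "results_frame",
]


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """PCA + SVM cross-validation settings.

    ``variance_fraction`` — retain the smallest number of principal
    components whose cumulative explained variance reaches this fraction.
    ``kernel`` — ``"quadratic"`` is the inhomogeneous polynomial kernel
    of degree 2 with unit coefficient, (x·y + 1)²; ``"linear"`` and
    ``"rbf"`` are available for comparison.  ``folds`` may be an integer
    or ``"loo"`` (leave-one-out).  ``C`` is the SVM box constraint.
    """

    variance_fraction: float = 0.95
    kernel: str = "quadratic"
    folds: int | str = 27
    seed: int = 0
    C: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.variance_fraction <= 1:
            raise ClassifyError(
                f"variance_fraction must lie in (0, 1], got {self.variance_fraction}"
            )
        if self.folds != "loo" and (not isinstance(self.folds, int) or self.folds < 2):
            raise ClassifyError(f"folds must be an integer >= 2 or 'loo', got {self.folds!r}")

    def make_svm(self) -> SVC:
        if self.kernel == "quadratic":
            # degree-2 polynomial kernel (γ x·y + 1)² with the usual
            # automatic kernel scale γ = 1/(n_features · Var(X))
            return SVC(kernel="poly", degree=2, gamma="scale", coef0=1.0, C=self.C)
        return SVC(kernel=self.kernel, C=self.C)


@dataclass
class ClassificationResult:
    """Cross-validated accuracy of one condition cell."""

    condition: tuple  # (electrode, method, emotion) or any descriptive key
    accuracy: float   # percent, 100 * correct / total
    n_subjects: int
    fold_assignments: list[dict] = field(repr=False)  # test indices, y, y_pred, n_components

    @property
    def n_correct(self) -> int:
        return round(self.accuracy * self.n_subjects / 100.0)


class PCAReducer:
    """Mean-centering PCA keeping the smallest component count whose
    cumulative explained variance reaches ``variance_fraction``.

    Reusable on held-out rows via :meth:`transform`.
    """

    def __init__(self, variance_fraction: float = 0.95):
        if not 0 < variance_fraction <= 1:
            raise ClassifyError(f"variance_fraction must lie in (0, 1], got {variance_fraction}")
        self.variance_fraction = variance_fraction
        self._pca: PCA | None = None
        self.n_components_: int | None = None

    def fit(self, X: np.ndarray) -> "PCAReducer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ClassifyError(f"PCA needs a 2-D matrix with >= 2 rows, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ClassifyError("PCA input contains non-finite entries")
        if not X.var(axis=0).sum() > 0:
            raise ClassifyError("degenerate input: all rows identical (zero variance)")
        pca = PCA(svd_solver="full")
        pca.fit(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        # smallest k with cumulative variance >= fraction (tolerating float
        # round-off when the fraction is exactly 1)
        k = int(np.searchsorted(cum, self.variance_fraction - 1e-12) + 1)
        self.n_components_ = min(k, len(cum))
        self._pca = pca
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise ClassifyError("PCAReducer is not fitted")
        return self._pca.transform(np.asarray(X, dtype=np.float64))[:, : self.n_components_]

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def pca_reduce(X: np.ndarray, variance_fraction: float = 0.95) -> tuple[np.ndarray, PCAReducer]:
    """Reduce ``X`` to the principal components explaining
    ``variance_fraction`` of its variance; returns (reduced, transform)."""
    reducer = PCAReducer(variance_fraction)
    return reducer.fit_transform(X), reducer


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition indices into ``n_folds`` near-equal, class-balanced folds.

    Within each class the indices are shuffled, the classes are then
    interleaved by fractional position (so any contiguous chunk is close
    to the overall class ratio) and the merged order is split evenly.
    Unlike stratified splitters that require folds <= class size, this
    supports fold counts up to the subject count (folds of 1–2 subjects),
    reducing exactly to leave-one-out when folds == n.
    """
    y = np.asarray(y)
    keyed: list[tuple[float, int]] = []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        keyed += [((pos + 0.5) / len(idx), i) for pos, i in enumerate(idx)]
    merged = np.array([i for _, i in sorted(keyed, key=lambda t: (t[0], t[1]))])
    return [fold for fold in np.array_split(merged, n_folds) if len(fold)]


def svm_cv(
    X: np.ndarray,
    y: Sequence,
    config: ClassifierConfig | None = None,
    condition: tuple = (),
) -> ClassificationResult:
    """Cross-validated PCA + SVM accuracy over all subjects.

    Folds are a seeded stratified partition; within each fold the
    z-scoring, the PCA transform and the SVM are fit on the training rows
    only and applied to the held-out rows.  Accuracy is the percentage of
    all subjects whose held-out prediction matches their label.
    """
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ClassifyError(f"X has {X.shape[0]} rows but y has {y.shape[0]} labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ClassifyError("classification needs both classes present")
    n = X.shape[0]
    n_folds = n if config.folds == "loo" else int(config.folds)
    if n_folds > n:
        raise ClassifyError(f"folds={n_folds} exceeds the {n} available subjects")

    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(y, n_folds, rng)
    correct = 0
    assignments = []
    for test_idx in folds:
        train_mask = np.ones(n, bool)
        train_mask[test_idx] = False
        X_train, y_train = X[train_mask], y[train_mask]
        X_test = X[test_idx]
        if np.unique(y_train).size < 2:
            # tiny degenerate folds: predict the training majority class
            y_pred = np.full(len(test_idx), y_train[0])
            n_comp = 0
        else:
            if config.standardize:
                scaler = StandardScaler().fit(X_train)
                # guard all-constant columns
                scaler.scale_[scaler.scale_ == 0] = 1.0
                X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
            try:
                reducer = PCAReducer(config.variance_fraction).fit(X_train)
                Z_train, Z_test = reducer.transform(X_train), reducer.transform(X_test)
                n_comp = reducer.n_components_
            except ClassifyError:
                # degenerate training matrix (e.g. duplicated subjects):
                # fall back to the raw features
                Z_train, Z_test, n_comp = X_train, X_test, X_train.shape[1]
            svm = config.make_svm().fit(Z_train, y_train)
            y_pred = svm.predict(Z_test)
        correct += int((y_pred == y[test_idx]).sum())
        assignments.append(
            {
                "test_indices": test_idx.tolist(),
                "y_true": y[test_idx].tolist(),
                "y_pred": np.asarray(y_pred).tolist(),
                "n_components": n_comp,
            }
        )
    return ClassificationResult(condition, 100.0 * correct / n, n, assignments)


def grid_classification(
    table: FeatureTable,
    labels: dict[str, object] | pd.Series,
    config: ClassifierConfig | None = None,
    electrodes: Iterable[str] = ("Fz", "Cz", "Pz"),
    methods: Iterable[str] = METHODS,
    emotions: Iterable[str] = EMOTIONS,
    pool_sections: bool = False,
) -> list[ClassificationResult]:
    """One cross-validated result per electrode × method × emotion cell.

    ``labels`` maps subject_id → class label.  With the defaults this is
    the 27-cell identification-rate grid; per-(electrode, method) emotion
    averages are available from :func:`results_frame`.
    """
    config = config or ClassifierConfig()
    labels = pd.Series(labels)
    missing = [s for s in table.subjects if s not in labels.index]
    if missing:
        raise ClassifyError(f"labels missing for subjects: {missing}")
    y = labels.loc[table.subjects].to_numpy()
    results = []
    for electrode in electrodes:
        for method in methods:
            for emotion in emotions:
                X = table.select_cell(electrode, method, emotion, pool_sections=pool_sections)
                results.append(
                    svm_cv(X.to_numpy(), y, config, condition=(electrode, method, emotion))
                )
    return results


def results_frame(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    """Identification-rate table: (electrode, method) rows, one accuracy
    column per emotion plus their arithmetic mean ``Avg``."""
    res_list = list(results)
    rows: dict[tuple, dict] = {}
    for res in res_list:
        electrode, method, emotion = res.condition
        rows.setdefault((electrode, method), {})[emotion] = res.accuracy
    order = list(dict.fromkeys(res.condition[2] for res in res_list))
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame = frame.reindex(columns=order)
    frame.index.names = ["electrode", "method"]
    frame["Avg"] = frame.mean(axis=1)
    return frame
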