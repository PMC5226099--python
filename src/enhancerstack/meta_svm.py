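"""The stacking stage: meta-features and the RBF-SVM main classifier.

Every base forest scores every pooled held-out window, and the meta-feature
of window i for base j is

    meta[i, j] = confidence_score_j(i) * heldout_fscore_j

so a weak base classifier (low held-out F-score) contributes a
proportionally damped feature.  The main classifier is a soft-margin SVM
with the RBF kernel k(x, x') = exp(-gamma * ||x - x'||^2); C and gamma are
chosen by exhaustive grid search minimizing the mean balanced error rate
(BER) over seeded stratified 10-fold cross-validation, ties resolved toward
the smallest C then smallest gamma.

The printed search grids are C in {2, 4, ..., 50} and gamma in
{2, 4, ..., 200}; C = 0 (no misclassification penalty) and gamma = 0
(constant kernel) are degenerate and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from enhancerstack.base_forest import BaseModel, confidence_scores
from enhancerstack.features import FeatureMatrix


@dataclass
class MetaDataset:
    """n_windows x n_base matrix of confidence x F-score meta-features."""

    meta_features: np.ndarray
    base_names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.meta_features = np.asarray(self.meta_features, dtype=float)
        if self.meta_features.ndim != 2 or self.meta_features.shape[1] != len(self.base_names):
            raise ValueError(
                f"meta_features shape {self.meta_features.shape} does not match "
                f"{len(self.base_names)} base models"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.meta_features.shape[0],):
                raise ValueError("labels length does not match meta_features rows")


@dataclass
class SvmConfig:
    """Grid-search settings for the RBF-SVM main classifier."""

    C_grid: tuple[float, ...] = tuple(range(2, 51, 2))
    gamma_grid: tuple[float, ...] = tuple(range(2, 201, 2))
    n_folds: int = 10
    seed: int = 0
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("all C and gamma values must be positive")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass
class MetaModel:
    """Fitted main classifier with its selected hyperparameters."""

    svm: SVC
    chosen_C: float
    chosen_gamma: float
    cv_balanced_error: float
    base_names: list[str]
    cv_surface: np.ndarray = field(repr=False, default_factory=lambda: np.empty((0, 0)))

    def dump_cv_surface(self, config: SvmConfig, path: str | Path) -> None:
        """Write the full C x gamma mean-BER surface as TSV."""
        with open(path, "w") as fh:
            fh.write("C\\gamma\t" + "\t".join(f"{g:g}" for g in config.gamma_grid) + "\n")
            for c, row in zip(config.C_grid, self.cv_surface):
                fh.write(f"{c:g}\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def build_meta_features(
    base_models: Sequence[BaseModel],
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
) -> MetaDataset:
    """Score windows with ALL base models and weight by held-out F-scores.

    Column j is confidence_score_j * heldout_fscore_j, so entries lie in
    [0, heldout_fscore_j] ⊆ [0, 1].
    """
    if len(base_models) < 2:
        raise ValueError("stacking needs at least 2 base models")
    cols = [confidence_scores(m, features) * m.heldout_fscore for m in base_models]
    return MetaDataset(np.column_stack(cols), [m.tissue for m in base_models], labels)


def rbf_kernel(x, x_prime, gamma: float) -> float:
    """Gaussian radial basis kernel exp(-gamma * ||x - x'||^2)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(x_prime, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return float(np.exp(-gamma * np.sum((a - b) ** 2)))


def balanced_error_rate(labels, predictions) -> float:
    """BER = 1 - (sensitivity + specificity) / 2; needs both classes in labels."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("balanced error rate requires both classes in labels")
    sens = ((y == 1) & (p == 1)).sum() / n_pos
    spec = ((y == 0) & (p == 0)).sum() / n_neg
    return float(1.0 - (sens + spec) / 2.0)


def grid_search_svm(meta: MetaDataset, config: SvmConfig) -> MetaModel:
    """Exhaustive (C, gamma) grid search under stratified k-fold CV.

    For every pair the mean BER over the (seeded, shared) folds is
    computed; the minimizing pair — ties to smallest C then smallest gamma —
    is refit on all data.  The full BER surface is kept on the model.
    """
    if meta.labels is None:
        raise ValueError("meta dataset has no labels; cannot train")
    y = meta.labels
    X = meta.meta_features
    if len(np.unique(y)) < 2:
        raise ValueError("meta labels contain a single class")
    if len(y) < config.n_folds:
        raise ValueError(f"{len(y)} samples is fewer than {config.n_folds} folds")
    if min(np.bincount(y)) < config.n_folds:
        raise ValueError(
            f"minority class has {min(np.bincount(y))} samples, fewer than "
            f"{config.n_folds} folds; stratified CV impossible"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed % 2**31)
    folds = list(skf.split(X, y))

    surface = np.empty((len(config.C_grid), len(config.gamma_grid)))
    best: tuple[float, float, float] | None = None  # (ber, C, gamma)
    for i, C in enumerate(config.C_grid):
        for j, gamma in enumerate(config.gamma_grid):
            bers = []
            for train_idx, val_idx in folds:
                clf = SVC(C=C, gamma=gamma, kernel="rbf", tol=config.tol)
                clf.fit(X[train_idx], y[train_idx])
                bers.append(balanced_error_rate(y[val_idx], clf.predict(X[val_idx])))
            mean_ber = float(np.mean(bers))
            surface[i, j] = mean_ber
            if best is None or mean_ber < best[0]:
                best = (mean_ber, C, gamma)
    assert best is not None
    ber, C, gamma = best
    final = SVC(C=C, gamma=gamma, kernel="rbf", tol=config.tol)
    final.fit(X, y)
    return MetaModel(
        svm=final,
        chosen_C=C,
        chosen_gamma=gamma,
        cv_balanced_error=ber,
        base_names=list(meta.base_names),
        cv_surface=surface,
    )


def predict_meta(model: MetaModel, meta: MetaDataset | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores and 0/1 labels (label 1 iff score > 0)."""
    if isinstance(meta, MetaDataset):
        if meta.base_names != model.base_names:
            raise ValueError(
                f"meta-feature columns {meta.base_names} do not match "
                f"trained base models {model.base_names}"
            )
        X = meta.meta_features
    else:
        X = np.asarray(meta, dtype=float)
        if X.shape[1] != len(model.base_names):
            raise ValueError(f"expected {len(model.base_names)} columns, got {X.shape[1]}")
    scores = model.svm.decision_function(X)
    return scores, (scores > 0).astype(int)
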