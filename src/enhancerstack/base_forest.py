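"""Per-tissue random-forest base classifiers.

Each tissue gets its own forest trained on a stratified 60% of its balanced
dataset and scored on the held-out 40%.  The forest's soft output is the
*confidence score*: the fraction of trees voting "enhancer" for a window

    confidence = tree_number(positive) / tree_number(total)

which (scaled by the model's held-out F-score) later becomes the tissue's
meta-feature.  ``entropy`` and ``info_gain`` — the split criterion the
trees optimize — are exposed as standalone, independently tested
operations.

Forest fitting itself is delegated to scikit-learn's
``RandomForestClassifier`` with the entropy criterion and Breiman defaults;
``confidence_scores`` iterates the fitted trees so the score is the exact
vote fraction, not the averaged per-tree probability.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from enhancerstack.evaluation import ConfusionCounts, MetricsReport, confusion, metrics
from enhancerstack.features import FeatureMatrix, LabeledDataset

logger = logging.getLogger(__name__)


def entropy(dist: Sequence[float]) -> float:
    """Shannon entropy of a class distribution in bits: -sum p_i log2 p_i.

    Terms with p_i = 0 contribute 0.
    """
    p = np.asarray(dist, dtype=float)
    if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("class proportions must be non-negative and sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _label_entropy(labels: np.ndarray) -> float:
    counts = np.bincount(labels)
    return entropy(counts[counts > 0] / len(labels))


def info_gain(parent_labels: Sequence[int], partition: Sequence[Sequence[int]]) -> float:
    """Information gain of a candidate split in bits.

    gain = entropy(parent) - sum_children (|child|/|parent|) * entropy(child).
    The children must partition the parent's labels as a multiset.
    """
    parent = np.asarray(parent_labels, dtype=int)
    children = [np.asarray(c, dtype=int) for c in partition]
    if Counter(parent.tolist()) != Counter(x for c in children for x in c.tolist()):
        raise ValueError("children do not partition the parent labels")
    gain = _label_entropy(parent) - sum(
        len(c) / len(parent) * _label_entropy(c) for c in children if len(c)
    )
    return max(0.0, float(gain))  # clamp -0.0 / rounding

@dataclass
class ForestConfig:
    """Random-forest settings (Breiman defaults).

    n_trees: number of bootstrap resamples / trees.
    features_per_split: candidate features per node ("sqrt" = ceil(sqrt(p))).
    """

    n_trees: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    features_per_split: int | str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")


@dataclass
class BaseModel:
    """One tissue's trained forest plus its held-out evaluation."""

    tissue: str
    forest: RandomForestClassifier
    feature_names: list[str]
    heldout_fscore: float
    heldout_report: MetricsReport
    heldout_confusion: ConfusionCounts
    # held-out portion retained so the meta-classifier can pool it
    heldout_features: np.ndarray = field(repr=False, default_factory=lambda: np.empty((0, 0)))
    heldout_labels: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0, dtype=int))


def train_base(
    dataset: LabeledDataset, config: ForestConfig, train_fraction: float = 0.6
) -> BaseModel:
    """Train a tissue's base forest on a stratified 60/40 split.

    The forest is fit on the training portion; the held-out F-score is
    computed from confidence scores thresholded at 0.5 (a window is called
    enhancer when at least half the trees vote for it).  If the held-out
    F-score is undefined (no predicted or no true positives) the stored
    ``heldout_fscore`` is 0.0, since the stacking stage needs a number.
    """
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError(f"dataset {dataset.source_name!r} has a single class; cannot train")
    X = dataset.features.values
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=train_fraction,
        stratify=y,
        random_state=config.seed % 2**31,
    )
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="entropy",
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        max_features=config.features_per_split,
        random_state=config.seed % 2**31,
    )
    forest.fit(X_tr, y_tr)
    model = BaseModel(
        tissue=dataset.source_name,
        forest=forest,
        feature_names=list(dataset.features.mark_names),
        heldout_fscore=0.0,
        heldout_report=MetricsReport(),
        heldout_confusion=ConfusionCounts(0, 0, 0, 0),
        heldout_features=X_te,
        heldout_labels=y_te,
    )
    conf = confidence_scores(model, X_te)
    model.heldout_confusion = confusion(y_te, (conf >= 0.5).astype(int))
    model.heldout_report = metrics(model.heldout_confusion)
    if model.heldout_report.f_score is None:
        logger.warning(
            "tissue %s: held-out F-score undefined (no predicted or true positives); using 0.0",
            dataset.source_name,
        )
        model.heldout_fscore = 0.0
    else:
        model.heldout_fscore = model.heldout_report.f_score
    return model


def confidence_scores(model: BaseModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Fraction of trees voting class 1 for each window — values on a
    1/n_trees grid in [0, 1]."""
    if isinstance(features, FeatureMatrix):
        if features.mark_names != model.feature_names:
            missing = set(model.feature_names) - set(features.mark_names)
            extra = set(features.mark_names) - set(model.feature_names)
            raise ValueError(
                f"feature columns do not match training columns "
                f"(missing: {sorted(missing)}, extra: {sorted(extra)})"
            )
        X = features.values
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
            )
    votes = np.zeros(X.shape[0])
    for tree in model.forest.estimators_:
        votes += tree.predict(X) == 1
    return votes / len(model.forest.estimators_)
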