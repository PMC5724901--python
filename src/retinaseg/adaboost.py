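"""Binary AdaBoost with depth-bounded decision-tree weak learners.

The boosting loop is the classical discrete AdaBoost recursion: at round t a
tree h_t is fit to the current sample distribution D_t, its weighted error
eps_t = sum_i D_t(i) [h_t(x_i) != y_i] sets the vote weight
alpha_t = 1/2 ln((1 - eps_t)/eps_t), and the distribution is re-weighted as
D_{t+1}(i) = D_t(i)/Z_t * exp(-/+ alpha_t) with Z_t = 2 sqrt(eps_t (1 -
eps_t)), so D_{t+1} stays a distribution and the misclassified samples carry
exactly half of the total weight.  Training stops early when eps_t = 0
(perfect learner; its vote is capped) or eps_t >= 0.5 (no learner beats
chance).  The strong classifier is H(x) = sign(sum_t alpha_t h_t(x)); the
unthresholded margin is kept for ROC analysis.

Fitted sklearn trees are immediately converted to explicit node arrays:
prediction, serialization and reloading all go through the same portable
representation (no pickled estimators).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "DegenerateLearnerError",
    "TreeNodes",
    "EnsembleModel",
    "train_weak",
    "adaboost_train",
    "ensemble_score",
    "staged_scores",
    "validate_length",
]

_EPS_MIN = 1e-10  # floor on eps when a learner is perfect, caps alpha


class DegenerateLearnerError(ValueError):
    """Raised when the training data cannot support a two-class learner."""


@dataclass(frozen=True)
class TreeNodes:
    """A decision tree as flat node arrays (sklearn layout: leaf nodes have
    children == -1).  ``leaf_value`` holds the +/-1 vote at every node."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        node = np.zeros(X.shape[0], dtype=np.intp)
        while True:
            internal = self.left[node] >= 0
            if not internal.any():
                break
            idx = np.flatnonzero(internal)
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.left[cur], self.right[cur])
        return self.leaf_value[node].astype(float)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_value": self.leaf_value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNodes":
        return cls(
            feature=np.asarray(d["feature"], np.intp),
            threshold=np.asarray(d["threshold"], float),
            left=np.asarray(d["left"], np.intp),
            right=np.asarray(d["right"], np.intp),
            leaf_value=np.asarray(d["leaf_value"], int),
        )


def _sklearn_to_nodes(clf: DecisionTreeClassifier) -> TreeNodes:
    tree = clf.tree_
    counts = tree.value[:, 0, :] * tree.weighted_n_node_samples[:, None]
    votes = clf.classes_[np.argmax(counts, axis=1)]
    return TreeNodes(
        feature=tree.feature.copy(),
        threshold=tree.threshold.copy(),
        left=tree.children_left.copy(),
        right=tree.children_right.copy(),
        leaf_value=votes.astype(int),
    )


@dataclass
class EnsembleModel:
    """Ordered (weak learner, alpha_t) rounds plus the training log."""

    learners: list = field(default_factory=list)
    alphas: list = field(default_factory=list)
    errors: list = field(default_factory=list)
    zs: list = field(default_factory=list)
    max_depth: int = 3
    n_features: int = 0
    format_version: int = 1

    @property
    def n_rounds(self) -> int:
        return len(self.learners)

    def to_dict(self) -> dict:
        return {
            "format_version": self.format_version,
            "max_depth": self.max_depth,
            "n_features": self.n_features,
            "alphas": list(map(float, self.alphas)),
            "errors": list(map(float, self.errors)),
            "zs": list(map(float, self.zs)),
            "learners": [t.to_dict() for t in self.learners],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        model = cls(
            learners=[TreeNodes.from_dict(t) for t in d["learners"]],
            alphas=list(d["alphas"]),
            errors=list(d["errors"]),
            zs=list(d["zs"]),
            max_depth=int(d["max_depth"]),
            n_features=int(d["n_features"]),
            format_version=int(d["format_version"]),
        )
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def truncated(self, t: int) -> "EnsembleModel":
        """Prefix ensemble with the first ``t`` rounds."""
        return EnsembleModel(
            learners=self.learners[:t],
            alphas=self.alphas[:t],
            errors=self.errors[:t],
            zs=self.zs[:t],
            max_depth=self.max_depth,
            n_features=self.n_features,
        )


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("labels must be -1 or +1")
    return y.astype(int)


def train_weak(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    max_depth: int = 3,
    random_state: int = 0,
) -> TreeNodes:
    """Depth-bounded tree minimizing the weighted misclassification rate."""
    y = _check_labels(y)
    if len(np.unique(y)) < 2:
        raise DegenerateLearnerError("training data contains a single class")
    clf = DecisionTreeClassifier(max_depth=max_depth, random_state=random_state)
    clf.fit(np.asarray(X, float), y, sample_weight=np.asarray(weights, float))
    return _sklearn_to_nodes(clf)


def adaboost_train(
    X: np.ndarray,
    y: np.ndarray,
    n_rounds: int,
    max_depth: int = 3,
    seed: int = 0,
) -> EnsembleModel:
    """Run the boosting recursion for up to ``n_rounds`` rounds.

    The initial distribution is uniform.  Stops early on a perfect round
    (eps = 0, alpha capped at 1/2 ln((1-eps_min)/eps_min)) or when the best
    tree no longer beats chance (eps >= 0.5).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    X = np.asarray(X, float)
    y = _check_labels(y)
    m = len(y)
    D = np.full(m, 1.0 / m)
    model = EnsembleModel(max_depth=max_depth, n_features=X.shape[1])
    for t in range(n_rounds):
        tree = train_weak(X, y, D, max_depth=max_depth, random_state=seed)
        pred = tree.predict(X)
        miss = pred != y
        eps = float(D[miss].sum())
        if eps >= 0.5:
            break
        eps_eff = max(eps, _EPS_MIN)
        alpha = 0.5 * np.log((1.0 - eps_eff) / eps_eff)
        z = 2.0 * np.sqrt(eps_eff * (1.0 - eps_eff))
        model.learners.append(tree)
        model.alphas.append(alpha)
        model.errors.append(eps)
        model.zs.append(z)
        if eps == 0.0:
            break
        D = D / z * np.exp(np.where(miss, alpha, -alpha))
        D /= D.sum()  # guard drift; the exact update already normalizes
    return model


def ensemble_score(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Continuous margin sum_t alpha_t h_t(x); empty model scores 0.
    Predicted class is sign(margin) with ties going to +1."""
    X = np.atleast_2d(np.asarray(X, float))
    margin = np.zeros(X.shape[0])
    for alpha, tree in zip(model.alphas, model.learners):
        margin += alpha * tree.predict(X)
    return margin


def staged_scores(model: EnsembleModel, X: np.ndarray):
    """Yield the margin after each round (prefix ensembles 1..T)."""
    X = np.atleast_2d(np.asarray(X, float))
    margin = np.zeros(X.shape[0])
    for alpha, tree in zip(model.alphas, model.learners):
        margin = margin + alpha * tree.predict(X)
        yield margin


def validate_length(model: EnsembleModel, X_val: np.ndarray, y_val: np.ndarray) -> int:
    """Holdout-optimal ensemble length (first minimum of the error curve).

    Returns the 1-based round count whose prefix ensemble minimizes the
    holdout misclassification rate; the caller may truncate the model there.
    """
    y_val = _check_labels(y_val)
    if len(y_val) == 0:
        raise ValueError("holdout set is empty")
    errors = np.array(
        [
            float((np.where(margin >= 0, 1, -1) != y_val).mean())
            for margin in staged_scores(model, X_val)
        ]
    )
    if errors.size == 0:
        raise ValueError("model has no rounds")
    return int(np.argmin(errors)) + 1
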