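"""Rotation Forest ensemble classifier.

Each of the L base trees sees the training data through its own sparse
rotation: the d features are randomly partitioned into K disjoint subsets;
for every subset a random nonempty set of classes is chosen, a bootstrap
sample of those classes' rows is drawn, and PCA is fitted on the subset's
columns of that sample; all principal axes become one diagonal block of the
rotation matrix, whose rows are then rearranged back to the original
feature order.  Trees are trained on X R and their posteriors averaged.

The rotation construction is implemented here from first principles
(partition, class-conditional bootstrap, covariance eigendecomposition,
block assembly, rearrangement); the base learner is an unpruned
Gini-impurity decision tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "RotationForestConfig",
    "Rotation",
    "build_rotation",
    "RotationForest",
    "RotationForestModel",
]

_FORMAT_TAG = "dtirf-rotation-forest"
_FORMAT_VERSION = 1


@dataclass
class RotationForestConfig:
    """Ensemble hyperparameters.

    K
        Number of disjoint feature subsets per tree (must not exceed the
        feature count).
    L
        Number of trees.
    bootstrap_fraction
        Fraction of the selected classes' rows drawn (with replacement)
        before fitting each subset's PCA.
    seed
        Master seed; every tree derives an independent substream from it.
    class_subset
        "random" draws a uniformly random nonempty subset of classes per
        feature subset; "all" always uses every class (making the rotation
        construction invariant under label relabelling).
    voting
        "soft" averages tree posteriors; "majority" averages hard votes.
    threshold
        Decision threshold on the positive-class score; ties go positive.
    """

    K: int = 21
    L: int = 42
    bootstrap_fraction: float = 0.75
    seed: int = 0
    class_subset: str = "random"
    voting: str = "soft"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.class_subset not in ("random", "all"):
            raise ValueError("class_subset must be 'random' or 'all'")
        if self.voting not in ("soft", "majority"):
            raise ValueError("voting must be 'soft' or 'majority'")


class Rotation:
    """Sparse block-diagonal rotation with rows in original feature order.

    Stored structurally as (subset index arrays, per-subset orthonormal
    blocks); :meth:`dense` assembles the full d x d matrix, and
    :meth:`transform` applies it without materializing it.
    """

    def __init__(self, subsets: list[np.ndarray], blocks: list[np.ndarray], d: int):
        self.subsets = [np.asarray(s, dtype=int) for s in subsets]
        self.blocks = [np.asarray(b, dtype=float) for b in blocks]
        self.d = int(d)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.d:
            raise ValueError(f"expected {self.d} features, got {X.shape[1]}")
        Y = np.empty_like(X)
        for subset, block in zip(self.subsets, self.blocks):
            Y[:, subset] = X[:, subset] @ block
        return Y

    def dense(self) -> np.ndarray:
        R = np.zeros((self.d, self.d))
        for subset, block in zip(self.subsets, self.blocks):
            R[np.ix_(subset, subset)] = block
        return R

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        R = self.dense()
        return R.astype(dtype) if dtype is not None else R


def _principal_axes(sample: np.ndarray) -> np.ndarray:
    """All principal axes of a sample, eigenvalue-descending, signs fixed.

    Returns a d_k x d_k orthonormal matrix (columns = components).  Signs
    are fixed by making each component's largest-magnitude entry positive;
    a zero-variance sample yields the identity.
    """
    d_k = sample.shape[1]
    cov = np.atleast_2d(np.cov(sample, rowvar=False))
    if not np.any(np.abs(cov) > 1e-12):
        return np.eye(d_k)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order]
    for c in range(d_k):
        if eigvecs[np.argmax(np.abs(eigvecs[:, c])), c] < 0:
            eigvecs[:, c] = -eigvecs[:, c]
    return eigvecs


def build_rotation(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    rng: np.random.Generator,
    bootstrap_fraction: float = 0.75,
    class_subset: str = "random",
) -> Rotation:
    """Construct one rearranged rotation matrix.

    Features are shuffled and split into K near-equal disjoint subsets.
    For each subset a nonempty class subset is drawn, a bootstrap sample of
    ``bootstrap_fraction`` of those classes' rows is taken (with
    replacement), and the PCA of the subset's columns of that sample forms
    the diagonal block.  Rows are rearranged so the result acts on features
    in their original order; its columns are orthonormal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if K > d:
        raise ValueError(f"K={K} exceeds feature count d={d}")
    classes = np.unique(y)
    perm = rng.permutation(d)
    subsets = np.array_split(perm, K)
    blocks: list[np.ndarray] = []
    for subset in subsets:
        if class_subset == "all":
            chosen = classes
        else:
            mask_int = int(rng.integers(1, 2 ** len(classes)))
            chosen = classes[[bool(mask_int >> i & 1) for i in range(len(classes))]]
        rows = np.flatnonzero(np.isin(y, chosen))
        size = max(2, int(round(bootstrap_fraction * rows.size)))
        boot = rng.choice(rows, size=size, replace=True)
        blocks.append(_principal_axes(X[np.ix_(boot, subset)]))
    return Rotation(subsets=list(subsets), blocks=blocks, d=d)


class _SerializedTree:
    """Decision tree restored from its node arrays; predicts by traversal.

    Mirrors the fitted tree's decision rule (descend left when
    ``x[feature] <= threshold``) and its leaf posterior normalization, so a
    reloaded model scores identically to the one that was saved.
    """

    def __init__(self, children_left, children_right, feature, threshold, value, classes):
        self.children_left = np.asarray(children_left, dtype=int)
        self.children_right = np.asarray(children_right, dtype=int)
        self.feature = np.asarray(feature, dtype=int)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(value, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], self.value.shape[1]))
        for i, x in enumerate(X):
            node = 0
            while self.children_left[node] != -1:
                if x[self.feature[node]] <= self.threshold[node]:
                    node = self.children_left[node]
                else:
                    node = self.children_right[node]
            v = self.value[node]
            out[i] = v / v.sum()
        return out


def _tree_to_dict(tree: DecisionTreeClassifier) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value[:, 0, :].tolist(),
    }


class RotationForest:
    """Rotation Forest binary classifier.

    Parameters are carried by a :class:`RotationForestConfig`; the fitted
    state is L (rotation, tree) pairs plus the class list.  All randomness
    derives from ``config.seed`` through per-tree substreams, so
    fit -> predict is bit-reproducible.
    """

    def __init__(self, config: RotationForestConfig | None = None, **kwargs):
        self.config = config if config is not None else RotationForestConfig(**kwargs)
        self.rotations_: list[Rotation] = []
        self.trees_: list = []
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RotationForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        cfg = self.config
        root = np.random.SeedSequence(cfg.seed)
        self.rotations_, self.trees_ = [], []
        for child in root.spawn(cfg.L):
            rng = np.random.default_rng(child)
            rotation = build_rotation(
                X, y, cfg.K, rng,
                bootstrap_fraction=cfg.bootstrap_fraction,
                class_subset=cfg.class_subset,
            )
            tree_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            tree = DecisionTreeClassifier(criterion="gini", random_state=tree_seed)
            tree.fit(rotation.transform(X), y)
            self.rotations_.append(rotation)
            self.trees_.append(tree)
        return self

    @property
    def rotations(self) -> list[Rotation]:
        return self.rotations_

    def _check_fitted(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.rotations_[0].d:
            raise ValueError(
                f"expected {self.rotations_[0].d} features, got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class score per sample: mean tree posterior (soft
        voting) or mean hard vote (majority)."""
        X = self._check_fitted(X)
        pos_col = len(self.classes_) - 1
        scores = np.zeros(X.shape[0])
        for rotation, tree in zip(self.rotations_, self.trees_):
            proba = tree.predict_proba(rotation.transform(X))[:, pos_col]
            if self.config.voting == "majority":
                scores += (proba >= self.config.threshold).astype(float)
            else:
                scores += proba
        return scores / len(self.trees_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Positive class iff score >= threshold (ties go positive)."""
        scores = self.predict_proba(X)
        return np.where(scores >= self.config.threshold, self.classes_[1], self.classes_[0])

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize config, rotations and trees to a versioned JSON file."""
        if self.classes_ is None:
            raise ValueError("cannot save an unfitted model")
        doc = {
            "format": _FORMAT_TAG,
            "version": _FORMAT_VERSION,
            "config": {
                "K": self.config.K,
                "L": self.config.L,
                "bootstrap_fraction": self.config.bootstrap_fraction,
                "seed": self.config.seed,
                "class_subset": self.config.class_subset,
                "voting": self.config.voting,
                "threshold": self.config.threshold,
            },
            "classes": self.classes_.tolist(),
            "members": [
                {
                    "subsets": [s.tolist() for s in rot.subsets],
                    "blocks": [b.tolist() for b in rot.blocks],
                    "d": rot.d,
                    "tree": _tree_to_dict(tree) if isinstance(tree, DecisionTreeClassifier)
                    else {
                        "children_left": tree.children_left.tolist(),
                        "children_right": tree.children_right.tolist(),
                        "feature": tree.feature.tolist(),
                        "threshold": tree.threshold.tolist(),
                        "value": tree.value.tolist(),
                    },
                }
                for rot, tree in zip(self.rotations_, self.trees_)
            ],
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "RotationForest":
        with open(path, "rt", encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("format") != _FORMAT_TAG:
            raise ValueError("not a rotation forest model file")
        if doc.get("version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('version')}")
        model = cls(RotationForestConfig(**doc["config"]))
        model.classes_ = np.asarray(doc["classes"])
        for member in doc["members"]:
            model.rotations_.append(
                Rotation(subsets=member["subsets"], blocks=member["blocks"], d=member["d"])
            )
            t = member["tree"]
            model.trees_.append(
                _SerializedTree(
                    t["children_left"], t["children_right"], t["feature"],
                    t["threshold"], t["value"], model.classes_,
                )
            )
        return model


#: Alias matching the fitted-model vocabulary used elsewhere in the docs.
RotationForestModel = RotationForest
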