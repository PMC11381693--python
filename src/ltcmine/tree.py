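"""Cost-sensitive classification trees on binary condition indicators.

A CART-style learner specialised to the analysis design: features are strictly
binary (condition present/absent), the outcome is binary (at risk / not at
risk), impurity is Gini, and class imbalance is handled by a misclassification
loss matrix that penalises false negatives more heavily than false positives.
The loss enters through per-observation class weights ("altered priors"), the
standard CART equivalence for binary outcomes, so that the weighted Gini of
the root is maximal when the loss is derived from the outcome proportions.

Growth is greedy: at each node the condition giving the largest decrease in
weighted Gini impurity is selected, subject to a maximum depth, a minimum
terminal-node size, and a minimum node size to attempt a split. Ties in split
gain are broken by the lowest feature (registry) index, which makes fitting
fully deterministic given the data. A feature never appears twice on a
root-to-leaf path (a second split on a binary feature is degenerate). Each
leaf predicts the class with minimum expected misclassification loss, so a
leaf predicts "at risk" when its positive fraction exceeds
``fp_penalty / (fp_penalty + fn_penalty)`` rather than one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

_GAIN_EPS = 1e-12  # guard against accepting pure float-noise "gains"


@dataclass(frozen=True)
class LossMatrix:
    """Misclassification costs; false-positive cost is the reference (1.0)."""

    fn_penalty: float
    fp_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.fn_penalty <= 0 or self.fp_penalty <= 0:
            raise ValueError("loss penalties must be strictly positive")

    def scaled(self, multiplier: float) -> "LossMatrix":
        return LossMatrix(self.fn_penalty * multiplier, self.fp_penalty)


def loss_from_proportions(p_at_risk: float) -> LossMatrix:
    """Loss matrix derived directly from the outcome proportions.

    ``fn_penalty = (1 - p) / p`` equalises the two classes' total expected
    loss at the root (the altered-priors balance): with 21% of the sample at
    risk the false-negative penalty is about 3.76.
    """
    if not 0.0 < p_at_risk < 1.0:
        raise ValueError(f"p_at_risk must be in (0, 1), got {p_at_risk}")
    return LossMatrix(fn_penalty=(1.0 - p_at_risk) / p_at_risk, fp_penalty=1.0)


@dataclass(frozen=True)
class TreeHyperparams:
    """Growth constraints. ``min_node_size`` bounds terminal nodes; a node is
    split only if it holds at least ``min_split`` observations (default twice
    the terminal bound). ``complexity_penalty`` rejects splits whose gain is
    at most that fraction of the root impurity (0 disables, as depth and node
    size then govern growth; 0.01 mimics rpart's default pruning)."""

    max_depth: int = 10
    min_node_size: int = 25
    min_split: Optional[int] = None
    complexity_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        ms = self.effective_min_split
        if ms < 2 * self.min_node_size:
            raise ValueError("min_split must be >= 2 * min_node_size")

    @property
    def effective_min_split(self) -> int:
        return self.min_split if self.min_split is not None else 2 * self.min_node_size


def gini_impurity(counts: tuple[float, float], weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Weighted Gini impurity ``2 q (1 - q)`` of a (n_neg, n_pos) node.

    ``weights`` are the per-observation class weights (fp_penalty, fn_penalty);
    ``q`` is the weighted positive fraction.
    """
    n_neg, n_pos = counts
    if n_neg + n_pos <= 0:
        raise ValueError("node must contain at least one observation")
    wn = weights[0] * n_neg
    wp = weights[1] * n_pos
    q = wp / (wp + wn)
    return 2.0 * q * (1.0 - q)


@dataclass
class TreeNode:
    """One node; ``split`` is a feature index into the training columns, or
    None for a leaf. ``present``/``absent`` are the children for indicator
    value 1 and 0."""

    node_id: int
    depth: int
    n: int
    n_at_risk: int
    predicted_class: int
    split: Optional[int] = None
    present: Optional["TreeNode"] = None
    absent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def to_dict(self, feature_names: list[str]) -> dict:
        d = {
            "node_id": self.node_id,
            "depth": self.depth,
            "n": self.n,
            "n_at_risk": self.n_at_risk,
            "predicted_class": self.predicted_class,
        }
        if not self.is_leaf:
            d["split_condition_id"] = feature_names[self.split]
            d["present"] = self.present.to_dict(feature_names)
            d["absent"] = self.absent.to_dict(feature_names)
        return d


@dataclass
class DecisionTreeModel:
    """A fitted cost-sensitive tree plus its training metadata."""

    root: TreeNode
    feature_names: list[str]
    loss: LossMatrix
    hyperparams: TreeHyperparams
    n_train: int

    def leaves(self) -> list[tuple[TreeNode, list[tuple[int, bool]]]]:
        """All leaves with their root-to-leaf paths as (feature, required) lists."""
        out: list[tuple[TreeNode, list[tuple[int, bool]]]] = []

        def walk(node: TreeNode, path: list[tuple[int, bool]]) -> None:
            if node.is_leaf:
                out.append((node, list(path)))
                return
            walk(node.present, path + [(node.split, True)])
            walk(node.absent, path + [(node.split, False)])

        walk(self.root, [])
        return out

    def max_depth_reached(self) -> int:
        return max(leaf.depth for leaf, _ in self.leaves())

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Route rows down the tree; returns (predicted labels, leaf node ids)."""
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X must have {len(self.feature_names)} columns "
                f"(got shape {X.shape})"
            )
        labels = np.empty(len(X), dtype=np.int8)
        leaf_ids = np.empty(len(X), dtype=np.int64)
        stack = [(self.root, np.arange(len(X)))]
        while stack:
            node, rows = stack.pop()
            if len(rows) == 0:
                continue
            if node.is_leaf:
                labels[rows] = node.predicted_class
                leaf_ids[rows] = node.node_id
                continue
            mask = X[rows, node.split] == 1
            stack.append((node.present, rows[mask]))
            stack.append((node.absent, rows[~mask]))
        return labels, leaf_ids

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "loss": {"fn_penalty": self.loss.fn_penalty, "fp_penalty": self.loss.fp_penalty},
            "hyperparams": {
                "max_depth": self.hyperparams.max_depth,
                "min_node_size": self.hyperparams.min_node_size,
                "min_split": self.hyperparams.effective_min_split,
                "complexity_penalty": self.hyperparams.complexity_penalty,
            },
            "n_train": self.n_train,
            "root": self.root.to_dict(self.feature_names),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _leaf_class(n_neg: int, n_pos: int, loss: LossMatrix) -> int:
    # Minimum expected loss: predicting not-at-risk costs fn_penalty per
    # positive, predicting at-risk costs fp_penalty per negative. Ties favour
    # the not-at-risk class (positive fraction must strictly exceed
    # fp / (fp + fn)).
    return int(loss.fn_penalty * n_pos > loss.fp_penalty * n_neg)


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    loss: LossMatrix,
    hp: TreeHyperparams = TreeHyperparams(),
    feature_names: Optional[list[str]] = None,
) -> DecisionTreeModel:
    """Greedy top-down induction of a cost-sensitive binary tree.

    ``X`` is an (n, p) 0/1 matrix in registry column order; ``y`` the 0/1
    at-risk labels. Fitting is deterministic: split-gain ties break to the
    lowest column index.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y have different lengths")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length must match X columns")

    w_neg, w_pos = loss.fp_penalty, loss.fn_penalty
    w = np.where(y == 1.0, w_pos, w_neg)
    # Column stack so per-node statistics are a single matmul:
    # [raw n, raw positives, weighted total, weighted positives] per feature.
    B = np.column_stack([np.ones(n), y, w, w * y])
    min_split = hp.effective_min_split
    min_leaf = hp.min_node_size

    counter = [0]

    def new_node(depth: int, n_node: int, n_pos: int) -> TreeNode:
        node = TreeNode(
            node_id=counter[0],
            depth=depth,
            n=n_node,
            n_at_risk=n_pos,
            predicted_class=_leaf_class(n_node - n_pos, n_pos, loss),
        )
        counter[0] += 1
        return node

    root_n_pos = int(y.sum())
    root_impurity = gini_impurity((n - root_n_pos, root_n_pos), (w_neg, w_pos)) if n else 0.0
    gain_floor = max(hp.complexity_penalty * root_impurity, _GAIN_EPS)

    # The node partitions are passed down as gathered arrays rather than row
    # indices: each level then touches every row once, keeping the whole fit
    # O(depth * n * p) in memory traffic.
    def grow(Xs: np.ndarray, Bs: np.ndarray, depth: int, used: np.ndarray) -> TreeNode:
        n_node = len(Xs)
        n_pos = int(round(Bs[:, 1].sum()))
        node = new_node(depth, n_node, n_pos)
        if (
            depth >= hp.max_depth
            or n_node < min_split
            or n_pos == 0
            or n_pos == n_node
        ):
            return node
        stats = Xs.T @ Bs  # per feature: [n1, pos1, weighted n1, weighted pos1]
        n1 = stats[:, 0]
        wt1 = stats[:, 2]
        wp1 = stats[:, 3]
        n0 = n_node - n1
        wt = w_pos * n_pos + w_neg * (n_node - n_pos)
        wp = w_pos * n_pos
        valid = (~used) & (n1 >= min_leaf) & (n0 >= min_leaf)
        if not valid.any():
            return node
        with np.errstate(divide="ignore", invalid="ignore"):
            q1 = np.where(wt1 > 0, wp1 / wt1, 0.0)
            wt0 = wt - wt1
            wp0 = wp - wp1
            q0 = np.where(wt0 > 0, wp0 / wt0, 0.0)
            child_imp = (wt1 * 2 * q1 * (1 - q1) + wt0 * 2 * q0 * (1 - q0)) / wt
        node_imp = gini_impurity((n_node - n_pos, n_pos), (w_neg, w_pos))
        gains = np.where(valid, node_imp - child_imp, -np.inf)
        j = int(np.argmax(gains))  # ties -> lowest index
        if gains[j] <= gain_floor:
            return node
        node.split = j
        used_child = used.copy()
        used_child[j] = True
        mask = Xs[:, j] == 1.0
        node.present = grow(Xs[mask], Bs[mask], depth + 1, used_child)
        node.absent = grow(Xs[~mask], Bs[~mask], depth + 1, used_child)
        return node

    if n == 0:
        raise ValueError("cannot fit a tree on an empty dataset")
    root = grow(X, B, 0, np.zeros(p, dtype=bool))
    return DecisionTreeModel(
        root=root, feature_names=list(feature_names), loss=loss,
        hyperparams=hp, n_train=n,
    )


def expected_loss(tree: DecisionTreeModel, X: np.ndarray, y: np.ndarray) -> float:
    """Total expected misclassification loss of the tree on (X, y)."""
    labels, _ = tree.predict(X)
    y = np.asarray(y).ravel()
    fn = np.sum((labels == 0) & (y == 1))
    fp = np.sum((labels == 1) & (y == 0))
    return float(fn * tree.loss.fn_penalty + fp * tree.loss.fp_penalty)
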