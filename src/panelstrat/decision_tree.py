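"""CART-style recursive partitioning with terminal-node-size regularisation.

Splits minimise weighted Gini impurity (entropy available via ``criterion``),
there is no cost-complexity pruning, and leaf ties predict non-infected —
the triage-safe default for a tool meant to withhold intervention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_search import PerfReport, confusion

__all__ = ["TreeNode", "gini", "entropy_impurity", "best_split", "grow_tree",
           "predict_tree", "tree_performance", "tree_markers", "tree_to_dict"]


@dataclass
class TreeNode:
    """Internal node (marker/cutoff with children) or leaf (class + counts)."""

    counts: tuple[int, int]  # (non-infected, infected) reaching this node
    marker: str | None = None
    cutoff: float | None = None
    left: "TreeNode | None" = None   # values <= cutoff
    right: "TreeNode | None" = None  # values > cutoff
    prediction: bool | None = None   # leaves only

    @property
    def is_leaf(self) -> bool:
        return self.marker is None


def gini(class_counts) -> float:
    """Gini impurity 1 - sum p_i^2; 0 for a pure node, 0.5 at 50/50."""
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("gini: empty node")
    p = counts / total
    return float(1.0 - np.sum(p**2))


def entropy_impurity(class_counts) -> float:
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy: empty node")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


_CRITERIA = {"gini": gini, "entropy": entropy_impurity}


def _counts(labels: np.ndarray) -> tuple[int, int]:
    return int((~labels).sum()), int(labels.sum())


def best_split(frame, markers, min_leaf: int = 1, criterion: str = "gini"):
    """(marker, cutoff, impurity decrease) maximising the weighted decrease.

    Candidate cutoffs are midpoints between adjacent distinct values.
    Returns None when no split decreases impurity or every split would leave
    a child smaller than ``min_leaf``.  Ties break by larger decrease, then
    marker name order, then lower cutoff.
    """
    impurity = _CRITERIA[criterion]
    labels = frame["infected"].to_numpy(dtype=bool)
    n = len(labels)
    if n == 0:
        raise ValueError("best_split: empty node")
    parent = impurity(_counts(labels))
    best = None  # (decrease, marker, cutoff)
    for marker in sorted(markers):
        vals = frame[marker].to_numpy(dtype=float)
        distinct = np.unique(vals)
        for cut in (distinct[:-1] + distinct[1:]) / 2.0:
            left = vals <= cut
            n_left = int(left.sum())
            if n_left < min_leaf or n - n_left < min_leaf:
                continue
            child = (
                n_left / n * impurity(_counts(labels[left]))
                + (n - n_left) / n * impurity(_counts(labels[~left]))
            )
            decrease = parent - child
            if decrease <= 1e-12:
                continue
            key = (-decrease, marker, float(cut))
            if best is None or key < best[0]:
                best = (key, marker, float(cut), decrease)
    if best is None:
        return None
    return best[1], best[2], best[3]


def grow_tree(frame, markers, min_leaf: int = 1, criterion: str = "gini") -> TreeNode:
    """Recursively grown tree honouring the minimum terminal-node size."""
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    if len(frame) == 0:
        raise ValueError("grow_tree: empty cohort")
    labels = frame["infected"].to_numpy(dtype=bool)
    counts = _counts(labels)
    split = best_split(frame, markers, min_leaf=min_leaf, criterion=criterion)
    if split is None:
        # majority class; tie -> non-infected
        return TreeNode(counts=counts, prediction=counts[1] > counts[0])
    marker, cutoff, _ = split
    vals = frame[marker].to_numpy(dtype=float)
    left = grow_tree(frame[vals <= cutoff], markers, min_leaf, criterion)
    right = grow_tree(frame[vals > cutoff], markers, min_leaf, criterion)
    return TreeNode(counts=counts, marker=marker, cutoff=cutoff, left=left, right=right)


def predict_tree(tree: TreeNode, patient) -> bool:
    """Root-to-leaf descent; '> cutoff' goes right."""
    node = tree
    while not node.is_leaf:
        try:
            value = float(patient[node.marker])
        except (KeyError, TypeError):
            raise ValueError(f"patient is missing marker {node.marker!r} tested by the tree") from None
        node = node.right if value > node.cutoff else node.left
    return bool(node.prediction)


def tree_performance(tree: TreeNode, frame) -> PerfReport:
    preds = np.array([predict_tree(tree, row) for _, row in frame.iterrows()])
    return confusion(preds, frame["infected"].to_numpy(dtype=bool))


def tree_markers(tree: TreeNode) -> list[str]:
    """Sorted distinct markers the tree actually tests."""
    found: set[str] = set()

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        found.add(node.marker)
        walk(node.left)
        walk(node.right)

    walk(tree)
    return sorted(found)


def tree_to_dict(tree: TreeNode) -> dict:
    if tree.is_leaf:
        return {"class": "infected" if tree.prediction else "non-infected",
                "counts": list(tree.counts)}
    return {
        "marker": tree.marker,
        "cutoff": tree.cutoff,
        "counts": list(tree.counts),
        "left": tree_to_dict(tree.left),
        "right": tree_to_dict(tree.right),
    }
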