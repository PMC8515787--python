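"""Decision-tree training, decision-path scoring and first-split error.

A depth-3 decision tree with the information-gain (entropy) criterion is
trained to separate frames of reactive paths from frames of unreactive
paths.  The *main decision path* is the root-to-leaf path whose leaf
maximizes n_r·n_r/(n_r+n_u): the number of reactive samples weighted by
the reactive fraction, favouring leaves that are both populous and pure.

Because the features are highly correlated, small input perturbations
can swap which feature wins the first split.  The reliability of that
first split is estimated with random forests of depth-1 trees (whose
feature importance is by construction the importance of the first split
alone): the time-ordered samples are cut into contiguous blocks, one
forest is fitted per block to get a per-feature spread σ, the mean
importance comes from a forest on the full data, and a Gaussian
Monte-Carlo argmax converts (mean, σ) pairs into the probability that
each feature truly is the most important first split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .invrep import FeatureLabel
from .select import Dataset

__all__ = [
    "TreeNode",
    "ImportanceEstimate",
    "fit_tree",
    "main_decision_path",
    "leaf_reactive_probability",
    "main_path_score",
    "block_partition",
    "rf_first_split_importance",
    "blocked_importance",
    "prob_most_important",
    "render_tree",
]

log = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """One node of a fitted tree; ``left`` is the condition-true branch."""

    n_unreactive: int
    n_reactive: int
    feature: FeatureLabel | None = None  # None at leaves
    feature_index: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    depth: int = 0
    node_id: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    @property
    def n_samples(self) -> int:
        return self.n_unreactive + self.n_reactive

    def inequality(self) -> str:
        if self.is_leaf:
            return "(leaf)"
        return f"{self.feature} <= {self.threshold:.4g}"


@dataclass
class ImportanceEstimate:
    """First-split importances with block-error bars.

    ``mean`` comes from a forest on the full dataset, ``sigma`` from the
    spread over per-block forests, ``p_most_important`` (once computed)
    from a Gaussian Monte-Carlo argmax over features.
    """

    feature_labels: list[FeatureLabel]
    mean: np.ndarray  # (F,)
    sigma: np.ndarray  # (F,)
    block_importances: np.ndarray  # (n_blocks, F)
    p_most_important: np.ndarray | None = None


def fit_tree(data: Dataset, max_depth: int = 3, seed: int = 0) -> TreeNode:
    """Fit the entropy decision tree and export it as :class:`TreeNode`s.

    Single-class input yields a degenerate single-leaf tree with a
    warning rather than an error.
    """
    classes = np.unique(data.labels)
    if classes.size < 2:
        warnings.warn("single-class dataset: returning a degenerate single-leaf tree")
        n = data.n_samples
        only = int(classes[0])
        return TreeNode(
            n_unreactive=n if only == 0 else 0,
            n_reactive=n if only == 1 else 0,
        )
    clf = DecisionTreeClassifier(
        criterion="entropy", max_depth=max_depth, random_state=seed
    )
    clf.fit(data.features, data.labels)
    return _export_sklearn_tree(clf, data.feature_labels)


def _node_counts(tree, node: int, classes: np.ndarray) -> tuple[int, int]:
    # sklearn >=1.3 stores per-node class *fractions*; scale back to counts
    frac = np.asarray(tree.value[node][0], dtype=float)
    if np.isclose(frac.sum(), 1.0):
        counts = frac * tree.weighted_n_node_samples[node]
    else:  # older layout: already counts
        counts = frac
    by_class = {int(c): int(round(counts[k])) for k, c in enumerate(classes)}
    return by_class.get(0, 0), by_class.get(1, 0)


def _export_sklearn_tree(clf: DecisionTreeClassifier, labels: list[FeatureLabel]) -> TreeNode:
    t = clf.tree_
    counter = {"id": 0}

    def build(node: int, depth: int) -> TreeNode:
        nid = counter["id"]
        counter["id"] += 1
        n_u, n_r = _node_counts(t, node, clf.classes_)
        if t.children_left[node] == -1:
            return TreeNode(n_unreactive=n_u, n_reactive=n_r, depth=depth, node_id=nid)
        fidx = int(t.feature[node])
        out = TreeNode(
            n_unreactive=n_u,
            n_reactive=n_r,
            feature=labels[fidx],
            feature_index=fidx,
            threshold=float(t.threshold[node]),
            depth=depth,
            node_id=nid,
        )
        out.left = build(int(t.children_left[node]), depth + 1)
        out.right = build(int(t.children_right[node]), depth + 1)
        return out

    root = build(0, 0)
    _check_counts(root)
    return root


def _check_counts(node: TreeNode) -> None:
    if node.is_leaf:
        return
    assert node.left is not None and node.right is not None
    if (node.left.n_unreactive + node.right.n_unreactive != node.n_unreactive
            or node.left.n_reactive + node.right.n_reactive != node.n_reactive):
        raise AssertionError("child counts do not sum to parent counts")
    _check_counts(node.left)
    _check_counts(node.right)


def main_path_score(node: TreeNode) -> float:
    """n_r·n_r/(n_r+n_u); zero for an empty node."""
    if node.n_samples == 0:
        return 0.0
    return node.n_reactive ** 2 / node.n_samples


def leaf_reactive_probability(node: TreeNode) -> float:
    """Fraction of samples in the node that belong to reactive paths."""
    if node.n_samples == 0:
        raise ValueError("empty node has no reactive probability")
    return node.n_reactive / node.n_samples


def main_decision_path(root: TreeNode) -> list[TreeNode]:
    """Root-to-leaf path of the best-scoring leaf.

    Score ties break toward the shallower leaf, then the earlier leaf in
    preorder — deterministic for any fitted tree.
    """
    best: tuple[float, int, int] | None = None
    best_path: list[TreeNode] = []

    def walk(node: TreeNode, path: list[TreeNode]) -> None:
        nonlocal best, best_path
        path = path + [node]
        if node.is_leaf:
            key = (-main_path_score(node), node.depth, node.node_id)
            if best is None or key < best:
                best = key
                best_path = path
            return
        walk(node.left, path)
        walk(node.right, path)

    walk(root, [])
    return best_path


def _make_forest(n_trees: int, seed: int, max_features: float = 0.25) -> RandomForestClassifier:
    # A 25% feature-subsampling fraction keeps the first-split estimate
    # informative on M^2-sized feature vectors: with sqrt subsampling a
    # genuinely dominant feature enters too few trees to accumulate
    # importance against its many partial correlates.
    return RandomForestClassifier(
        n_estimators=n_trees,
        criterion="entropy",
        max_depth=1,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )


def block_partition(n: int, n_blocks: int) -> list[np.ndarray]:
    """Contiguous, near-equal index blocks: sizes differ by at most one,
    larger blocks first (e.g. 25 rows / 10 blocks -> 3,3,3,3,3,2,2,2,2,2)."""
    if n < n_blocks:
        raise ValueError(f"cannot cut {n} rows into {n_blocks} blocks")
    return np.array_split(np.arange(n), n_blocks)


def rf_first_split_importance(
    data: Dataset, n_trees: int = 1000, seed: int = 0, max_features: float = 0.25
) -> np.ndarray:
    """Per-feature importance of the first split, from a depth-1 forest.

    With every tree limited to one split, the forest's feature
    importance reduces to the importance of the first split alone.
    Importances are normalized to sum to 1.
    """
    if np.unique(data.labels).size < 2:
        raise ValueError("first-split importance needs both classes present")
    forest = _make_forest(n_trees, seed, max_features)
    forest.fit(data.features, data.labels)
    imp = forest.feature_importances_
    total = imp.sum()
    return imp / total if total > 0 else imp


def blocked_importance(
    data: Dataset, n_blocks: int = 10, n_trees: int = 1000, seed: int = 0,
    max_features: float = 0.25,
) -> ImportanceEstimate:
    """Block-error estimate of the first-split importances.

    Rows (already ordered by generation time) are cut into ``n_blocks``
    contiguous, near-equal blocks; row order is shuffled within each
    block; one depth-1 forest per block gives an importance series whose
    per-feature sample standard deviation is σ.  The mean importance
    comes from a single forest on the full dataset.
    """
    n = data.n_samples
    if n < n_blocks:
        raise ValueError(
            f"{n} samples cannot fill {n_blocks} blocks; reduce n_blocks"
        )
    if np.any(np.diff(data.generation_orders) < 0):
        raise ValueError("dataset rows must be sorted by generation_order")
    block_rows = block_partition(n, n_blocks)
    series = np.zeros((n_blocks, data.n_features))
    for b, rows in enumerate(block_rows):
        # every block shares the shuffle stream and the forest seed, so
        # identical blocks give exactly identical importances (sigma 0)
        rows = rows[np.random.default_rng(seed).permutation(rows.size)]
        X, y = data.features[rows], data.labels[rows]
        if np.unique(y).size < 2:
            log.warning("block %d is single-class; its importances are zero", b)
            continue
        forest = _make_forest(n_trees, seed=seed, max_features=max_features)
        forest.fit(X, y)
        imp = forest.feature_importances_
        series[b] = imp / imp.sum() if imp.sum() > 0 else imp
    mean = rf_first_split_importance(data, n_trees=n_trees, seed=seed,
                                     max_features=max_features)
    sigma = series.std(axis=0, ddof=1)
    return ImportanceEstimate(
        feature_labels=data.feature_labels,
        mean=mean,
        sigma=sigma,
        block_importances=series,
    )


def prob_most_important(
    est: ImportanceEstimate, n_mc: int = 100_000, seed: int = 0,
    chunk: int = 4000,
) -> ImportanceEstimate:
    """Probability that each feature is the true most-important one.

    Each feature's importance is modelled as an independent Gaussian
    with the block (mean, σ); ``n_mc`` joint draws are taken and the
    argmax frequencies are the probabilities.  If every σ is zero the
    distribution is degenerate: probability 1 on the max-mean feature
    (split uniformly over exact ties).
    """
    mean = np.asarray(est.mean, dtype=float)
    sigma = np.clip(np.asarray(est.sigma, dtype=float), 0.0, None)
    f = mean.size
    p = np.zeros(f)
    if f == 1:
        p[0] = 1.0
    elif np.all(sigma == 0):
        winners = np.flatnonzero(mean == mean.max())
        p[winners] = 1.0 / winners.size
    else:
        rng = np.random.default_rng(seed)
        counts = np.zeros(f, dtype=np.int64)
        done = 0
        while done < n_mc:
            k = min(chunk, n_mc - done)
            draws = rng.normal(loc=mean, scale=sigma, size=(k, f))
            counts += np.bincount(np.argmax(draws, axis=1), minlength=f)
            done += k
        p = counts / n_mc
    return ImportanceEstimate(
        feature_labels=est.feature_labels,
        mean=est.mean,
        sigma=est.sigma,
        block_importances=est.block_importances,
        p_most_important=p,
    )


def render_tree(root: TreeNode, out) -> None:
    """Write the tree as Graphviz DOT text.

    Each node box shows the split inequality (primed label notation),
    the sample count, the (unreactive, reactive) counts and the majority
    class; the condition-true branch is drawn on the left.
    """
    lines = ["digraph decision_tree {", "  node [shape=box];",
             "  graph [ordering=out];"]
    counter = {"id": 0}

    def emit(node: TreeNode) -> int:
        nid = counter["id"]
        counter["id"] += 1
        majority = "reactive" if node.n_reactive > node.n_unreactive else "unreactive"
        parts = []
        if not node.is_leaf:
            parts.append(node.inequality())
        parts.append(f"samples = {node.n_samples}")
        parts.append(f"(u, r) = ({node.n_unreactive}, {node.n_reactive})")
        parts.append(f"class = {majority}")
        label = "\\n".join(parts)
        lines.append(f'  n{nid} [label="{label}"];')
        if not node.is_leaf:
            lid = emit(node.left)
            rid = emit(node.right)
            lines.append(f'  n{nid} -> n{lid} [label="True"];')
            lines.append(f'  n{nid} -> n{rid} [label="False"];')
        return nid

    emit(root)
    lines.append("}")
    Path(out).write_text("\n".join(lines) + "\n")
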