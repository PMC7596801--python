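"""Task trees over cells: hierarchical-clustering, embedding, star, and shuffled variants.

A :class:`TaskTree` is a rooted tree whose leaves are bijective with cells
(tasks). Each node ``v`` carries a leaf group ``G_v`` (the tasks under its
subtree) and a positive weight ``w_v`` used by the tree-structured penalty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix


class TaskTree:
    """Rooted tree over ``k`` tasks with per-node leaf groups and weights.

    Nodes are integers ``0 .. n_nodes-1``; leaves are ``0 .. k-1`` and map to
    ``cell_ids`` in order. ``parents[root]`` is ``None``.
    """

    def __init__(self, parents: list[int | None], cell_ids: list[str]):
        self.parents = list(parents)
        self.cell_ids = list(cell_ids)
        self.n_nodes = len(parents)
        self.k = len(cell_ids)
        if self.k < 1:
            raise ValueError("tree needs at least one task")
        if len(set(self.cell_ids)) != self.k:
            raise ValueError("duplicate cell ids")

        roots = [v for v, p in enumerate(self.parents) if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]

        self.children: dict[int, list[int]] = {v: [] for v in range(self.n_nodes)}
        for v, p in enumerate(self.parents):
            if p is not None:
                if not 0 <= p < self.n_nodes:
                    raise ValueError(f"node {v}: parent {p} out of range")
                self.children[p].append(v)

        self._check_acyclic()
        for leaf in range(self.k):
            if self.children[leaf]:
                raise ValueError(f"leaf node {leaf} has children")

        self.groups: dict[int, np.ndarray] = {}
        self.weights: dict[int, float] = {}
        compute_groups_and_weights(self)

    def _check_acyclic(self) -> None:
        for start in range(self.n_nodes):
            seen = set()
            v: int | None = start
            while v is not None:
                if v in seen:
                    raise ValueError(f"cycle detected through node {start}")
                seen.add(v)
                v = self.parents[v]

    @property
    def leaves(self) -> range:
        return range(self.k)

    def height(self) -> float:
        return self.weights[self.root]

    def penalty_groups(self) -> list[tuple[np.ndarray, float]]:
        """(task-index array, weight) per node, ordered leaves-to-root.

        The ordering (ascending subtree height) is the order in which the
        exact proximal operator of the laminar group penalty must apply its
        group soft-thresholding passes.
        """
        order = sorted(range(self.n_nodes), key=lambda v: (len(self.groups[v]), v))
        return [(self.groups[v], self.weights[v]) for v in order]

    def __repr__(self) -> str:
        return f"TaskTree(k={self.k}, nodes={self.n_nodes})"


def compute_groups_and_weights(tree: TaskTree, normalize: bool = False) -> TaskTree:
    """Fill ``G_v`` (subtree leaf sets) and ``w_v`` (subtree height, leaves = 1).

    With ``normalize=True`` all weights are divided by the root height.
    """
    groups: dict[int, list[int]] = {}
    heights: dict[int, float] = {}

    def visit(v: int) -> None:
        if not tree.children[v]:
            groups[v] = [v]
            heights[v] = 1.0
            return
        acc: list[int] = []
        for c in tree.children[v]:
            visit(c)
            acc.extend(groups[c])
        groups[v] = sorted(acc)
        heights[v] = 1.0 + max(heights[c] for c in tree.children[v])

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, tree.n_nodes * 2 + 100))
    try:
        visit(tree.root)
    finally:
        sys.setrecursionlimit(old_limit)

    if len(groups[tree.root]) != tree.k:
        raise ValueError("not all leaves reachable from root")
    scale = heights[tree.root] if normalize else 1.0
    tree.groups = {v: np.asarray(g, dtype=int) for v, g in groups.items()}
    tree.weights = {v: h / scale for v, h in heights.items()}
    return tree


def _tree_from_linkage(Z: np.ndarray, cell_ids: list[str]) -> TaskTree:
    k = len(cell_ids)
    parents: list[int | None] = [None] * (2 * k - 1)
    for i in range(Z.shape[0]):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        parents[a] = k + i
        parents[b] = k + i
    return TaskTree(parents, cell_ids)


def build_hc_tree(expr: ExpressionMatrix) -> TaskTree:
    """Complete-linkage agglomeration of cells under dissimilarity 1 - Pearson(cell_i, cell_j)."""
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells")
    stds = expr.values.std(axis=0)
    constant = np.flatnonzero(stds == 0)
    if constant.size:
        bad = expr.cell_ids[constant[0]]
        raise ValueError(f"cell {bad!r} has constant expression; correlation undefined")
    dissim = 1.0 - np.corrcoef(expr.values, rowvar=False)
    np.fill_diagonal(dissim, 0.0)
    # numerical noise can make the matrix asymmetric at the 1e-16 level
    dissim = np.maximum((dissim + dissim.T) / 2.0, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="complete")
    return _tree_from_linkage(Z, expr.cell_ids)


def build_embedding_tree(coords: pd.DataFrame) -> TaskTree:
    """Complete-linkage agglomeration of cells on their 2-D embedding coordinates."""
    if coords.index.has_duplicates:
        raise ValueError("duplicated cell ids in coordinates")
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    if coords.shape[1] != 2:
        raise ValueError("coordinates must have exactly 2 dimensions")
    Z = linkage(pdist(coords.to_numpy(dtype=float)), method="complete")
    return _tree_from_linkage(Z, [str(c) for c in coords.index])


def build_star_tree(cell_ids: list[str]) -> TaskTree:
    """Root plus ``k`` leaf children: the structureless baseline with k + 1 nodes."""
    k = len(cell_ids)
    if k == 0:
        raise ValueError("empty cell list")
    parents: list[int | None] = [k] * k + [None]
    return TaskTree(parents, cell_ids)


def shuffle_expression(expr: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Independently permute each cell's expression values across genes."""
    rng = np.random.default_rng(seed)
    shuffled = expr.values.copy()
    for j in range(expr.n_cells):
        shuffled[:, j] = rng.permutation(shuffled[:, j])
    return ExpressionMatrix(
        shuffled, expr.gene_ids, expr.cell_ids, expr.cell_labels, expr.scale
    )
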