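"""UPGMA clustering of shape distances into a phenetic tree.

UPGMA (average linkage) repeatedly merges the pair of clusters with the
smallest mean pairwise distance; the merged node sits at half the merge
distance, so the result is ultrametric.  Ties are broken deterministically
by the lexicographically smallest pair of original label indices, making
trees reproducible across runs and platforms.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

from .trees import PhyloTree, TreeNode


def upgma(d: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration of a distance matrix into a rooted
    ultrametric tree with branch lengths."""
    labels = list(d.ids)
    m = np.array(d.data, dtype=float)
    n = len(labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    if np.isnan(m).any():
        raise ValueError("distance matrix contains NaN")

    # active clusters: (min original index, size, node, height)
    nodes = {i: TreeNode(labels[i]) for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    min_idx = {i: i for i in range(n)}
    dist = {(i, j): m[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        # find minimal average distance; break ties by lowest-index pair
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                key = (i, j)
                cand = (dist[key], min(min_idx[i], min_idx[j]),
                        max(min_idx[i], min_idx[j]))
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        (dmin, _, _), i, j = best
        height = dmin / 2.0
        parent = TreeNode()
        for child_id in (i, j):
            child = nodes[child_id]
            child.length = height - heights[child_id]
            parent.add_child(child)
        nodes[next_id] = parent
        heights[next_id] = height
        sizes[next_id] = sizes[i] + sizes[j]
        min_idx[next_id] = min(min_idx[i], min_idx[j])
        active -= {i, j}
        for k in active:
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dist[(k, next_id) if k < next_id else (next_id, k)] = (
                sizes[i] * dist[a] + sizes[j] * dist[b]) / (sizes[i] + sizes[j])
        active.add(next_id)
        next_id += 1
    return PhyloTree(nodes[next_id - 1])


def cophenetic_matrix(tree: PhyloTree,
                      unit_branches: bool = False) -> DistanceMatrix:
    """Pairwise tip-to-tip path-length distances of a tree.

    Requires branch lengths unless ``unit_branches`` is set, in which case
    every edge counts 1.
    """
    if not unit_branches and not tree.has_branch_lengths():
        raise ValueError("tree lacks branch lengths "
                         "(pass unit_branches=True for edge counts)")
    tips = sorted(tree.leaf_names())
    pair = tree.tip_distances(unit_branches=unit_branches)
    n = len(tips)
    m = np.zeros((n, n))
    for a_i in range(n):
        for b_i in range(a_i + 1, n):
            m[a_i, b_i] = m[b_i, a_i] = pair[(tips[a_i], tips[b_i])]
    return DistanceMatrix(m, ids=tips)
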