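"""Squared-change parsimony reconstruction of ancestral shapes.

Given tangent-space coordinates at the tips of a rooted tree, the internal
node values minimizing the total squared change summed over edges are the
unique solution of a sparse linear system: at the optimum every internal
node equals the (weight-averaged) mean of its neighbors.  Coordinates are
independent, so all 2k dimensions are solved at once.

By default branches are unweighted (length 1), appropriate for a cladogram
without meaningful branch lengths; pass ``weighted=True`` to use branch
lengths as variances (weights 1/length).

Reconstructed tangent vectors back-project to landmark configurations as
``consensus + deviation`` (optionally magnified) and render as thin-plate
spline deformations of the consensus.
"""

from __future__ import annotations

import numpy as np

from .trees import PhyloTree, TreeNode
from .warps import tps_deformation_grid


def label_internal_nodes(tree: PhyloTree, prefix: str = "node") -> PhyloTree:
    """Assign stable ids (``node1``, ``node2``, ... in preorder) to unnamed
    internal nodes, in place."""
    counter = 0
    for node in tree.preorder():
        if not node.is_leaf and not node.name:
            counter += 1
            node.name = f"{prefix}{counter}"
    return tree


def squared_change_reconstruct(tree: PhyloTree,
                               tip_values: dict[str, np.ndarray],
                               weighted: bool = False) -> dict[str, np.ndarray]:
    """Internal-node values minimizing the summed squared change per edge.

    ``tip_values`` maps every tip label to a coordinate vector (all the
    same length).  Returns a mapping from internal-node id to the
    reconstructed vector; unnamed internal nodes are labelled in place.
    """
    tips = tree.leaf_names()
    missing = [t for t in tips if t not in tip_values]
    if missing:
        raise ValueError(f"tips without values: {missing}")
    label_internal_nodes(tree)
    internal = [n for n in tree.preorder() if not n.is_leaf]
    index = {id(n): i for i, n in enumerate(internal)}
    p = np.atleast_1d(np.asarray(next(iter(tip_values.values())), dtype=float)).size
    n_int = len(internal)
    A = np.zeros((n_int, n_int))
    b = np.zeros((n_int, p))
    for node in internal:
        i = index[id(node)]
        neighbors = list(node.children)
        if node.parent is not None:
            neighbors.append(node.parent)
        for nb in neighbors:
            edge_child = nb if nb in node.children else node
            w = 1.0
            if weighted:
                if edge_child.length is None or edge_child.length <= 0:
                    raise ValueError("weighted reconstruction needs positive "
                                     "branch lengths on every edge")
                w = 1.0 / edge_child.length
            A[i, i] += w
            if nb.is_leaf:
                b[i] += w * np.atleast_1d(np.asarray(tip_values[nb.name], dtype=float))
            else:
                A[i, index[id(nb)]] -= w
    x = np.linalg.solve(A, b)
    return {internal[i].name: x[i] for i in range(n_int)}


def total_squared_change(tree: PhyloTree, tip_values: dict[str, np.ndarray],
                         node_values: dict[str, np.ndarray],
                         weighted: bool = False) -> float:
    """Objective value of an assignment (for optimality checks)."""
    def value(node: TreeNode) -> np.ndarray:
        key = node.name
        src = tip_values if node.is_leaf else node_values
        return np.atleast_1d(np.asarray(src[key], dtype=float))

    total = 0.0
    for node in tree.preorder():
        if node.parent is None:
            continue
        w = 1.0
        if weighted:
            w = 1.0 / node.length
        total += w * float(((value(node) - value(node.parent)) ** 2).sum())
    return total


def ancestral_configuration(node_value: np.ndarray, consensus: np.ndarray,
                            magnification: float = 1.0) -> np.ndarray:
    """Back-project a tangent vector to a k x 2 landmark configuration,
    optionally exaggerating the deviation from the consensus."""
    k = consensus.shape[0]
    deviation = np.asarray(node_value, dtype=float).reshape(k, 2)
    return consensus + magnification * deviation


def ancestral_deformation(node_value: np.ndarray, consensus: np.ndarray,
                          magnification: float = 1.0, resolution: int = 20
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Thin-plate spline deformation grid from the consensus to a
    reconstructed ancestral shape."""
    if magnification < 0:
        raise ValueError("magnification must be non-negative")
    target = ancestral_configuration(node_value, consensus, magnification)
    return tps_deformation_grid(consensus, target, resolution=resolution)
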