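"""Congruence between distance structures: tree distances, character
distances and the two-way Mantel test.

Trees become distance matrices either cophenetically (summed branch
lengths; requires lengths, natural for the UPGMA phenogram) or nodally
(edges counted along the tip-to-tip path; natural for cladograms without
meaningful branch lengths).  Character sub-matrices become mismatch
proportions over jointly scored characters.

The Mantel statistic is the Pearson correlation over the n(n-1)/2
unordered off-diagonal pairs; its null distribution comes from joint
row/column permutations of one matrix, with the one-tailed upper p-value
(count of permuted r >= observed, + 1) / (permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

from .formats import MISSING, CharacterMatrix
from .phenetics import cophenetic_matrix
from .trees import PhyloTree


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None
    tail: str = "upper"

    @property
    def significant_by_half_rule(self) -> bool:
        """The r > 0.5 rule of thumb for 1%-level significance of matrix
        correlations (reported alongside the permutation p, which is the
        primary inference)."""
        return self.r > 0.5


def tree_to_distances(tree: PhyloTree, mode: str = "cophenetic") -> DistanceMatrix:
    """Tip pairwise distances of a tree.

    ``cophenetic`` sums branch lengths (error if any are missing);
    ``nodal`` counts edges on the connecting path.
    """
    if mode == "cophenetic":
        return cophenetic_matrix(tree)
    if mode == "nodal":
        return cophenetic_matrix(tree, unit_branches=True)
    raise ValueError(f"unknown mode {mode!r}")


def character_distance(matrix: CharacterMatrix, subset=None,
                       on_empty_overlap: str = "error") -> DistanceMatrix:
    """Pairwise mismatch proportion over jointly scored characters.

    ``subset`` restricts to the given original character ids.  Pairs of
    taxa with no jointly scored characters either raise (default) or get
    distance 1.0 with ``on_empty_overlap='max'``.
    """
    if subset is not None:
        matrix = matrix.subset(subset)
    states = matrix.states
    scored = states != MISSING
    n = matrix.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = scored[i] & scored[j]
            n_joint = int(joint.sum())
            if n_joint == 0:
                if on_empty_overlap == "error":
                    raise ValueError(
                        f"taxa {matrix.taxa[i]!r} and {matrix.taxa[j]!r} share "
                        "no scored characters in this subset")
                d[i, j] = d[j, i] = 1.0
                continue
            mism = int((states[i, joint] != states[j, joint]).sum())
            d[i, j] = d[j, i] = mism / n_joint
    return DistanceMatrix(d, ids=list(matrix.taxa))


def _condensed(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(a: DistanceMatrix, b: DistanceMatrix,
                n_permutations: int = 9999,
                seed: int | None = None) -> MantelResult:
    """Two-way Mantel test of matrix correspondence (upper tail).

    ``b`` is reordered to ``a``'s labels, which must match as sets.
    Deterministic under ``seed``.
    """
    if set(a.ids) != set(b.ids):
        raise ValueError("distance matrices have different labels")
    if a.shape[0] < 4:
        raise ValueError("Mantel test needs at least 4 taxa")
    b = b.filter(a.ids)
    x = _condensed(np.asarray(a.data))
    bm = np.asarray(b.data)
    y = _condensed(bm)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx < 1e-30 or sy < 1e-30:
        raise ValueError("zero variance in a distance matrix: r undefined")
    r_obs = float(xc @ yc / (sx * sy))
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = _condensed(bm[np.ix_(perm, perm)])
        ypc = yp - yp.mean()
        r_perm = float(xc @ ypc / (sx * np.sqrt(ypc @ ypc)))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r_obs, p, n_permutations, seed)


def body_region_correlations(matrix: CharacterMatrix,
                             wing_distances: DistanceMatrix,
                             regions: dict[str, list[int]],
                             n_permutations: int = 9999,
                             seed: int | None = None) -> dict[str, MantelResult]:
    """Mantel correlations between a wing-shape distance matrix and each
    anatomical character sub-matrix (head, mouthparts, thorax, ...)."""
    out = {}
    for name, ids in regions.items():
        cd = character_distance(matrix, subset=ids, on_empty_overlap="max")
        out[name] = mantel_test(wing_distances, cd,
                                n_permutations=n_permutations, seed=seed)
    return out
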