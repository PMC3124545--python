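"""Maximum-parsimony phylogenetics for unordered multistate characters.

Tree length is Fitch length: the minimum number of state changes summed
over characters, computed by the Fitch set algorithm (states as bitmasks,
vectorized over characters).  Missing entries ('?') contribute the set of
states observed for that character and so never force a change.

The heuristic search is the classic two-phase strategy: random-addition
Wagner starting trees followed by branch swapping (NNI, SPR or TBR),
retaining every distinct topology found at the best length.  On six or
seven taxa the search can be checked against exhaustive enumeration of all
unrooted topologies.

Homoplasy is summarized by the ensemble consistency index CI = M/S and
retention index RI = (G - S)/(G - M), where S is tree length, M the sum of
per-character minima (distinct observed states - 1) and G the sum of
per-character maxima (scored taxa - modal state count).

Trees are represented rooted along the edge adjacent to a fixed "anchor"
leaf, which makes rooted topologies correspond one-to-one with unrooted
ones; Fitch length is independent of that choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formats import MISSING, CharacterMatrix
from .trees import PhyloTree, TreeNode

__all__ = [
    "ParsimonyStats", "SearchResult", "Change",
    "fitch_length", "character_bounds", "ci_ri",
    "heuristic_search", "exhaustive_search", "bootstrap_support",
    "apply_support", "strict_consensus", "map_changes", "reroot_at_outgroup",
]


# ---------------------------------------------------------------------------
# encoding and Fitch length
# ---------------------------------------------------------------------------

def encode_matrix(matrix: CharacterMatrix) -> np.ndarray:
    """States as bitmasks, one uint16 per cell; '?' becomes the union of
    the states observed for that character."""
    states = matrix.states
    bits = np.where(states == MISSING, 0, 1 << np.clip(states, 0, None)
                    ).astype(np.uint16)
    observed = np.bitwise_or.reduce(bits, axis=0)
    return np.where(states == MISSING, observed, bits).astype(np.uint16)


def _tree_fitch_length(root: TreeNode, tip_bits: dict[str, np.ndarray],
                       weights: np.ndarray | None = None,
                       per_character: bool = False):
    """Fitch length of a rooted tree whose leaves are named in tip_bits.

    Internal nodes must be binary; the root may have 2 or 3 children
    (children are folded pairwise, which is exact for a root of degree
    <= 3, i.e. a tree rooted on an edge or an unrooted trifurcation).
    """
    n_chars = next(iter(tip_bits.values())).shape[0]
    steps = np.zeros(n_chars, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    stack: list[tuple[TreeNode, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf:
            try:
                sets[id(node)] = tip_bits[node.name]
            except KeyError:
                raise ValueError(f"tip {node.name!r} not in character matrix")
            continue
        if not expanded:
            if node is not root and len(node.children) != 2:
                raise ValueError("Fitch length requires a binary tree "
                                 "(resolve polytomies first)")
            stack.append((node, True))
            for child in node.children:
                stack.append((child, False))
            continue
        acc = None
        for child in node.children:
            cs = sets.pop(id(child))
            if acc is None:
                acc = cs
            else:
                inter = acc & cs
                empty = inter == 0
                steps += empty
                acc = np.where(empty, acc | cs, inter)
        sets[id(node)] = acc
    if per_character:
        return steps
    if weights is None:
        return int(steps.sum())
    return float(steps @ weights) if weights.dtype.kind == "f" else int(steps @ weights)


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix,
                 weights: np.ndarray | None = None) -> int:
    """Minimum number of unordered-state changes of ``tree`` on ``matrix``."""
    tips = tree.leaf_names()
    if set(tips) != set(matrix.taxa):
        extra = sorted(set(tips) - set(matrix.taxa))
        missing = sorted(set(matrix.taxa) - set(tips))
        raise ValueError(f"taxon mismatch: tree-only={extra}, matrix-only={missing}")
    bits = encode_matrix(matrix)
    tip_bits = {t: bits[i] for i, t in enumerate(matrix.taxa)}
    return _tree_fitch_length(tree.root, tip_bits, weights)


def character_bounds(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-character (min_steps, max_steps) over all possible trees:
    min = distinct observed states - 1; max = scored taxa - modal count."""
    n_chars = matrix.n_characters
    mins = np.zeros(n_chars, dtype=np.int64)
    maxs = np.zeros(n_chars, dtype=np.int64)
    for c in range(n_chars):
        col = matrix.states[:, c]
        scored = col[col != MISSING]
        if scored.size == 0:
            continue
        counts = np.bincount(scored)
        counts = counts[counts > 0]
        mins[c] = counts.size - 1
        maxs[c] = scored.size - counts.max()
    return mins, maxs


@dataclass
class ParsimonyStats:
    """Tree length with ensemble homoplasy indices."""

    length: int
    min_steps: int
    max_steps: int
    ci: float
    ri: float
    ci_informative: float | None = None
    ri_defined: bool = True

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return round(self.ci, ndigits), round(self.ri, ndigits)


def ci_ri(s: int, matrix: CharacterMatrix) -> ParsimonyStats:
    """Ensemble CI and RI for a tree of length ``s`` on ``matrix``.

    The headline CI includes all characters; ``ci_informative`` excludes
    characters that cannot show homoplasy on any tree (min == max).
    """
    mins, maxs = character_bounds(matrix)
    m, g = int(mins.sum()), int(maxs.sum())
    if not (m <= s <= g):
        raise ValueError(f"length {s} outside feasible range [{m}, {g}]")
    ci = m / s if s > 0 else 1.0
    if g > m:
        ri = (g - s) / (g - m)
        ri_defined = True
    else:
        ri = float("nan")
        ri_defined = False
        warnings.warn("no parsimony-informative variation: RI undefined")
    informative = maxs > mins
    ci_inf = None
    if informative.any():
        m_inf = int(mins[informative].sum())
        s_inf = s - int(mins[~informative].sum())  # uninformative realize their minimum
        ci_inf = m_inf / s_inf if s_inf > 0 else 1.0
    return ParsimonyStats(s, m, g, ci, ri, ci_inf, ri_defined)


# ---------------------------------------------------------------------------
# tree manipulation helpers (anchored rooted representation)
# ---------------------------------------------------------------------------

def _leaf(name: str) -> TreeNode:
    return TreeNode(name)


def _copy_tree(node: TreeNode) -> TreeNode:
    clone = TreeNode(node.name)
    for child in node.children:
        clone.add_child(_copy_tree(child))
    return clone


def _nodes_below(root: TreeNode) -> list[TreeNode]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _splits_of(root: TreeNode) -> frozenset[frozenset[str]]:
    """Canonical unrooted-topology key: the set of non-trivial splits, each
    encoded as the side not containing the alphabetically first tip."""
    return frozenset(PhyloTree(root).bipartitions())


def _insert_leaf_above(u: TreeNode, leaf: TreeNode) -> TreeNode:
    parent = u.parent
    idx = parent.children.index(u)
    joint = TreeNode()
    joint.children = [u, leaf]
    u.parent = joint
    leaf.parent = joint
    parent.children[idx] = joint
    joint.parent = parent
    return joint


def _remove_joint(joint: TreeNode, u: TreeNode) -> None:
    parent = joint.parent
    idx = parent.children.index(joint)
    parent.children[idx] = u
    u.parent = parent


def _subtree_adjacency(v: TreeNode) -> dict[int, list[TreeNode]]:
    """Unrooted adjacency of the subtree hanging from ``v``, with the
    degree-2 attachment node ``v`` suppressed."""
    adj: dict[int, list[TreeNode]] = {}
    for node in _nodes_below(v):
        for child in node.children:
            a, b = node, child
            adj.setdefault(id(a), []).append(b)
            adj.setdefault(id(b), []).append(a)
    # splice out v (degree 2 inside its own subtree)
    c1, c2 = v.children
    adj[id(c1)] = [n for n in adj[id(c1)] if n is not v] + [c2]
    adj[id(c2)] = [n for n in adj[id(c2)] if n is not v] + [c1]
    del adj[id(v)]
    return adj


def _root_on_edge(adj: dict[int, list[TreeNode]], a: TreeNode,
                  b: TreeNode) -> TreeNode:
    """Build a fresh rooted (degree-2 root) copy of an unrooted adjacency,
    rooted on edge (a, b)."""
    def build(node: TreeNode, come_from: TreeNode) -> TreeNode:
        clone = TreeNode(node.name)
        for nb in adj[id(node)]:
            if nb is not come_from:
                clone.add_child(build(nb, node))
        return clone
    root = TreeNode()
    root.add_child(build(a, b))
    root.add_child(build(b, a))
    return root


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    best_trees: list[PhyloTree]
    best_length: int
    n_replicates: int
    seed: int | None
    hit_max_trees: bool = False
    stats: ParsimonyStats | None = None


def _random_addition_tree(order: list[str], tip_bits, rng) -> TreeNode:
    anchor = order[0]
    root = TreeNode()
    root.add_child(_leaf(anchor))
    cherry = TreeNode()
    cherry.add_child(_leaf(order[1]))
    cherry.add_child(_leaf(order[2]))
    root.add_child(cherry)
    cherry.parent = root
    for name in order[3:]:
        leaf = _leaf(name)
        best_len, best_edges = None, []
        targets = [n for n in _nodes_below(root)
                   if n.parent is not None and n.name != anchor]
        for u in targets:
            joint = _insert_leaf_above(u, leaf)
            length = _tree_fitch_length(root, tip_bits)
            _remove_joint(joint, u)
            if best_len is None or length < best_len:
                best_len, best_edges = length, [u]
            elif length == best_len:
                best_edges.append(u)
        u = best_edges[rng.integers(0, len(best_edges))]
        _insert_leaf_above(u, leaf)
    return root


def _swap_candidates(root: TreeNode, anchor: str):
    """Prunable subtree roots: every node except the tree root, the anchor
    leaf and the anchor's sibling (whose removal would empty the tree)."""
    return [n for n in _nodes_below(root)
            if n.parent is not None and n.parent.parent is not None
            and n.name != anchor]


def _iter_moves(root: TreeNode, anchor: str, swapper: str, tip_bits):
    """Yield (length, splits) for every neighbor topology under the chosen
    swap regime, leaving the tree unchanged afterwards."""
    for v in _swap_candidates(root, anchor):
        p = v.parent
        g = p.parent
        gi = g.children.index(p)
        sib = p.children[0] if p.children[1] is v else p.children[1]
        orig_children = list(p.children)
        # prune: splice p out
        g.children[gi] = sib
        sib.parent = g

        if swapper == "nni":
            # regrafting onto edges adjacent to the original location
            # reproduces the NNI rearrangements across edge (p, g)
            targets = [n for n in g.children
                       if n is not sib and n.name != anchor] + \
                      ([g] if g.parent is not None else [])
        else:
            targets = [n for n in _nodes_below(root)
                       if n.parent is not None and n.name != anchor
                       and n is not sib]

        subtree_versions: list[TreeNode] = [v]
        if swapper == "tbr" and v.children:
            adj = _subtree_adjacency(v)
            for node in _nodes_below(v):
                # edges (c1, v) and (c2, v) merge into the original
                # attachment edge (c1, c2), already covered by plain SPR
                if node is v or node.parent is v:
                    continue
                subtree_versions.append(_root_on_edge(adj, node, node.parent))

        for sub in subtree_versions:
            for u in targets:
                gu = u.parent
                ui = gu.children.index(u)
                p.children = [u, sub]
                u.parent = p
                sub.parent = p
                gu.children[ui] = p
                p.parent = gu
                length = _tree_fitch_length(root, tip_bits)
                yield length, root
                gu.children[ui] = u
                u.parent = gu
        # undo prune
        g.children[gi] = p
        p.parent = g
        p.children = orig_children
        for child in p.children:
            child.parent = p
        v.parent = p
        sib.parent = p


def _search_from(root: TreeNode, anchor: str, swapper: str, tip_bits,
                 max_trees: int):
    """Branch swapping to a local optimum, then a walk through the island
    of equally short trees.  Returns (best_length, {splits: root})."""
    current = root
    current_len = _tree_fitch_length(current, tip_bits)
    improved = True
    while improved:
        improved = False
        for length, tree_root in _iter_moves(current, anchor, swapper, tip_bits):
            if length < current_len:
                current = _copy_tree(tree_root)
                current_len = length
                improved = True
                break
    best: dict[frozenset, TreeNode] = {_splits_of(current): current}
    queue = [current]
    hit_cap = False
    while queue:
        tree = queue.pop()
        for length, tree_root in _iter_moves(tree, anchor, swapper, tip_bits):
            if length < current_len:
                # a shorter tree reachable from the island: restart from it
                return _search_from(_copy_tree(tree_root), anchor, swapper,
                                    tip_bits, max_trees)
            if length == current_len:
                key = _splits_of(tree_root)
                if key not in best:
                    if len(best) >= max_trees:
                        hit_cap = True
                        continue
                    clone = _copy_tree(tree_root)
                    best[key] = clone
                    queue.append(clone)
    return current_len, best, hit_cap


def heuristic_search(matrix: CharacterMatrix, n_addition_replicates: int = 100,
                     swapper: str = "tbr", max_trees: int = 1000,
                     seed: int | None = None, outgroup: str | None = None,
                     weights: np.ndarray | None = None) -> SearchResult:
    """Random-addition Wagner trees plus branch swapping.

    Retains all distinct topologies at the best length found (up to
    ``max_trees``); deterministic under ``seed``.  If ``outgroup`` is
    given, reported trees are rooted on its edge.
    """
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search needs at least 4 taxa")
    if swapper not in ("nni", "spr", "tbr"):
        raise ValueError(f"unknown swapper {swapper!r}")
    if weights is not None:
        raise NotImplementedError("use bootstrap_support for weighted searches")
    rng = np.random.default_rng(seed)
    bits = encode_matrix(matrix)
    tip_bits = {t: bits[i] for i, t in enumerate(matrix.taxa)}
    best_len = None
    best: dict[frozenset, TreeNode] = {}
    hit_cap = False
    for _ in range(n_addition_replicates):
        order = [matrix.taxa[i] for i in rng.permutation(matrix.n_taxa)]
        start = _random_addition_tree(order, tip_bits, rng)
        length, trees, cap = _search_from(start, order[0], swapper, tip_bits,
                                          max_trees)
        hit_cap = hit_cap or cap
        if best_len is None or length < best_len:
            best_len, best = length, dict(trees)
        elif length == best_len:
            for key, tree in trees.items():
                if key not in best:
                    if len(best) >= max_trees:
                        hit_cap = True
                        break
                    best[key] = tree
    if hit_cap:
        warnings.warn(f"max_trees={max_trees} reached; tree list truncated")
    out_trees = []
    for root in best.values():
        tree = PhyloTree(_copy_tree(root))
        if outgroup is not None:
            tree = reroot_at_outgroup(tree, outgroup)
        out_trees.append(tree)
    stats = ci_ri(best_len, matrix)
    return SearchResult(out_trees, best_len, n_addition_replicates, seed,
                        hit_cap, stats)


def _all_topologies(taxa: list[str]):
    """All unrooted binary topologies, as anchored rooted trees."""
    anchor = taxa[0]
    root = TreeNode()
    root.add_child(_leaf(anchor))
    cherry = TreeNode()
    cherry.add_child(_leaf(taxa[1]))
    cherry.add_child(_leaf(taxa[2]))
    root.add_child(cherry)
    cherry.parent = root
    trees = [root]
    for name in taxa[3:]:
        grown = []
        for tree in trees:
            targets = [n for n in _nodes_below(tree)
                       if n.parent is not None and n.name != anchor]
            for i in range(len(targets)):
                clone = _copy_tree(tree)
                clone_targets = [n for n in _nodes_below(clone)
                                 if n.parent is not None and n.name != anchor]
                _insert_leaf_above(clone_targets[i], _leaf(name))
                grown.append(clone)
        trees = grown
    return trees


def exhaustive_search(matrix: CharacterMatrix,
                      outgroup: str | None = None) -> SearchResult:
    """Evaluate every unrooted topology (feasible to ~8 taxa)."""
    if matrix.n_taxa > 9:
        raise ValueError("exhaustive search limited to 9 taxa")
    bits = encode_matrix(matrix)
    tip_bits = {t: bits[i] for i, t in enumerate(matrix.taxa)}
    best_len, best = None, {}
    for root in _all_topologies(list(matrix.taxa)):
        length = _tree_fitch_length(root, tip_bits)
        if best_len is None or length < best_len:
            best_len, best = length, {_splits_of(root): root}
        elif length == best_len:
            best.setdefault(_splits_of(root), root)
    out = []
    for root in best.values():
        tree = PhyloTree(root)
        if outgroup is not None:
            tree = reroot_at_outgroup(tree, outgroup)
        out.append(tree)
    return SearchResult(out, best_len, 0, None, False, ci_ri(best_len, matrix))


# ---------------------------------------------------------------------------
# bootstrap, consensus, rooting
# ---------------------------------------------------------------------------

def bootstrap_support(matrix: CharacterMatrix, n_reps: int = 1000,
                      seed: int | None = None, addition_replicates: int = 10,
                      swapper: str = "spr") -> dict[frozenset, float]:
    """Character bootstrap: resample columns with replacement, search with
    reduced effort, and record bipartition frequencies (0-1)."""
    rng = np.random.default_rng(seed)
    bits = encode_matrix(matrix)
    n_chars = matrix.n_characters
    counts_by_split: dict[frozenset, int] = {}
    for _ in range(n_reps):
        weights = np.bincount(rng.integers(0, n_chars, size=n_chars),
                              minlength=n_chars).astype(np.int64)
        cols = np.repeat(np.arange(n_chars), weights)
        tip_bits = {t: bits[i][cols] for i, t in enumerate(matrix.taxa)}
        best_len, best_root = None, None
        for _rep in range(addition_replicates):
            order = [matrix.taxa[i] for i in rng.permutation(matrix.n_taxa)]
            start = _random_addition_tree(order, tip_bits, rng)
            length, trees, _cap = _search_from(start, order[0], swapper,
                                               tip_bits, max_trees=1)
            if best_len is None or length < best_len:
                best_len = length
                best_root = next(iter(trees.values()))
        for split in _splits_of(best_root):
            counts_by_split[split] = counts_by_split.get(split, 0) + 1
    return {s: c / n_reps for s, c in counts_by_split.items()}


def apply_support(tree: PhyloTree, frequencies: dict[frozenset, float],
                  percent: bool = True) -> PhyloTree:
    """Annotate a tree's internal nodes with bootstrap frequencies."""
    all_tips = frozenset(tree.leaf_names())
    anchor = min(all_tips)
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        side = clade if anchor not in clade else all_tips - clade
        if 1 < len(side) < len(all_tips) - 1:
            freq = frequencies.get(side, 0.0)
            node.support = round(freq * 100, 1) if percent else freq
    return tree


def strict_consensus(trees: list[PhyloTree]) -> tuple[PhyloTree, int]:
    """Tree containing exactly the splits common to all inputs, plus the
    number of nodes collapsed relative to the first input."""
    if not trees:
        raise ValueError("no trees given")
    tip_sets = [set(t.leaf_names()) for t in trees]
    if any(ts != tip_sets[0] for ts in tip_sets[1:]):
        raise ValueError("trees have different tip sets")
    splits = [t.bipartitions() for t in trees]
    common = set.intersection(*splits)
    n_collapsed = len(splits[0]) - len(common)
    tips = sorted(tip_sets[0])
    anchor = tips[0]
    all_tips = frozenset(tips)
    # clades in the anchor-rooted tree: the split side away from the anchor
    clades = sorted(common, key=len, reverse=True)
    root = TreeNode()
    node_for: dict[frozenset, TreeNode] = {all_tips: root}
    tipset_of: dict[int, frozenset] = {id(root): all_tips}
    for clade in clades:
        # parent = smallest existing clade strictly containing this one
        parent_set = min((s for s in node_for if clade < s), key=len)
        node = TreeNode()
        node_for[frozenset(clade)] = node
        node_for[parent_set].add_child(node)
    for tip in tips:
        parent_set = min((s for s in node_for if tip in s), key=len)
        node_for[parent_set].add_child(_leaf(tip))
    return PhyloTree(root), n_collapsed


def reroot_at_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Reroot (topology only) on the edge leading to the outgroup tip."""
    if outgroup not in tree.leaf_names():
        raise ValueError(f"outgroup {outgroup!r} not among tips")
    adj: dict[int, list[TreeNode]] = {}
    nodes = list(tree.postorder())
    for node in nodes:
        for child in node.children:
            adj.setdefault(id(node), []).append(child)
            adj.setdefault(id(child), []).append(node)
    # suppress a degree-2 root
    root = tree.root
    if len(root.children) == 2:
        c1, c2 = root.children
        adj[id(c1)] = [n for n in adj[id(c1)] if n is not root] + [c2]
        adj[id(c2)] = [n for n in adj[id(c2)] if n is not root] + [c1]
        del adj[id(root)]
    og = next(n for n in nodes if n.name == outgroup)
    return PhyloTree(_root_on_edge(adj, og, adj[id(og)][0]))


# ---------------------------------------------------------------------------
# character-change mapping
# ---------------------------------------------------------------------------

@dataclass
class Change:
    """One state change on one branch (branch named by its child node)."""

    character_id: int
    node: TreeNode
    from_state: int
    to_state: int
    homoplasious: bool


def map_changes(tree: PhyloTree, matrix: CharacterMatrix) -> list[Change]:
    """Resolve Fitch state sets to one most-parsimonious assignment and
    list every change, flagging characters whose realized steps exceed
    their minimum as homoplasious.

    Ambiguities are resolved by keeping the parent's state whenever the
    child's preliminary set allows it (the classic Fitch backtracking rule,
    which always realizes the minimum length), choosing the lowest state
    otherwise.
    """
    if not all(len(n.children) in (0, 2) for n in tree.postorder()):
        raise ValueError("change mapping requires a binary rooted tree")
    if set(tree.leaf_names()) != set(matrix.taxa):
        raise ValueError("tree tips do not match matrix taxa")
    bits = encode_matrix(matrix)
    tip_bits = {t: bits[i] for i, t in enumerate(matrix.taxa)}
    prelim: dict[int, np.ndarray] = {}
    order = list(tree.postorder())
    for node in order:
        if node.is_leaf:
            prelim[id(node)] = tip_bits[node.name]
            continue
        left, right = (prelim[id(c)] for c in node.children)
        inter = left & right
        prelim[id(node)] = np.where(inter == 0, left | right, inter)
    realized = _tree_fitch_length(tree.root, tip_bits, per_character=True)
    mins, _ = character_bounds(matrix)
    homoplasious = realized > mins

    def lowest_bit(mask: np.ndarray) -> np.ndarray:
        return (mask & (~mask + 1)).astype(np.uint16)

    state_of: dict[int, np.ndarray] = {}
    changes: list[Change] = []
    root = tree.root
    state_of[id(root)] = lowest_bit(prelim[id(root)])
    for node in tree.preorder():
        if node is root:
            continue
        parent_state = state_of[id(node.parent)]
        p = prelim[id(node)]
        keep = (parent_state & p) != 0
        state = np.where(keep, parent_state, lowest_bit(p)).astype(np.uint16)
        state_of[id(node)] = state
        for c in np.flatnonzero(state != parent_state):
            changes.append(Change(
                matrix.character_ids[c], node,
                int(np.log2(parent_state[c])), int(np.log2(state[c])),
                bool(homoplasious[c])))
    return changes
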