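"""Lightweight phylogenetic tree structure shared by all pipeline stages.

A :class:`PhyloTree` is a rooted node tree with optional branch lengths and
support values.  It is deliberately minimal: the parsimony search mutates
trees millions of times, so nodes are plain slotted objects.  Newick parsing
is delegated to dendropy (see :mod:`wingshape.formats`).
"""

from __future__ import annotations

from typing import Iterator


class TreeNode:
    """One node of a rooted tree."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, n_children={len(self.children)})"


class PhyloTree:
    """Rooted tree with labels, optional branch lengths and support values."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.postorder()
                   if n is not self.root)

    # -- copying -----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def rec(node: TreeNode) -> TreeNode:
            clone = TreeNode(node.name, node.length, node.support)
            for child in node.children:
                clone.add_child(rec(child))
            return clone
        return PhyloTree(rec(self.root))

    # -- distances ---------------------------------------------------------
    def tip_distances(self, unit_branches: bool = False) -> dict[tuple[str, str], float]:
        """Pairwise tip-to-tip path lengths.

        With ``unit_branches`` every edge counts 1 (nodal distance);
        otherwise branch lengths are summed and must all be present.
        """
        dist: dict[tuple[str, str], float] = {}
        # tips_below[node] = {tip_name: distance to node}
        tips_below: dict[int, dict[str, float]] = {}
        for node in self.postorder():
            if node.is_leaf:
                tips_below[id(node)] = {node.name: 0.0}
                continue
            child_maps = []
            for child in node.children:
                step = 1.0 if unit_branches else child.length
                if step is None:
                    raise ValueError(
                        f"missing branch length on edge above {child.name or 'internal node'}")
                child_maps.append({t: d + step
                                   for t, d in tips_below.pop(id(child)).items()})
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for ta, da in child_maps[i].items():
                        for tb, db in child_maps[j].items():
                            key = (ta, tb) if ta < tb else (tb, ta)
                            dist[key] = da + db
            merged: dict[str, float] = {}
            for m in child_maps:
                merged.update(m)
            tips_below[id(node)] = merged
        return dist

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the side NOT holding the
        alphabetically first tip (a rooting-independent canonical form)."""
        all_tips = frozenset(self.leaf_names())
        anchor = min(all_tips)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
                continue
            clade = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = clade
            side = clade if anchor not in clade else all_tips - clade
            if 1 < len(side) < len(all_tips) - 1:
                splits.add(side)
        return splits

    # -- serialization -----------------------------------------------------
    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = _escape(node.name or "")
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = node.name
                if label is None and node.support is not None:
                    label = _format_number(node.support, decimals)
                s = f"({inner}){_escape(label) if label else ''}"
            if node.length is not None:
                s += f":{_format_number(node.length, decimals)}"
            return s
        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves})"


def _format_number(x: float, decimals: int) -> str:
    s = f"{x:.{decimals}f}".rstrip("0").rstrip(".")
    return s or "0"


_NEWICK_META = set("(),:;[]'")


def _escape(label: str) -> str:
    if any(c in _NEWICK_META or c.isspace() for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise ValueError("trees have different tip sets")
    sa, sb = a.bipartitions(), b.bipartitions()
    return len(sa ^ sb)
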