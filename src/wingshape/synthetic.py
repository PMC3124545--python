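"""Synthetic wing-morphometrics data with known evolutionary structure.

Real landmark coordinates for studies of this kind are rarely deposited,
so every pipeline stage is exercised on generated data whose ground truth
is known by construction:

* a fixed, documented 19-landmark wing-like template (elongate outline,
  landmarks concentrated basally and along the leading edge);
* a pure-birth (Yule) tree;
* shape evolution as independent Brownian motion per tangent-space
  coordinate along branches, starting from the template, with i.i.d.
  Gaussian digitization noise added at the tips;
* discrete characters evolved on the *same* tree under a symmetric
  k-state Markov (Mk) model.

Because shapes and characters share one true tree, the congruence between
morphometric and phylogenetic distance structures that the pipeline is
designed to detect is positive by construction, and ancestral shapes are
recoverable against stored true node values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats import (MISSING, CharacterMatrix, TpsRecord, write_character_matrix,
                      write_groups, write_newick, write_tps)
from .superimposition import LandmarkConfiguration, center_and_scale
from .trees import PhyloTree, TreeNode
from .warps import _similarity_basis  # orthonormal similarity directions

# Hand-placed wing-like template: base cluster (articulation), leading edge,
# apex, trailing edge, two interior vein junctions.  Aspect ratio ~3:1.
_WING_TEMPLATE_19 = np.array([
    (0.00, 0.10), (0.30, 0.55), (0.45, -0.35), (1.10, 0.80), (1.25, -0.60),
    (2.20, 0.95), (3.40, 1.05), (4.80, 1.10), (6.20, 1.00), (7.60, 0.75),
    (8.80, 0.30), (9.30, -0.05),
    (8.20, -0.55), (7.00, -0.85), (5.60, -1.00), (4.10, -1.05), (2.80, -0.95),
    (3.00, 0.25), (5.20, -0.15),
])


@dataclass
class SimulationConfig:
    """Study-scale defaults: 81 taxa, 19 landmarks, 119 characters."""

    n_taxa: int = 81
    n_landmarks: int = 19
    bm_rate: float = 0.001       # per-coordinate variance per unit branch length
    noise_sd: float = 0.005      # digitization noise, shape units
    n_characters: int = 119
    n_states: int = 3
    char_rate: float = 0.1       # expected substitutions per unit branch length
    birth_rate: float = 1.0
    missing_fraction: float = 0.0
    n_groups: int = 9
    seed: int = 0

    def __post_init__(self):
        for name in ("bm_rate", "noise_sd", "char_rate", "birth_rate",
                     "missing_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def wing_template(k: int = 19) -> LandmarkConfiguration:
    """The fixed wing-like template, centered with unit centroid size.

    For ``k`` < 19 the first k landmarks are used; larger k adds evenly
    interpolated points along the leading-to-trailing outline.
    """
    if k < 4:
        raise ValueError("need at least 4 landmarks")
    if k <= 19:
        coords = _WING_TEMPLATE_19[:k]
    else:
        extra = k - 19
        t = np.linspace(0.15, 0.85, extra)
        arc = np.column_stack([9.3 * t, 1.2 * np.sin(np.pi * t) - 0.05 + 0.03 * t])
        coords = np.vstack([_WING_TEMPLATE_19, arc])
    return center_and_scale(LandmarkConfiguration("template", coords))


def simulate_tree(n_taxa: int, birth_rate: float = 1.0,
                  seed: int | None = None) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_taxa`` tips, ultrametric, with the
    present set one inter-speciation waiting time after the last split."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    birth_time = {}
    active = []
    for _ in range(2):
        child = root.add_child(TreeNode())
        birth_time[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(0, len(active)))
        node.length = t - birth_time[id(node)]
        for _ in range(2):
            child = node.add_child(TreeNode())
            birth_time[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = t - birth_time[id(node)]
    tree = PhyloTree(root)
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.name = f"t{i}"
    return tree


def assign_groups(tree: PhyloTree, n_groups: int) -> dict[str, str]:
    """Partition tips into ``n_groups`` monophyletic groups by repeatedly
    splitting the largest clade (emulates tribes on the true tree)."""
    if n_groups < 1:
        raise ValueError("need at least 1 group")
    clades: list[list[str]] = [[]]
    node_tips: dict[int, list[str]] = {}
    for node in tree.postorder():
        node_tips[id(node)] = ([node.name] if node.is_leaf else
                               sum((node_tips[id(c)] for c in node.children), []))
    frontier = [tree.root]
    while len(frontier) < n_groups:
        frontier.sort(key=lambda n: (-len(node_tips[id(n)]), node_tips[id(n)][0]))
        biggest = frontier[0]
        if biggest.is_leaf:
            break
        frontier = frontier[1:] + list(biggest.children)
    groups = {}
    for gi, node in enumerate(sorted(frontier, key=lambda n: node_tips[id(n)][0]),
                              start=1):
        for tip in node_tips[id(node)]:
            groups[tip] = f"g{gi}"
    return groups


def simulate_bm_landmarks(tree: PhyloTree, template: LandmarkConfiguration,
                          bm_rate: float, noise_sd: float,
                          seed: int | None = None
                          ) -> tuple[list[LandmarkConfiguration],
                                     dict[str, np.ndarray]]:
    """Brownian-motion shape evolution in the tangent space at the template.

    Per-branch increments are isotropic Gaussian (variance ``bm_rate`` x
    branch length per coordinate), projected onto the tangent space so
    that no spurious translation/scale/rotation accumulates.  Tips get
    additional i.i.d. digitization noise of sd ``noise_sd`` on raw
    coordinates.

    Returns the tip configurations and a mapping of every node (internal
    nodes labelled in place) to its true noise-free k x 2 shape.
    """
    from .ancestral import label_internal_nodes

    rng = np.random.default_rng(seed)
    ref = template.coords
    k = ref.shape[0]
    sim_basis = _similarity_basis(ref.reshape(-1))

    def tangent_noise(scale: float) -> np.ndarray:
        z = rng.normal(0.0, scale, size=2 * k)
        return z - sim_basis.T @ (sim_basis @ z)

    label_internal_nodes(tree)
    deviations: dict[int, np.ndarray] = {id(tree.root): np.zeros(2 * k)}
    true_shapes: dict[str, np.ndarray] = {}
    configs: list[LandmarkConfiguration] = []
    for node in tree.preorder():
        if node is not tree.root:
            t = node.length if node.length is not None else 1.0
            step = tangent_noise(np.sqrt(bm_rate * t)) if bm_rate * t > 0 else 0.0
            deviations[id(node)] = deviations[id(node.parent)] + step
        shape = ref + deviations[id(node)].reshape(k, 2)
        name = node.name or "root"
        true_shapes[name] = shape
        if node.is_leaf:
            observed = shape + rng.normal(0.0, noise_sd, size=(k, 2))
            configs.append(LandmarkConfiguration(name, observed))
    return configs, true_shapes


def simulate_mk_characters(tree: PhyloTree, n_characters: int,
                           n_states: int = 3, rate: float = 0.3,
                           missing_fraction: float = 0.0,
                           seed: int | None = None) -> CharacterMatrix:
    """Symmetric Mk characters on a tree (root state uniform; transition
    probability from the Jukes-Cantor-type closed form)."""
    if n_states < 2 or n_states > 10:
        raise ValueError("n_states must be in 2..10 (single-digit symbols)")
    rng = np.random.default_rng(seed)
    s = n_states
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.integers(0, s, size=n_characters)}
    tip_states: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is not tree.root:
            t = node.length if node.length is not None else 1.0
            p_same = 1.0 / s + (1.0 - 1.0 / s) * np.exp(-rate * t * s / (s - 1))
            parent = states[id(node.parent)]
            change = rng.random(n_characters) >= p_same
            shift = rng.integers(1, s, size=n_characters)
            states[id(node)] = np.where(change, (parent + shift) % s, parent)
        if node.is_leaf:
            tip_states[node.name] = states[id(node)]
    taxa = tree.leaf_names()
    m = np.array([tip_states[t] for t in taxa], dtype=np.int8)
    if missing_fraction > 0:
        mask = rng.random(m.shape) < missing_fraction
        # never blank out a whole character
        keep = np.argmax(~mask, axis=0)
        mask[keep, np.arange(m.shape[1])] &= False
        m = np.where(mask, MISSING, m).astype(np.int8)
    return CharacterMatrix(taxa, m)


@dataclass
class SyntheticBundle:
    """One complete simulated study data set."""

    config: SimulationConfig
    tree: PhyloTree
    configurations: list[LandmarkConfiguration]
    matrix: CharacterMatrix
    groups: dict[str, str]
    true_shapes: dict[str, np.ndarray] = field(repr=False)


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Simulate tree, shapes and characters from one seeded config.

    Sub-stage seeds are fanned out from ``config.seed`` so each component
    is independently reproducible.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2 ** 31)
    tree = simulate_tree(config.n_taxa, config.birth_rate, int(seeds[0]))
    template = wing_template(config.n_landmarks)
    configs, true_shapes = simulate_bm_landmarks(
        tree, template, config.bm_rate, config.noise_sd, int(seeds[1]))
    matrix = simulate_mk_characters(
        tree, config.n_characters, config.n_states, config.char_rate,
        config.missing_fraction, int(seeds[2]))
    groups = assign_groups(tree, config.n_groups)
    for cfg in configs:
        cfg.group = groups[cfg.label]
    return SyntheticBundle(config, tree, configs, matrix, groups, true_shapes)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as TPS + grouping CSV + character TSV + Newick +
    true node-shape CSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "landmarks": outdir / "landmarks.tps",
        "groups": outdir / "groups.csv",
        "characters": outdir / "characters.tsv",
        "tree": outdir / "true_tree.nwk",
        "true_shapes": outdir / "true_node_shapes.csv",
    }
    records = [TpsRecord(c.k, c.coords, specimen_id=c.label)
               for c in bundle.configurations]
    write_tps(records, paths["landmarks"])
    write_groups(bundle.groups, paths["groups"])
    write_character_matrix(bundle.matrix, paths["characters"])
    write_newick(bundle.tree, paths["tree"])
    with open(paths["true_shapes"], "w") as fh:
        k = bundle.config.n_landmarks
        header = ",".join(f"x{i + 1},y{i + 1}" for i in range(k))
        fh.write(f"node,{header}\n")
        for name, shape in bundle.true_shapes.items():
            flat = ",".join(f"{v:.8f}" for v in shape.reshape(-1))
            fh.write(f"{name},{flat}\n")
    return paths
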