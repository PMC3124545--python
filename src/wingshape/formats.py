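"""Readers and writers for every external representation the pipeline touches.

Formats covered:

* **TPS** landmark files (the tpsDig dialect: ``LM=``, coordinate pairs,
  ``IMAGE=``, ``ID=``, ``SCALE=``).  Curves/outlines are not supported and
  raise — the analyses here are landmark-only.
* **Character matrices** as TSV (``taxon<TAB>statestring``) or NEXUS
  (standard data, via dendropy).  States are single digits 0-9 or ``?``.
* **Newick** trees (parsed by dendropy, serialized by
  :meth:`~wingshape.trees.PhyloTree.to_newick`).
* **PHYLIP square** distance matrices.
* A **grouping table** (CSV with ``specimen_id,group`` columns).

Every reader/writer pair round-trips at the stated precision, and parsers
never silently drop records.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .trees import PhyloTree, TreeNode

logger = logging.getLogger(__name__)

MISSING = -1  # internal code for '?'


class ParseError(ValueError):
    """Raised when an input file violates its format."""


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------

@dataclass
class TpsRecord:
    """One digitized specimen: landmark count, coordinates and metadata.

    ``scale``, when set, means the stored coordinates are raw image units
    and should be multiplied by it to obtain physical units.
    """

    n_landmarks: int
    coords: np.ndarray  # (k, 2)
    image_name: str = ""
    specimen_id: str = ""
    scale: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.n_landmarks, 2):
            raise ParseError(
                f"record {self.specimen_id!r}: {self.coords.shape[0]} coordinate "
                f"pairs but LM={self.n_landmarks}")
        if not np.all(np.isfinite(self.coords)):
            raise ParseError(f"record {self.specimen_id!r}: non-finite coordinate")


def read_tps(path: str | Path, apply_scale: bool = True) -> list[TpsRecord]:
    """Parse a TPS landmark file into one record per ``LM=`` block.

    With ``apply_scale`` (default) coordinates are multiplied by any
    ``SCALE=`` factor and the factor is consumed; pass ``False`` to keep
    raw image units with the factor recorded on the record.
    """
    lines = Path(path).read_text().splitlines()
    records: list[TpsRecord] = []
    i, block = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ParseError(f"line {i + 1}: expected 'LM=' block header, got {line!r}")
        block += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise ParseError(f"block {block}, line {i + 1}: bad landmark count {line!r}")
        i += 1
        coords = []
        for j in range(k):
            if i >= len(lines) or "=" in lines[i]:
                raise ParseError(
                    f"block {block}: LM={k} declared but only {j} coordinate lines found")
            parts = lines[i].split()
            if len(parts) != 2:
                raise ParseError(
                    f"block {block}, line {i + 1}: expected 'x y', got {lines[i]!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise ParseError(
                    f"block {block}, line {i + 1}: non-numeric coordinate {lines[i]!r}")
            i += 1
        image, spec_id, scale = "", "", None
        while i < len(lines) and lines[i].strip() and not lines[i].strip().upper().startswith("LM="):
            meta = lines[i].strip()
            key, _, value = meta.partition("=")
            key = key.strip().upper()
            if key == "IMAGE":
                image = value.strip()
            elif key == "ID":
                spec_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            elif key in ("CURVES", "POINTS", "OUTLINES"):
                raise ParseError(
                    f"block {block}: outline/curve data ({key}=) is not supported")
            else:
                raise ParseError(f"block {block}, line {i + 1}: unknown key {key!r}")
            i += 1
        arr = np.asarray(coords)
        if apply_scale and scale is not None:
            arr = arr * scale
            scale = None
        records.append(TpsRecord(k, arr, image, spec_id, scale))
    logger.info("read_tps: %d records from %s", len(records), path)
    return records


def write_tps(records: list[TpsRecord], path: str | Path, decimals: int = 6) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"LM={rec.n_landmarks}\n")
            for x, y in rec.coords:
                fh.write(f"{x:.{decimals}f} {y:.{decimals}f}\n")
            if rec.image_name:
                fh.write(f"IMAGE={rec.image_name}\n")
            if rec.specimen_id:
                fh.write(f"ID={rec.specimen_id}\n")
            if rec.scale is not None:
                fh.write(f"SCALE={rec.scale:.{decimals}f}\n")


# ---------------------------------------------------------------------------
# Character matrices
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Taxa x characters discrete matrix, states 0-9 with '?' missing.

    ``states`` holds small ints with :data:`MISSING` (-1) for '?'.
    ``character_ids`` preserves the original character numbering so that
    anatomical sub-matrices (e.g. thorax characters 61-79) can be selected
    after other characters have been dropped.
    """

    taxa: list[str]
    states: np.ndarray  # (n_taxa, n_characters) int8
    character_ids: list[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.character_ids is None:
            self.character_ids = list(range(self.states.shape[1]))
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ParseError(f"duplicate taxon labels: {dupes}")
        if len(self.taxa) < 3:
            raise ValueError("a character matrix needs at least 3 taxa")
        if self.states.shape != (len(self.taxa), len(self.character_ids)):
            raise ValueError("states shape inconsistent with taxa/character ids")
        all_missing = np.all(self.states == MISSING, axis=0)
        if np.any(all_missing):
            bad = [self.character_ids[i] for i in np.flatnonzero(all_missing)]
            raise ValueError(f"characters with no scored taxa: {bad}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.states == MISSING

    def subset(self, character_ids) -> "CharacterMatrix":
        """Sub-matrix restricted to the given original character ids."""
        wanted = set(character_ids)
        cols = [i for i, cid in enumerate(self.character_ids) if cid in wanted]
        if not cols:
            raise ValueError("character subset is empty")
        return CharacterMatrix(list(self.taxa), self.states[:, cols],
                               [self.character_ids[i] for i in cols])

    def exclude(self, character_ids) -> "CharacterMatrix":
        banned = set(character_ids)
        keep = [cid for cid in self.character_ids if cid not in banned]
        return self.subset(keep)


_STATE_CHARS = set("0123456789?")


def _parse_state_string(s: str, row_label: str) -> list[int]:
    out = []
    for ch in s:
        if ch not in _STATE_CHARS:
            raise ParseError(
                f"row {row_label!r}: state symbol {ch!r} not in 0-9/'?' "
                "(polymorphic '(..)' codings are not supported)")
        out.append(MISSING if ch == "?" else int(ch))
    return out


def read_character_matrix(path: str | Path, format: str | None = None) -> CharacterMatrix:
    """Read a discrete character matrix from TSV or NEXUS.

    TSV rows are ``taxon<TAB>statestring`` (e.g. ``Copris_sp\\t010?2``).
    The format is inferred from the extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus") else "tsv"
    if format == "nexus":
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        taxa = [t.label for t in dmat.taxon_namespace]
        rows = []
        for t in dmat.taxon_namespace:
            symbols = "".join(str(c.symbol) for c in dmat[t])
            rows.append(_parse_state_string(symbols, t.label))
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ParseError(f"ragged NEXUS matrix: row lengths {sorted(widths)}")
        return CharacterMatrix(taxa, np.array(rows, dtype=np.int8))
    if format != "tsv":
        raise ValueError(f"unknown character matrix format {format!r}")
    taxa, rows = [], []
    width = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ParseError(f"line {ln}: expected 'taxon<TAB>states', got {line!r}")
        taxon, states = parts
        row = _parse_state_string(states.strip(), taxon)
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ParseError(
                f"ragged matrix: row {taxon!r} has {len(row)} characters, expected {width}")
        taxa.append(taxon)
        rows.append(row)
    logger.info("read_character_matrix: %d taxa x %d characters from %s",
                len(taxa), width or 0, path)
    return CharacterMatrix(taxa, np.array(rows, dtype=np.int8))


def write_character_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(matrix.taxa, matrix.states):
            s = "".join("?" if v == MISSING else str(v) for v in row)
            fh.write(f"{taxon}\t{s}\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick string (or path to one) into a :class:`PhyloTree`.

    Internal-node labels that parse as numbers are also exposed as support
    values.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and not source.strip().startswith("(")
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        node = TreeNode(label, dnode.edge.length)
        if label is not None and dnode.child_nodes():
            try:
                node.support = float(label)
            except ValueError:
                pass
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def write_newick(tree: PhyloTree, path: str | Path | None = None,
                 decimals: int = 6) -> str:
    text = tree.to_newick(decimals=decimals)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------

def read_distance_matrix(path: str | Path, atol: float = 1e-6) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (count line, then label + row)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError("first line must be the taxon count")
    if len(lines) != n + 1:
        raise ParseError(f"expected {n} matrix rows, found {len(lines) - 1}")
    labels, values = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ParseError(
                f"row {parts[0]!r}: expected {n} values, found {len(parts) - 1}")
        labels.append(parts[0])
        values.append([float(v) for v in parts[1:]])
    m = np.array(values)
    asym = np.abs(m - m.T)
    if asym.max() > atol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ParseError(
            f"matrix asymmetric: worst cell ({labels[i]}, {labels[j]}) "
            f"|{m[i, j]:g} - {m[j, i]:g}| = {asym[i, j]:g} > {atol:g}")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(m, ids=labels)


def write_distance_matrix(d: DistanceMatrix, path: str | Path,
                          decimals: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(f"{d.shape[0]}\n")
        for label, row in zip(d.ids, d.data):
            vals = " ".join(f"{v:.{decimals}f}" for v in row)
            fh.write(f"{label} {vals}\n")


# ---------------------------------------------------------------------------
# Grouping table
# ---------------------------------------------------------------------------

def read_groups(path: str | Path) -> dict[str, str]:
    """CSV with ``specimen_id,group`` columns -> specimen-to-group mapping."""
    df = pd.read_csv(path, dtype=str)
    missing = {"specimen_id", "group"} - set(df.columns)
    if missing:
        raise ParseError(f"grouping table missing columns: {sorted(missing)}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ParseError(f"duplicate specimen ids in grouping table: {dupes}")
    return dict(zip(df["specimen_id"], df["group"]))


def write_groups(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"specimen_id": list(groups), "group": list(groups.values())}
                 ).to_csv(path, index=False)
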