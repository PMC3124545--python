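"""Generalized least-squares Procrustes superimposition of 2-D landmarks.

Each specimen is a configuration of k landmarks.  Alignment removes the
nuisance similarity parameters — translation (centering), scale (unit
centroid size) and rotation (closed-form 2-D least-squares rotation,
reflections excluded) — leaving only shape.  The iterative GPA alternates
aligning all specimens to the current consensus with re-estimating the
consensus as their normalized mean, until the consensus stops moving.

Distances between shapes are *partial* Procrustes distances: the root
summed squared difference after centering, unit-size scaling and optimal
proper rotation.  For small shape variation these are nearly identical to
distances in the linear tangent space at the consensus; the adequacy check
quantifies that agreement (near-1 correlation means ordinary multivariate
statistics in tangent space are safe).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats import TpsRecord

logger = logging.getLogger(__name__)


class DegenerateConfigurationError(ValueError):
    """All landmarks coincident (zero centroid size)."""


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 2 landmark coordinates."""

    label: str
    coords: np.ndarray
    group: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"{self.label}: coords must be k x 2")
        if self.coords.shape[0] < 3:
            raise ValueError(f"{self.label}: need at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.label}: non-finite coordinates")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid_size(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c ** 2).sum()))

    def flat(self) -> np.ndarray:
        """Row-major 2k vector (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(-1)


def configs_from_tps(records: list[TpsRecord],
                     groups: dict[str, str] | None = None) -> list[LandmarkConfiguration]:
    """Turn parsed TPS records into configurations, attaching group labels."""
    out = []
    for i, rec in enumerate(records):
        label = rec.specimen_id or rec.image_name or f"specimen_{i + 1}"
        group = (groups or {}).get(label, "")
        out.append(LandmarkConfiguration(label, rec.coords, group))
    return out


@dataclass
class AlignedShapeSet:
    """Result of a GPA run: consensus plus aligned specimens."""

    consensus: np.ndarray                  # (k, 2), centered, unit size
    aligned: list[LandmarkConfiguration]   # centered, unit size, rotated
    centroid_sizes: np.ndarray             # original sizes, one per specimen
    iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    @property
    def n(self) -> int:
        return len(self.aligned)


@dataclass
class TangentCheckResult:
    """Tangent-space vs shape-space distance agreement."""

    correlation_through_origin: float
    slope: float
    pearson_correlation: float
    n_pairs: int


def center_and_scale(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Remove location and scale: centroid at origin, centroid size 1."""
    c = config.coords - config.coords.mean(axis=0)
    size = np.sqrt((c ** 2).sum())
    if size < 1e-12:
        raise DegenerateConfigurationError(
            f"{config.label}: all landmarks coincident")
    return LandmarkConfiguration(config.label, c / size, config.group)


def optimal_rotation(target: LandmarkConfiguration | np.ndarray,
                     reference: LandmarkConfiguration | np.ndarray
                     ) -> tuple[float, np.ndarray]:
    """Proper rotation of ``target`` minimizing summed squared distance to
    ``reference``; both must already be centered (and normally scaled).

    Returns ``(angle, rotated_coords)``.  Reflections are never applied
    (determinant +1 only).  If the cross-covariance is numerically zero the
    rotation is undefined; identity is returned with a warning.
    """
    t = target.coords if isinstance(target, LandmarkConfiguration) else np.asarray(target)
    r = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference)
    if t.shape != r.shape:
        raise ValueError(f"landmark count mismatch: {t.shape[0]} vs {r.shape[0]}")
    # 2-D closed form: maximize trace of R(theta) @ t.T @ r
    num = float(t[:, 0] @ r[:, 1] - t[:, 1] @ r[:, 0])
    den = float((t * r).sum())
    if abs(num) < 1e-300 and abs(den) < 1e-300:
        warnings.warn("singular cross-covariance; returning identity rotation")
        return 0.0, t.copy()
    angle = np.arctan2(num, den)
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    return angle, t @ rot.T


def _normalize(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return c / np.sqrt((c ** 2).sum())


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Rotation (det +1) putting the shape's principal axis on x.

    Makes GPA output orientation independent of input ordering.  The sign
    ambiguity (rotation by pi) is fixed by the third moment of the x
    coordinates, falling back to the y third moment, then to the first
    landmark's position.
    """
    cov = coords.T @ coords
    theta = 0.5 * np.arctan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1])
    ca, sa = np.cos(-theta), np.sin(-theta)
    rot = np.array([[ca, -sa], [sa, ca]])
    out = coords @ rot.T
    for moment in ((out[:, 0] ** 3).sum(), (out[:, 1] ** 3).sum(),
                   out[0, 0], out[0, 1]):
        if abs(moment) > 1e-9:
            if moment < 0:
                out = -out  # rotation by pi, still det +1
            break
    return out


def gpa_align(configs: list[LandmarkConfiguration], tol: float = 1e-10,
              max_iter: int = 100) -> AlignedShapeSet:
    """Iterative GLS Procrustes alignment of two or more configurations."""
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValueError(f"landmark counts differ: {sorted(ks)}")
    sizes = np.array([c.centroid_size for c in configs])
    scaled = [center_and_scale(c) for c in configs]
    # order-independent start: plain normalized mean of the scaled inputs
    consensus = _canonical_orientation(_normalize(
        np.mean([c.coords for c in scaled], axis=0)))
    aligned = [c.coords for c in scaled]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = [optimal_rotation(a, consensus)[1] for a in aligned]
        new_consensus = _normalize(np.mean(aligned, axis=0))
        _, new_consensus = optimal_rotation(new_consensus, consensus)
        shift = procrustes_distance_coords(consensus, new_consensus)
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations")
    consensus = _canonical_orientation(consensus)
    aligned = [optimal_rotation(a, consensus)[1] for a in aligned]
    out = [LandmarkConfiguration(c.label, a, c.group)
           for c, a in zip(configs, aligned)]
    logger.info("gpa_align: %d specimens, %d iterations, converged=%s",
                len(configs), iterations, converged)
    return AlignedShapeSet(consensus, out, sizes, iterations, converged)


def procrustes_distance_coords(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two centered, unit-size k x 2
    arrays (no further centering/scaling applied)."""
    _, rotated = optimal_rotation(a, b)
    return float(np.sqrt(((rotated - b) ** 2).sum()))


def procrustes_distance(a: LandmarkConfiguration,
                        b: LandmarkConfiguration) -> float:
    """Partial Procrustes distance: root summed squared difference after
    centering, unit-size scaling and optimal proper rotation."""
    if a.k != b.k:
        raise ValueError("landmark count mismatch")
    return procrustes_distance_coords(center_and_scale(a).coords,
                                      center_and_scale(b).coords)


def procrustes_distance_matrix(aligned: AlignedShapeSet) -> np.ndarray:
    n = aligned.n
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = procrustes_distance_coords(
                aligned.aligned[i].coords, aligned.aligned[j].coords)
    return d


def tangent_project(aligned: AlignedShapeSet) -> np.ndarray:
    """Orthogonal projection of each aligned specimen onto the tangent
    space at the consensus.

    Returns an n x 2k matrix of tangent coordinates; the consensus itself
    maps to the zero vector.  Aligned specimens are unit vectors in R^2k,
    so the projection is ``x - (x . c) c`` with c the (unit) consensus.
    """
    c = aligned.consensus.reshape(-1)
    rows = []
    for spec in aligned.aligned:
        x = spec.flat()
        rows.append(x - (x @ c) * c)
    return np.array(rows)


def tangent_coords_at(consensus: np.ndarray,
                      configs: list[LandmarkConfiguration]) -> np.ndarray:
    """Tangent coordinates of arbitrary configurations at a given consensus
    (each is centered, scaled, rotated onto the consensus, then projected)."""
    c = consensus.reshape(-1)
    rows = []
    for cfg in configs:
        _, rotated = optimal_rotation(center_and_scale(cfg).coords, consensus)
        x = rotated.reshape(-1)
        rows.append(x - (x @ c) * c)
    return np.array(rows)


def tangent_adequacy_check(aligned: AlignedShapeSet) -> TangentCheckResult:
    """Regress pairwise tangent-space distance on Procrustes distance
    through the origin; near-1 correlation validates tangent-space
    statistics for the data at hand."""
    if aligned.n < 3:
        raise ValueError("adequacy check needs at least 3 specimens")
    tangent = tangent_project(aligned)
    n = aligned.n
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            xs.append(procrustes_distance_coords(
                aligned.aligned[i].coords, aligned.aligned[j].coords))
            ys.append(float(np.linalg.norm(tangent[i] - tangent[j])))
    x, y = np.array(xs), np.array(ys)
    sxx, syy, sxy = float(x @ x), float(y @ y), float(x @ y)
    if sxx < 1e-30 or syy < 1e-30:
        raise ValueError("all shapes identical: correlation undefined")
    r_origin = sxy / np.sqrt(sxx * syy)
    slope = sxy / sxx
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    pearson = float(xc @ yc / denom) if denom > 1e-30 else float("nan")
    return TangentCheckResult(float(r_origin), float(slope), pearson, len(x))
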