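"""Thin-plate spline decomposition of shape variation.

The bending-energy matrix of the consensus configuration supplies the
principal-warp eigenbasis; projecting each specimen's tangent-space
deviation onto that basis (plus a 2-D uniform/affine component) yields the
partial-warp score matrix.  Relative warps are the principal components of
those scores.  With the default exponent ``alpha = 0`` and the uniform
component included, the score space is an orthonormal rotation of tangent
space, so variance is conserved exactly and relative warps coincide with an
ordinary PCA of tangent coordinates.

The same spline machinery drives deformation-grid rendering: the
interpolating TPS maps the consensus landmarks exactly onto a target
configuration and is evaluated over a rectangular grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superimposition import AlignedShapeSet


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r2 * np.log(r2)
    return np.where(r2 > 0, u, 0.0)


def _kernel_matrix(pts_a: np.ndarray, pts_b: np.ndarray) -> np.ndarray:
    diff = pts_a[:, None, :] - pts_b[None, :, :]
    return _tps_kernel((diff ** 2).sum(axis=2))


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """k x k bending-energy matrix of a reference configuration.

    Symmetric positive semi-definite with a 3-dimensional null space (the
    affine transformations, which bend nothing).
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    if k < 4:
        raise ValueError("bending energy needs at least 4 landmarks")
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    off = d2[~np.eye(k, dtype=bool)]
    if off.min() < 1e-20:
        raise ValueError("coincident landmarks in reference: singular TPS kernel")
    K = _tps_kernel(d2)
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    L_inv = np.linalg.inv(L)
    be = L_inv[:k, :k]
    return (be + be.T) / 2.0


def principal_warps(reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the bending-energy matrix.

    Returns ``(eigenvalues, eigenvectors)`` with the 3 affine (zero)
    eigenvalues first, then ascending bending energy; eigenvectors are
    columns, orthonormal in R^k.
    """
    be = bending_energy_matrix(reference)
    evals, evecs = np.linalg.eigh(be)
    evals = np.clip(evals, 0.0, None)
    return evals, evecs


def _similarity_basis(consensus_flat: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4 x 2k) of the similarity directions at a
    centered unit-size consensus: x/y translation, scale, rotation."""
    k = consensus_flat.size // 2
    c = consensus_flat
    tx = np.zeros_like(c)
    tx[0::2] = 1.0
    ty = np.zeros_like(c)
    ty[1::2] = 1.0
    rot = np.empty_like(c)
    rot[0::2] = -c[1::2]
    rot[1::2] = c[0::2]
    basis = np.vstack([tx, ty, c, rot]).astype(float)
    q, _ = np.linalg.qr(basis.T)
    return q.T


def uniform_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal 2 x 2k basis of the uniform (affine, non-similarity)
    shape subspace at the consensus, computed by the complement method:
    affine deformation generators with the similarity directions projected
    out."""
    ref = np.asarray(consensus, dtype=float)
    k = ref.shape[0]
    gens = []
    for a, b, c, d in ((1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)):
        A = np.array([[a, b], [c, d]], dtype=float)
        gens.append((ref @ A.T).reshape(-1))
    G = np.array(gens)
    sim = _similarity_basis(ref.reshape(-1))
    G = G - (G @ sim.T) @ sim
    u, s, vt = np.linalg.svd(G, full_matrices=False)
    basis = vt[s > 1e-10 * s.max()]
    if basis.shape[0] != 2:
        raise ValueError(
            f"uniform subspace has dimension {basis.shape[0]}, expected 2 "
            "(degenerate consensus?)")
    return basis


@dataclass
class PartialWarpScores:
    """Specimen scores on the principal-warp (+ uniform) basis."""

    scores: np.ndarray          # (n, 2*(k-3) [+2])
    eigenvalues: np.ndarray     # (k-3,) nonzero bending energies, ascending
    warp_basis: np.ndarray      # (k-3, k) eigenvectors (rows)
    uniform: np.ndarray | None  # (2, 2k) or None
    alpha: float
    include_uniform: bool


def partial_warp_scores(aligned: AlignedShapeSet, alpha: float = 0.0,
                        include_uniform: bool = True) -> PartialWarpScores:
    """Project tangent-space deviations onto principal warps.

    Each nonzero-eigenvalue warp contributes an (x, y) score pair, scaled
    by ``eigenvalue**(-alpha/2)``; with ``include_uniform`` the 2-D affine
    component is appended.  The consensus scores zero on every column.
    """
    from .superimposition import tangent_project

    evals, evecs = principal_warps(aligned.consensus)
    nonaffine = evals > 1e-8 * max(evals.max(), 1.0)
    w_evals = evals[nonaffine]
    W = evecs[:, nonaffine]                       # (k, k-3)
    weights = w_evals ** (-alpha / 2.0) if alpha != 0 else np.ones_like(w_evals)

    tangent = tangent_project(aligned)            # (n, 2k)
    n, two_k = tangent.shape
    k = two_k // 2
    dx = tangent.reshape(n, k, 2)[:, :, 0]
    dy = tangent.reshape(n, k, 2)[:, :, 1]
    sx = (dx @ W) * weights                       # (n, k-3)
    sy = (dy @ W) * weights
    cols = np.empty((n, 2 * W.shape[1]))
    cols[:, 0::2] = sx
    cols[:, 1::2] = sy
    ub = None
    if include_uniform:
        ub = uniform_basis(aligned.consensus)
        cols = np.hstack([cols, tangent @ ub.T])
    return PartialWarpScores(cols, w_evals, W.T, ub, alpha, include_uniform)


@dataclass
class RelativeWarpResult:
    """SVD of the centered partial-warp score matrix."""

    scores: np.ndarray            # (n, m) specimen scores on relative warps
    singular_values: np.ndarray   # (m,) descending
    variance_fraction: np.ndarray  # (m,) sums to 1
    axes: np.ndarray              # (m, n_cols) loading vectors (rows)
    alpha: float
    include_uniform: bool


def relative_warps(pw: PartialWarpScores) -> RelativeWarpResult:
    """Relative warps: principal axes of the partial-warp scores."""
    X = pw.scores
    if X.shape[0] < 3:
        raise ValueError("relative warps need at least 3 specimens")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s ** 2).sum()
    if total < 1e-30:
        raise ValueError("no shape variation: relative warps undefined")
    return RelativeWarpResult(u * s, s, s ** 2 / total, vt,
                              pw.alpha, pw.include_uniform)


class ThinPlateSpline:
    """Interpolating 2-D TPS mapping reference landmarks onto targets."""

    def __init__(self, reference: np.ndarray, target: np.ndarray):
        ref = np.asarray(reference, dtype=float)
        tgt = np.asarray(target, dtype=float)
        if ref.shape != tgt.shape:
            raise ValueError("reference/target landmark counts differ")
        k = ref.shape[0]
        d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
        if d2[~np.eye(k, dtype=bool)].min() < 1e-20:
            raise ValueError("coincident reference landmarks")
        K = _tps_kernel(d2)
        Q = np.column_stack([np.ones(k), ref])
        L = np.zeros((k + 3, k + 3))
        L[:k, :k] = K
        L[:k, k:] = Q
        L[k:, :k] = Q.T
        rhs = np.zeros((k + 3, 2))
        rhs[:k] = tgt
        sol = np.linalg.solve(L, rhs)
        self.reference = ref
        self.w = sol[:k]        # (k, 2) kernel weights
        self.a = sol[k:]        # (3, 2) affine part

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        U = _kernel_matrix(pts, self.reference)
        P = np.column_stack([np.ones(len(pts)), pts])
        return U @ self.w + P @ self.a


def tps_deformation_grid(reference: np.ndarray, target: np.ndarray,
                         resolution: int = 20, margin: float = 0.1
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the interpolating spline on a rectangular grid spanning the
    reference (plus a relative margin).  Returns ``(grid, warped_grid)``,
    both (resolution^2, 2) arrays, for rendering deformation plots."""
    ref = np.asarray(reference, dtype=float)
    spline = ThinPlateSpline(ref, target)
    lo, hi = ref.min(axis=0), ref.max(axis=0)
    pad = margin * (hi - lo).max()
    xs = np.linspace(lo[0] - pad, hi[0] + pad, resolution)
    ys = np.linspace(lo[1] - pad, hi[1] + pad, resolution)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    return grid, spline.transform(grid)
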