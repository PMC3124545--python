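"""Per-group shape disparity: mean shapes, metric disparity, bootstrap SEs.

Metric disparity of a group is MD = sum_i d_i^2 / (N - 1), where d_i is
specimen i's distance from the group mean measured in the partial-warp /
tangent space referenced to the grand (total) mean.  Because that score
space is an orthonormal rotation of tangent space, MD computed from scores
equals MD computed directly from tangent coordinates.

Standard errors come from bootstrap resampling of group members, with the
group mean re-estimated inside every pseudoreplicate so that the SE
reflects mean uncertainty as well as spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superimposition import (AlignedShapeSet, LandmarkConfiguration,
                              center_and_scale, gpa_align, tangent_coords_at)


@dataclass
class DisparityResult:
    group: str
    n: int
    md: float
    se: float
    n_boot: int
    seed: int | None = None
    defined: bool = True  # False for singleton groups (MD undefined)


def group_mean_shape(members: list[LandmarkConfiguration]) -> LandmarkConfiguration:
    """GPA consensus of the group's members (unit centroid size)."""
    if not members:
        raise ValueError("empty group")
    if len(members) == 1:
        norm = center_and_scale(members[0])
        return LandmarkConfiguration("mean", norm.coords, members[0].group)
    aligned = gpa_align(members)
    return LandmarkConfiguration("mean", aligned.consensus, members[0].group)


def _md_from_rows(rows: np.ndarray) -> float:
    mean = rows.mean(axis=0)
    return float(((rows - mean) ** 2).sum() / (len(rows) - 1))


def metric_disparity(members: list[LandmarkConfiguration],
                     total_mean: np.ndarray | LandmarkConfiguration) -> float:
    """MD = sum of squared deviations from the group mean / (N - 1),
    measured in tangent space at the total (grand) mean."""
    if len(members) < 2:
        raise ValueError("metric disparity undefined for fewer than 2 members")
    consensus = (total_mean.coords if isinstance(total_mean, LandmarkConfiguration)
                 else np.asarray(total_mean))
    rows = tangent_coords_at(consensus, members)
    return _md_from_rows(rows)


def metric_disparity_from_tangent(rows: np.ndarray) -> float:
    """Same statistic, straight from precomputed tangent coordinates."""
    if len(rows) < 2:
        raise ValueError("metric disparity undefined for fewer than 2 members")
    return _md_from_rows(np.asarray(rows, dtype=float))


def bootstrap_disparity_se(members: list[LandmarkConfiguration],
                           total_mean: np.ndarray | LandmarkConfiguration,
                           n_boot: int = 10000, seed: int | None = None,
                           group: str = "") -> DisparityResult:
    """Bootstrap standard error of MD (members resampled with replacement,
    group mean recomputed per replicate).  Deterministic under ``seed``."""
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if len(members) == 1:
        return DisparityResult(group or members[0].group, 1, 0.0, 0.0,
                               n_boot, seed, defined=False)
    consensus = (total_mean.coords if isinstance(total_mean, LandmarkConfiguration)
                 else np.asarray(total_mean))
    rows = tangent_coords_at(consensus, members)
    md = _md_from_rows(rows)
    rng = np.random.default_rng(seed)
    n = len(rows)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _md_from_rows(rows[idx])
    se = float(boots.std(ddof=1))
    return DisparityResult(group or members[0].group, n, md, se, n_boot, seed)


def disparity_table(aligned: AlignedShapeSet, n_boot: int = 10000,
                    seed: int | None = None) -> list[DisparityResult]:
    """Per-group disparity from a globally aligned data set, grouped by the
    configurations' ``group`` labels."""
    from .superimposition import tangent_project

    rows = tangent_project(aligned)
    groups: dict[str, list[int]] = {}
    for i, cfg in enumerate(aligned.aligned):
        groups.setdefault(cfg.group or "all", []).append(i)
    rng = np.random.default_rng(seed)
    out = []
    for gi, (name, idx) in enumerate(sorted(groups.items())):
        sub = rows[idx]
        if len(sub) == 1:
            out.append(DisparityResult(name, 1, 0.0, 0.0, n_boot, seed, defined=False))
            continue
        md = _md_from_rows(sub)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = _md_from_rows(sub[rng.integers(0, len(sub), size=len(sub))])
        out.append(DisparityResult(name, len(sub), md, float(boots.std(ddof=1)),
                                   n_boot, seed))
    return out
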