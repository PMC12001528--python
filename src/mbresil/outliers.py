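"""Bagplot outlier detection on the (FPCA1, FPCA2) score plane.

The bagplot is the bivariate generalisation of the boxplot, built on Tukey's
halfspace depth: the depth of a point p relative to a cloud is the smallest
number of cloud points contained in any closed halfplane whose boundary line
passes through p.  Deep points are central; hull points have low depth.

The construction used here:

* ``depth median`` — centroid of the maximal-depth points;
* ``bag``          — convex hull of the ceil(n/2) deepest points (depth ties
  at the cutoff are included, broken by distance to the depth median);
* ``fence``        — the bag inflated by a factor of 3 about the depth
  median (the conventional bagplot constant);
* points strictly outside the fence are flagged as outliers.

Depth is computed exactly by an angular sweep: the count of points in the
closed halfplane with inward normal u changes only when u crosses a direction
perpendicular to some cloud point, so it suffices to evaluate the count at
one direction per angular interval between consecutive critical directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = ["BagplotError", "Bagplot", "halfspace_depth", "bagplot_fit", "flag_outlier_trajectories"]


class BagplotError(ValueError):
    """Invalid input to the bagplot routines."""


def halfspace_depth(p, cloud) -> int:
    """Exact Tukey halfspace depth of point ``p`` in a 2-D ``cloud``.

    Returns the minimum, over all closed halfplanes with ``p`` on the
    boundary, of the number of cloud points inside the halfplane (an integer
    in ``[0, n]``).  Points coincident with ``p`` lie on every boundary and
    always count.
    """
    p = np.asarray(p, dtype=float)
    pts = np.asarray(cloud, dtype=float)
    if p.shape != (2,) or pts.ndim != 2 or pts.shape[1] != 2:
        raise BagplotError("halfspace_depth expects a 2-vector and an n×2 cloud")
    if pts.shape[0] < 1:
        raise BagplotError("cloud must contain at least one point")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(pts))):
        raise BagplotError("non-finite coordinates")
    q = pts - p
    norms = np.hypot(q[:, 0], q[:, 1])
    scale = norms.max()
    if scale == 0:
        return pts.shape[0]
    coincident = norms <= 1e-12 * scale
    k = int(coincident.sum())
    r = q[~coincident]
    ang = np.arctan2(r[:, 1], r[:, 0])
    crit = np.unique(np.concatenate([ang + np.pi / 2, ang - np.pi / 2]) % (2 * np.pi))
    # evaluate the closed-halfplane count once per open interval between
    # consecutive critical directions (the count is constant there and the
    # minimum is attained on such an interval)
    mids = (crit + np.roll(crit, -1)) / 2.0
    mids[-1] = (crit[-1] + crit[0] + 2 * np.pi) / 2.0
    U = np.column_stack([np.cos(mids), np.sin(mids)])
    dots = U @ r.T
    counts = (dots >= -1e-9 * scale).sum(axis=1)
    return k + int(counts.min())


@dataclass
class Bagplot:
    """Fitted bagplot over a 2-D point cloud."""

    points: np.ndarray          # n × 2
    depths: np.ndarray          # integer Tukey depth per point
    depth_median: np.ndarray    # centroid of the deepest points
    bag_hull: np.ndarray        # bag polygon vertices (counter-clockwise)
    fence_hull: np.ndarray      # bag inflated by `fence_factor` about the median
    outlier_flags: np.ndarray   # boolean per point, True = outside the fence
    bag_indices: np.ndarray     # indices of points forming the bag set
    fence_factor: float = 3.0


def _inside_convex(polygon: np.ndarray, pts: np.ndarray, tol: float) -> np.ndarray:
    """Vectorised point-in-convex-polygon test (vertices counter-clockwise)."""
    inside = np.ones(len(pts), dtype=bool)
    m = len(polygon)
    for i in range(m):
        v0 = polygon[i]
        edge = polygon[(i + 1) % m] - v0
        rel = pts - v0
        cross = edge[0] * rel[:, 1] - edge[1] * rel[:, 0]
        inside &= cross >= -tol
    return inside


def bagplot_fit(points, fence_factor: float = 3.0, min_n: int = 10) -> Bagplot:
    """Fit a bagplot: depths, depth median, bag, fence and outlier flags.

    Requires at least ``min_n`` points in general position (not all
    collinear).  The bag is the convex hull of the ``ceil(n/2)`` deepest
    points; ties at the depth cutoff are resolved by distance to the depth
    median, with exact ties also included.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise BagplotError("bagplot_fit expects an n×2 array")
    n = pts.shape[0]
    if n < min_n:
        raise BagplotError(f"too few points for bagplot: {n} < {min_n}")
    if not np.all(np.isfinite(pts)):
        raise BagplotError("non-finite coordinates")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(centered).max())) < 2:
        raise BagplotError("degenerate 2-D configuration: points are collinear")

    depths = np.array([halfspace_depth(p, pts) for p in pts])
    deepest = depths == depths.max()
    median = pts[deepest].mean(axis=0)

    dist = np.linalg.norm(pts - median, axis=1)
    order = np.lexsort((dist, -depths))
    target = ceil(n / 2)
    cut_depth = depths[order[target - 1]]
    cut_dist = dist[order[target - 1]]
    in_bag = (depths > cut_depth) | (
        (depths == cut_depth) & (dist <= cut_dist + 1e-12 * max(1.0, cut_dist))
    )
    bag_idx = np.nonzero(in_bag)[0]
    try:
        hull = ConvexHull(pts[bag_idx])
    except QhullError as exc:
        raise BagplotError("degenerate 2-D configuration in bag points") from exc
    bag_hull = pts[bag_idx][hull.vertices]          # counter-clockwise in 2-D
    fence_hull = median + fence_factor * (bag_hull - median)

    scale = max(1.0, float(np.abs(pts).max()))
    inside_fence = _inside_convex(fence_hull, pts, tol=1e-9 * scale)
    return Bagplot(
        points=pts,
        depths=depths,
        depth_median=median,
        bag_hull=bag_hull,
        fence_hull=fence_hull,
        outlier_flags=~inside_fence,
        bag_indices=bag_idx,
        fence_factor=fence_factor,
    )


def flag_outlier_trajectories(
    scores: pd.DataFrame, fence_factor: float = 3.0, min_n: int = 10
) -> pd.DataFrame:
    """Annotate an FPCA score table with bagplot outlier flags.

    Fits a bagplot to the (FPCA1, FPCA2) columns and returns a copy of
    ``scores`` with added ``depth`` and ``outlier`` columns; a flagged row is
    a trajectory whose overall shape is atypical in the family.
    """
    for col in ("FPCA1", "FPCA2"):
        if col not in scores.columns:
            raise BagplotError(f"scores table lacks required column {col!r}")
    bag = bagplot_fit(
        scores[["FPCA1", "FPCA2"]].to_numpy(dtype=float),
        fence_factor=fence_factor,
        min_n=min_n,
    )
    out = scores.copy()
    out["depth"] = bag.depths
    out["outlier"] = bag.outlier_flags
    return out
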