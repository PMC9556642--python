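"""Movement amplitude descriptors: mean inter-distance and convex hull.

Both descriptors operate on the raw (gap-filled, unfiltered) 3D
positions visited within each 1-s analysis window: the mean Euclidean
distance between all pairs of positions (spatial dispersion, mm) and the
volume of the 3D convex hull of the window's positions (space covered,
cm^3).  Windows use the same 1-s / 50%-overlap grid as the windowed
cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .core import MarkerTrajectory
from .xcorr import slide_windows


@dataclass(frozen=True)
class SpatialSummary:
    mean_interdistance: float  # mm
    hull_volume: float  # cm^3
    window_id: tuple[int, int] = (-1, -1)


def mean_pairwise_distance(points: np.ndarray) -> float:
    """Mean Euclidean distance over all C(n,2) unordered pairs (mm)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least two points")
    return float(pdist(points).mean())


def convex_hull_volume(points: np.ndarray) -> float:
    """Volume of the 3D convex hull, in cm^3 (mm^3 / 1000).

    Degenerate point sets (coplanar/collinear) have zero volume; fewer
    than four points are an error (the window is flagged upstream).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if points.shape[0] < 4:
        raise ValueError("need at least four points for a 3D hull")
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0
    return float(hull.volume) / 1000.0


def window_summaries(
    traj: MarkerTrajectory,
    passage_slices: list[tuple[int, int]],
    window_samples: int = 100,
    overlap: float = 0.5,
) -> list[SpatialSummary]:
    """Both descriptors for every complete 1-s window of every passage."""
    out: list[SpatialSummary] = []
    missing = traj.missing_mask
    for pi, (a, b) in enumerate(passage_slices):
        seg = traj.positions[a:b]
        seg_mark = np.where(missing[a:b], np.nan, 0.0)
        for s in slide_windows(seg_mark, window_samples, overlap):
            pts = seg[s:s + window_samples]
            out.append(
                SpatialSummary(
                    mean_interdistance=mean_pairwise_distance(pts),
                    hull_volume=convex_hull_volume(pts),
                    window_id=(pi, s),
                )
            )
    return out


def summarize_take(
    traj: MarkerTrajectory,
    passage_slices: list[tuple[int, int]],
    window_samples: int = 100,
    overlap: float = 0.5,
) -> SpatialSummary:
    """Arithmetic mean of the window descriptors across the take."""
    wins = window_summaries(traj, passage_slices, window_samples, overlap)
    if not wins:
        raise ValueError("no valid window in the take")
    return SpatialSummary(
        mean_interdistance=float(np.mean([w.mean_interdistance for w in wins])),
        hull_volume=float(np.mean([w.hull_volume for w in wins])),
    )
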