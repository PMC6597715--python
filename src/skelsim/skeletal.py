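"""The 3D skeletal similarity metric.

A skeleton is compared to another in object-centered 3D space:

1. sample 999 points per segment along each Bezier curve (2997 in total);
2. respace the points evenly by arc length at 0.0005 vu within each
   segment, rescaling coordinates by 1000 (so the spacing is 0.5 units);
3. overlay the two point clouds by their centers of mass and search
   picture-plane rotations in 15 degree steps (24 candidates) for the
   alignment minimizing the mean closest-point distance;
4. report the mean Euclidean distance between each point on one skeleton
   and the closest point on the other at that alignment, symmetrized by
   averaging the two directions (a directed variant is available).

The picture plane is the x-z image plane; picture-plane rotation spins the
cloud about the viewing (y) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import resample_by_arclength, rotation_about_axis
from .rdm import RDM
from .skeleton import Skeleton

#: coordinate rescaling applied during respacing
RESCALE = 1000.0
#: default even spacing between skeletal points (vu)
DEFAULT_SPACING_VU = 0.0005
#: exact O(n^2) closest-point fallback below this cloud size
_EXACT_LIMIT = 500


@dataclass
class SkeletonPointCloud:
    """Sampled skeletal points, optionally respaced to even arc-length steps.

    ``spacing`` is the target inter-point distance in the cloud's own units
    (None until :func:`respace` has been applied).  ``segment_ids`` tags each
    point with its source segment.
    """

    points: np.ndarray
    source_id: str
    spacing: float | None = None
    segment_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("a point cloud needs at least 2 points")

    def __len__(self):
        return len(self.points)

    def centered(self) -> np.ndarray:
        return self.points - self.points.mean(axis=0)


@dataclass
class AlignmentResult:
    """Outcome of the rotation search: best picture-plane angle and the
    achieved mean closest-point distance."""

    rotation_deg: float
    translation: np.ndarray
    distance: float


def sample_points(sk: Skeleton, n_per_segment: int = 999) -> SkeletonPointCloud:
    """Sample each segment at ``n_per_segment`` equal parameter steps (vu)."""
    if n_per_segment < 2:
        raise ValueError("n_per_segment must be >= 2")
    t = np.linspace(0.0, 1.0, n_per_segment)
    chunks = [seg.point(t) for seg in sk.segments]
    seg_ids = np.repeat(np.arange(len(chunks)), n_per_segment)
    return SkeletonPointCloud(
        np.concatenate(chunks), sk.id, spacing=None, segment_ids=seg_ids
    )


def respace(
    pc: SkeletonPointCloud, spacing: float = DEFAULT_SPACING_VU
) -> SkeletonPointCloud:
    """Resample each segment's points at even arc-length steps.

    ``spacing`` is in the input units (vu); output coordinates are rescaled
    by 1000, so the default 0.0005 vu spacing becomes 0.5 output units.
    Respacing is per segment — junction structure is preserved and a segment
    shorter than the spacing keeps its two endpoints.
    """
    if pc.segment_ids is None:
        seg_ids = np.zeros(len(pc), dtype=int)
    else:
        seg_ids = pc.segment_ids
    chunks, ids = [], []
    for s in np.unique(seg_ids):
        poly = pc.points[seg_ids == s]
        res = resample_by_arclength(poly, spacing)
        chunks.append(res * RESCALE)
        ids.append(np.full(len(res), s))
    return SkeletonPointCloud(
        np.concatenate(chunks),
        pc.source_id,
        spacing=spacing * RESCALE,
        segment_ids=np.concatenate(ids),
    )


def skeleton_point_cloud(
    sk: Skeleton,
    n_per_segment: int = 999,
    spacing: float = DEFAULT_SPACING_VU,
) -> SkeletonPointCloud:
    """Full preprocessing: dense sampling followed by even respacing."""
    return respace(sample_points(sk, n_per_segment), spacing)


def _mean_nearest(tree: cKDTree, query: np.ndarray) -> float:
    return float(tree.query(query, k=1)[0].mean())


def mean_closest_point_distance(
    a: np.ndarray, b: np.ndarray, directed: bool = False
) -> float:
    """Mean distance from each point of ``a`` to its nearest neighbor in
    ``b`` (and, unless directed, averaged with the reverse direction).

    Uses an exact O(n m) computation for small clouds and a k-d tree (also
    exact) for larger ones.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if max(len(a), len(b)) <= _EXACT_LIMIT:
        d = cdist(a, b)
        ab = float(d.min(axis=1).mean())
        if directed:
            return ab
        return 0.5 * (ab + float(d.min(axis=0).mean()))
    ab = _mean_nearest(cKDTree(b), a)
    if directed:
        return ab
    return 0.5 * (ab + _mean_nearest(cKDTree(a), b))


def align(
    a: SkeletonPointCloud,
    b: SkeletonPointCloud,
    step_deg: float = 15.0,
    directed: bool = False,
) -> AlignmentResult:
    """Search picture-plane rotations of ``b`` for the minimum mean
    closest-point distance to ``a``.

    Both clouds are first overlaid by their centers of mass.  All rotations
    ``0, step, 2*step, ... < 360`` about the viewing (y) axis are evaluated;
    ties break toward the smallest angle.
    """
    pa = a.centered()
    pb = b.centered()
    translation = a.points.mean(axis=0) - b.points.mean(axis=0)
    angles = np.arange(0.0, 360.0, step_deg)
    large = max(len(pa), len(pb)) > _EXACT_LIMIT
    if large:
        tree_a, tree_b = cKDTree(pa), cKDTree(pb)
    best = (np.inf, 0.0)
    for ang in angles:
        rot = rotation_about_axis("y", ang)
        if large:
            d_ab = _mean_nearest(tree_a, pb @ rot.T)
            d = d_ab if directed else 0.5 * (d_ab + _mean_nearest(tree_b, pa @ rot))
        else:
            d = mean_closest_point_distance(pa, pb @ rot.T, directed=directed)
        if d < best[0] - 1e-15:
            best = (d, ang)
    return AlignmentResult(best[1], translation, best[0])


def skeletal_distance(
    a: SkeletonPointCloud,
    b: SkeletonPointCloud,
    step_deg: float = 15.0,
    directed: bool = False,
) -> float:
    """Mean closest-point distance between two respaced skeletal clouds at
    their maximal (best picture-plane rotation) alignment."""
    if a.spacing is None or b.spacing is None:
        raise ValueError("clouds must be respaced before comparison")
    if not np.isclose(a.spacing, b.spacing, rtol=1e-6):
        raise ValueError(
            f"mismatched spacings: {a.spacing} vs {b.spacing}"
        )
    return align(a, b, step_deg=step_deg, directed=directed).distance


def skeletal_rdm(
    skeletons: list[Skeleton],
    n_per_segment: int = 999,
    spacing: float = DEFAULT_SPACING_VU,
    step_deg: float = 15.0,
    directed: bool = False,
) -> RDM:
    """Pairwise skeletal distances for a set of skeletons."""
    if len(skeletons) < 2:
        raise ValueError("need at least 2 skeletons")
    ids = [sk.id for sk in skeletons]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate skeleton ids")
    clouds = [skeleton_point_cloud(sk, n_per_segment, spacing) for sk in skeletons]
    n = len(clouds)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = skeletal_distance(clouds[i], clouds[j], step_deg, directed)
            values[i, j] = values[j, i] = d
    return RDM(ids, values, model_id="skeletal")
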