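"""Procedural generation of three-segment skeletal objects.

An object's generative identity is its *skeleton*: three cubic Bezier
segments in 3D "virtual units" (vu).  The first (root) segment points toward
the viewer; the second and third segments attach at a random point along the
root (or the second segment) with their start tangent exactly perpendicular
to the parent tangent at the attachment point.  Segment chord lengths and
bend (curvature) magnitudes are drawn uniformly from [0.05, 0.25] vu and the
whole skeleton is rescaled so its bounding-box extent is 0.25 vu.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    arc_length,
    arclength_table,
    bezier_point,
    param_at_arclength,
    perpendicular_unit,
    unit_tangent,
)

#: lower/upper bound of segment chord length and bend magnitude draws (vu)
SIZE_RANGE = (0.05, 0.25)
#: normalized skeleton extent: longest bounding-box side after rescaling (vu)
NORMALIZED_EXTENT = 0.25

_EXTENT_SAMPLES = 256


@dataclass
class SkeletonSegment:
    """One cubic Bezier segment of a skeleton.

    ``control`` holds the four ordered control points (vu).  Non-root
    segments record the index of their parent segment and the parametric
    position ``attach_t`` on the parent curve where they start.
    """

    control: np.ndarray
    parent: int | None = None
    attach_t: float | None = None
    size: float | None = None
    curvature: float | None = None

    def __post_init__(self):
        self.control = np.asarray(self.control, dtype=float).reshape(4, 3)
        if not np.all(np.isfinite(self.control)):
            raise ValueError("segment control points must be finite")

    @property
    def length(self) -> float:
        """Arc length of the segment (vu)."""
        return arc_length(self.control)

    def point(self, t):
        return bezier_point(self.control, t)

    def tangent(self, t):
        return unit_tangent(self.control, t)


@dataclass
class Skeleton:
    """A three-segment skeletal object."""

    id: str
    segments: list[SkeletonSegment]
    extent: float = NORMALIZED_EXTENT
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.segments) != 3:
            raise ValueError("a skeleton has exactly 3 segments")

    def copy(self, new_id: str | None = None) -> "Skeleton":
        sk = copy.deepcopy(self)
        if new_id is not None:
            sk.id = new_id
        return sk

    def validate(self, atol: float = 1e-8) -> None:
        """Check structural invariants (attachment incidence, finiteness)."""
        for i, seg in enumerate(self.segments):
            if i == 0:
                if seg.parent is not None:
                    raise ValueError("segment 0 must be the root")
                continue
            if seg.parent is None or not (0 <= seg.parent < i):
                raise ValueError(f"segment {i} must attach to an earlier segment")
            start = seg.control[0]
            on_parent = self.segments[seg.parent].point(seg.attach_t)
            if np.linalg.norm(start - on_parent) > atol:
                raise ValueError(f"segment {i} start is off its parent curve")


def skeleton_extent(sk: Skeleton) -> float:
    """Longest bounding-box side over densely sampled curve points (vu)."""
    pts = sample_dense(sk)
    return float((pts.max(axis=0) - pts.min(axis=0)).max())


def sample_dense(sk: Skeleton, n: int = _EXTENT_SAMPLES) -> np.ndarray:
    """Concatenated dense curve samples of all segments, (3n, 3)."""
    t = np.linspace(0.0, 1.0, n)
    return np.concatenate([bezier_point(s.control, t) for s in sk.segments])


def normalize_skeleton(sk: Skeleton) -> Skeleton:
    """Rescale (about the bounding-box center) so the extent is 0.25 vu.

    The center is moved to the origin.  Uniform scaling preserves attachment
    incidence and tangent directions, so perpendicularity at junctions is
    untouched.  Normalizing an already-normalized skeleton is a no-op up to
    floating-point round-off (< 1e-12 per coordinate).
    """
    pts = sample_dense(sk)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    center = 0.5 * (lo + hi)
    extent = float((hi - lo).max())
    if extent <= 0:
        raise ValueError("degenerate skeleton: zero extent")
    factor = NORMALIZED_EXTENT / extent
    out = sk.copy()
    for seg in out.segments:
        seg.control = (seg.control - center) * factor
    out.extent = NORMALIZED_EXTENT
    out.meta = dict(sk.meta, normalization_factor=factor)
    return out


def _make_segment(p0, direction, rng, size=None, curvature=None):
    """Build a segment starting at ``p0`` with start tangent ``direction``.

    The middle control point is offset perpendicular to the chord by the
    bend magnitude, so the start tangent is exactly along ``direction``.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    if size is None:
        size = rng.uniform(*SIZE_RANGE)
    if curvature is None:
        curvature = rng.uniform(*SIZE_RANGE)
    bend_dir = perpendicular_unit(direction, rng)
    p0 = np.asarray(p0, dtype=float)
    control = np.stack(
        [
            p0,
            p0 + (size / 3.0) * direction,
            p0 + (2.0 * size / 3.0) * direction + curvature * bend_dir,
            p0 + size * direction,
        ]
    )
    return control, size, curvature


def build_skeleton(
    rng_seed: int,
    id: str | None = None,
    max_attempts: int = 100,
) -> Skeleton:
    """Draw a random three-segment skeleton, normalized to 0.25 vu extent.

    Deterministic given ``rng_seed``.  The root segment points along +y
    (toward the viewer); each child starts perpendicular to its parent's
    tangent at a uniformly drawn attachment point.
    """
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_attempts):
        sk = _draw_skeleton(rng, id or f"sk{rng_seed}")
        try:
            sk.validate()
        except ValueError:
            continue
        if all(seg.length > 1e-9 for seg in sk.segments):
            return normalize_skeleton(sk)
    raise RuntimeError(f"failed to draw a valid skeleton in {max_attempts} attempts")


def _draw_skeleton(rng: np.random.Generator, sk_id: str) -> Skeleton:
    segments = []
    # root: forward toward the camera (+y)
    control, size, curv = _make_segment(np.zeros(3), [0.0, 1.0, 0.0], rng)
    segments.append(SkeletonSegment(control, None, None, size, curv))
    # children: segment 1 attaches to the root; segment 2 to segment 0 or 1
    parents = [0, int(rng.integers(0, 2))]
    for parent in parents:
        attach_t = rng.uniform(0.1, 0.9)
        p0 = segments[parent].point(attach_t)
        tangent = segments[parent].tangent(attach_t)
        direction = perpendicular_unit(tangent, rng)
        control, size, curv = _make_segment(p0, direction, rng)
        segments.append(SkeletonSegment(control, parent, attach_t, size, curv))
    return Skeleton(sk_id, segments, meta={"seed_segments": len(segments)})


def generate_skeleton_set(n: int, seed: int, prefix: str = "sk") -> list[Skeleton]:
    """Generate ``n`` skeletons with independent streams spawned from ``seed``."""
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, ss in enumerate(children):
        sk_id = f"{prefix}{i:02d}"
        sub = int(ss.generate_state(1)[0] % (2**31))
        out.append(build_skeleton(sub, id=sk_id))
    return out


# ---------------------------------------------------------------------------
# increment morphs: slide one segment along the central segment
# ---------------------------------------------------------------------------

def attachment_arclength(sk: Skeleton, movable: int) -> float:
    """Arc-length position of segment ``movable``'s attachment on its parent."""
    seg = sk.segments[movable]
    parent = sk.segments[seg.parent]
    t_tab, s_tab = arclength_table(parent.control)
    return float(np.interp(seg.attach_t, t_tab, s_tab))


def make_increment_series(
    base: Skeleton,
    steps,
    movable: int = 2,
    central: int = 0,
) -> list[Skeleton]:
    """Relocate segment ``movable`` along segment ``central`` by fractions of
    the central segment's length.

    Step ``f`` moves the attachment by ``f * length(central)`` in arc length;
    the movable segment is translated rigidly, so its own shape and the
    coarse attachment topology are unchanged.  Step 0 returns the base
    geometry unchanged.
    """
    seg = base.segments[movable]
    if seg.parent != central:
        raise ValueError("movable segment must attach to the central segment")
    central_seg = base.segments[central]
    length = central_seg.length
    s0 = attachment_arclength(base, movable)
    out = []
    for f in steps:
        label = f"{base.id}_inc{int(round(f * 100)):02d}"
        if f == 0:
            out.append(base.copy(new_id=label))
            continue
        s_new = s0 + f * length
        if s_new < -1e-12 or s_new > length + 1e-12:
            raise ValueError(
                f"step {f} pushes the attachment outside the central segment"
            )
        t_new = float(param_at_arclength(central_seg.control, s_new))
        p_new = central_seg.point(t_new)
        delta = p_new - seg.control[0]
        sk = base.copy(new_id=label)
        sk.segments[movable].control = seg.control + delta
        sk.segments[movable].attach_t = t_new
        sk.meta = dict(base.meta, increment=f)
        out.append(sk)
    return out


# three coarse spatial-relation templates: nominal start directions of the
# two child segments (projected into the plane perpendicular to the parent
# tangent before use, so perpendicularity is exact)
_RELATION_TEMPLATES = [
    ([0.2, 0.0, -1.0], [-0.2, 0.0, -1.0]),   # both below, pointing down
    ([1.0, 0.0, 0.3], [-1.0, 0.0, -0.3]),    # either side, one up one down
    ([1.0, 0.0, -0.8], [-1.0, 0.0, -0.8]),   # either side, diagonally down
]


def build_exp2_bases(seed: int) -> list[Skeleton]:
    """Three reference skeletons with distinct coarse spatial relations.

    Both children attach to the central (root) segment, and the movable
    child (index 2) attaches in the first half of the root so that the full
    +50% increment series stays on the segment.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k, (dir1, dir2) in enumerate(_RELATION_TEMPLATES):
        control, size, curv = _make_segment(np.zeros(3), [0.0, 1.0, 0.0], rng)
        segments = [SkeletonSegment(control, None, None, size, curv)]
        for j, nominal in enumerate([dir1, dir2]):
            attach_t = rng.uniform(0.1, 0.4) if j == 1 else rng.uniform(0.45, 0.9)
            p0 = segments[0].point(attach_t)
            tangent = segments[0].tangent(attach_t)
            nominal = np.asarray(nominal, dtype=float)
            direction = nominal - (nominal @ tangent) * tangent
            direction /= np.linalg.norm(direction)
            c, size_j, curv_j = _make_segment(
                p0, direction, rng, curvature=rng.uniform(0.05, 0.1)
            )
            segments.append(SkeletonSegment(c, 0, attach_t, size_j, curv_j))
        sk = Skeleton(f"set{k + 1}", segments, meta={"relation_template": k})
        sk.validate()
        out.append(normalize_skeleton(sk))
    return out


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def skeleton_to_dict(sk: Skeleton) -> dict:
    return {
        "id": sk.id,
        "extent": sk.extent,
        "meta": {k: v for k, v in sk.meta.items()},
        "segments": [
            {
                "control": seg.control.tolist(),
                "parent": seg.parent,
                "attach_t": seg.attach_t,
                "size": seg.size,
                "curvature": seg.curvature,
            }
            for seg in sk.segments
        ],
    }


def skeleton_from_dict(d: dict) -> Skeleton:
    segments = [
        SkeletonSegment(
            np.asarray(s["control"], dtype=float),
            s["parent"],
            s["attach_t"],
            s.get("size"),
            s.get("curvature"),
        )
        for s in d["segments"]
    ]
    return Skeleton(d["id"], segments, d.get("extent", NORMALIZED_EXTENT), d.get("meta", {}))


def save_skeletons(skeletons: list[Skeleton], path) -> None:
    payload = [skeleton_to_dict(sk) for sk in skeletons]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_skeletons(path) -> list[Skeleton]:
    return [skeleton_from_dict(d) for d in json.loads(Path(path).read_text())]
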