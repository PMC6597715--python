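"""Surface forms: circular-cross-section tubes wrapped around a skeleton.

A surface form changes an object's visible contours and non-accidental
properties (taper, bulge, pinch, ...) without changing the underlying
skeleton: the tube's centerline is exactly the skeletal curve, and every
cross-section is a circle whose radius follows the form's taper profile as a
function of normalized arc length along the segment.

Two of the five library forms ("thin" and "thick") share the constant-radius
taper family and differ only in circumference, mirroring a stimulus set in
which two forms share non-accidental properties but differ metrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import trimesh

from .geometry import bezier_point, bezier_tangent
from .skeleton import Skeleton

#: minimum tube radius (vu); profiles never pinch to an exact point
MIN_RADIUS = 1.5e-3


@dataclass(frozen=True)
class SurfaceForm:
    """A named taper profile: radius (vu) as a function of normalized arc
    length ``s`` in [0, 1] along each segment."""

    id: int
    name: str
    base_radius: float
    profile: Callable[[np.ndarray, float], np.ndarray]
    family: str

    def radius(self, s: np.ndarray) -> np.ndarray:
        r = self.profile(np.asarray(s, dtype=float), self.base_radius)
        return np.maximum(r, MIN_RADIUS)


def _constant(s, r):
    return np.full_like(s, r)


def _taper_to_tip(s, r):
    # linear reduction toward the segment end
    return r * (1.0 - 0.85 * s)


def _bulge(s, r):
    # convex: widest at mid-segment
    return r * (0.55 + 0.75 * np.sin(np.pi * s))


def _pinch(s, r):
    # concave: narrowest at mid-segment
    return r * (1.15 - 0.75 * np.sin(np.pi * s))


#: the five-library: ids 1..5; forms 1 and 2 share the constant family
SURFACE_FORMS = [
    SurfaceForm(1, "thin", 0.011, _constant, family="constant"),
    SurfaceForm(2, "thick", 0.022, _constant, family="constant"),
    SurfaceForm(3, "tapered", 0.020, _taper_to_tip, family="taper"),
    SurfaceForm(4, "bulge", 0.015, _bulge, family="bulge"),
    SurfaceForm(5, "pinch", 0.017, _pinch, family="pinch"),
]


def get_surface_form(form_id: int) -> SurfaceForm:
    for f in SURFACE_FORMS:
        if f.id == form_id:
            return f
    raise KeyError(f"no surface form with id {form_id}")


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal/binormal frames along a polyline by parallel transport.

    Avoids the sudden frame flips of Frenet frames on near-straight runs.
    """
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(points)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    n = np.cross(tangents[0], helper)
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(points)):
        n = normals[i - 1] - (normals[i - 1] @ tangents[i]) * tangents[i]
        norm = np.linalg.norm(n)
        if norm < 1e-12:  # pathological kink; restart the frame
            n = np.cross(tangents[i], helper)
            norm = np.linalg.norm(n)
        normals[i] = n / norm
    binormals = np.cross(tangents, normals)
    return normals, binormals


def _tube_mesh(points: np.ndarray, radii: np.ndarray, n_around: int) -> trimesh.Trimesh:
    normals, binormals = _parallel_transport_frames(points)
    phi = np.linspace(0.0, 2.0 * np.pi, n_around, endpoint=False)
    circ = np.stack([np.cos(phi), np.sin(phi)], axis=1)  # (m, 2)
    rings = (
        points[:, None, :]
        + radii[:, None, None]
        * (circ[None, :, 0, None] * normals[:, None, :]
           + circ[None, :, 1, None] * binormals[:, None, :])
    )  # (n, m, 3)
    n, m = rings.shape[:2]
    verts = rings.reshape(-1, 3)
    i = np.arange(n - 1)[:, None]
    j = np.arange(m)[None, :]
    jn = (j + 1) % m
    a = (i * m + j).ravel()
    b = (i * m + jn).ravel()
    c = ((i + 1) * m + j).ravel()
    d = ((i + 1) * m + jn).ravel()
    faces = np.concatenate(
        [np.stack([a, c, b], axis=1), np.stack([b, c, d], axis=1)]
    )
    # end caps: triangle fans to the centerline endpoints
    verts = np.concatenate([verts, points[[0]], points[[-1]]])
    start_center = n * m
    end_center = n * m + 1
    j = np.arange(m)
    cap0 = np.stack([np.full(m, start_center), j, (j + 1) % m], axis=1)
    cap1 = np.stack(
        [np.full(m, end_center), (n - 1) * m + (j + 1) % m, (n - 1) * m + j], axis=1
    )
    faces = np.concatenate([faces, cap0, cap1])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def apply_surface_form(
    sk: Skeleton,
    form: SurfaceForm,
    n_along: int = 48,
    n_around: int = 14,
) -> trimesh.Trimesh:
    """Wrap a circular-cross-section tube around each skeletal segment.

    The mesh centerline is the skeleton curve itself; ring ``k`` of each
    segment has exactly the radius prescribed by the form's taper profile at
    that normalized arc position.  Segment tubes may interpenetrate near
    junctions — silhouette rendering tolerates the overlap.
    """
    meshes = []
    for seg in sk.segments:
        t = np.linspace(0.0, 1.0, n_along)
        pts = bezier_point(seg.control, t)
        # normalized arc length along the segment for the taper profile
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(d)])
        s /= s[-1]
        radii = form.radius(s)
        meshes.append(_tube_mesh(pts, radii, n_around))
    mesh = trimesh.util.concatenate(meshes)
    mesh.metadata["skeleton_id"] = sk.id
    mesh.metadata["form_id"] = form.id
    return mesh


def build_object_set(skeletons, forms=SURFACE_FORMS) -> dict[tuple[str, int], trimesh.Trimesh]:
    """All (skeleton, surface form) meshes, keyed by (skeleton id, form id)."""
    return {
        (sk.id, form.id): apply_surface_form(sk, form)
        for sk in skeletons
        for form in forms
    }
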