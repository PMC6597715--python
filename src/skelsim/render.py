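"""Orthographic Lambertian rendering of stimulus meshes.

The camera looks along -y; the image plane is x (right) by z (up).  A
"depth orientation" rotates the object about the vertical (z) axis before
projection.  Shading is flat Lambertian with a fixed light direction and a
constant background, rasterized with a z-buffer.  Rendering is fully
deterministic: the same mesh and spec always produce bit-identical pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import rotation_about_axis

#: world half-window (vu); chosen so a 0.25 vu object plus tube radius fits
#: at every orientation
WORLD_HALF_WINDOW = 0.21

EXP1_ORIENTATIONS = (-30, 0, 30)
EXP23_ORIENTATIONS = (30, 60, 90)

_LIGHT = np.array([0.3, 1.0, 0.6])
_LIGHT = _LIGHT / np.linalg.norm(_LIGHT)
_AMBIENT = 0.25
_DIFFUSE = 0.70


@dataclass(frozen=True)
class RenderSpec:
    """How to turn a mesh into a grayscale stimulus image."""

    orientation_deg: float = 0.0
    image_px: int = 128
    projection: str = "orthographic"
    background: float = 0.0

    def __post_init__(self):
        if self.image_px < 64:
            raise ValueError("image_px must be >= 64")
        if self.projection != "orthographic":
            raise ValueError("only orthographic projection is supported")


@dataclass
class StimulusImage:
    """A rendered grayscale view of a (skeleton, surface form, orientation)."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def image_ref(self) -> tuple:
        return (
            self.meta.get("skeleton_id"),
            self.meta.get("form_id"),
            self.meta.get("orientation"),
        )


def render(mesh, spec: RenderSpec, meta: dict | None = None) -> StimulusImage:
    """Rasterize a triangle mesh into a shaded grayscale image.

    Raises ``RuntimeError`` if no triangle projects inside the frame.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if len(faces) == 0:
        raise ValueError("empty mesh")
    center = 0.5 * (verts.min(axis=0) + verts.max(axis=0))
    rot = rotation_about_axis("z", spec.orientation_deg)
    v = (verts - center) @ rot.T

    px = spec.image_px
    w = WORLD_HALF_WINDOW
    # image coords: col from x, row from z (row 0 at the top)
    cols = (v[:, 0] + w) / (2.0 * w) * (px - 1)
    rows = (w - v[:, 2]) / (2.0 * w) * (px - 1)
    depth = v[:, 1]  # camera at +y: larger y is closer

    tri_cols = cols[faces]
    tri_rows = rows[faces]
    tri_depth = depth[faces]

    # flat shading from outward face normals (after rotation)
    e1 = v[faces[:, 1]] - v[faces[:, 0]]
    e2 = v[faces[:, 2]] - v[faces[:, 0]]
    n = np.cross(e1, e2)
    norm = np.linalg.norm(n, axis=1)
    valid = norm > 1e-15
    n[valid] /= norm[valid, None]
    facing = n[:, 1] > 0  # toward the camera
    shade = _AMBIENT + _DIFFUSE * np.clip(n @ _LIGHT, 0.0, None)
    shade = np.clip(shade, 0.0, 1.0)

    img = np.full((px, px), float(spec.background))
    zbuf = np.full((px, px), -np.inf)
    drawn = False
    for k in np.nonzero(valid & facing)[0]:
        c = tri_cols[k]
        r = tri_rows[k]
        c_lo = max(int(np.floor(c.min())), 0)
        c_hi = min(int(np.ceil(c.max())), px - 1)
        r_lo = max(int(np.floor(r.min())), 0)
        r_hi = min(int(np.ceil(r.max())), px - 1)
        if c_lo > c_hi or r_lo > r_hi:
            continue
        gc, gr = np.meshgrid(
            np.arange(c_lo, c_hi + 1), np.arange(r_lo, r_hi + 1)
        )
        # barycentric coordinates in image space
        d = (r[1] - r[2]) * (c[0] - c[2]) + (c[2] - c[1]) * (r[0] - r[2])
        if abs(d) < 1e-12:
            continue
        l0 = ((r[1] - r[2]) * (gc - c[2]) + (c[2] - c[1]) * (gr - r[2])) / d
        l1 = ((r[2] - r[0]) * (gc - c[2]) + (c[0] - c[2]) * (gr - r[2])) / d
        l2 = 1.0 - l0 - l1
        inside = (l0 >= -1e-9) & (l1 >= -1e-9) & (l2 >= -1e-9)
        if not inside.any():
            continue
        z = l0 * tri_depth[k, 0] + l1 * tri_depth[k, 1] + l2 * tri_depth[k, 2]
        rr = gr[inside]
        cc = gc[inside]
        zz = z[inside]
        closer = zz > zbuf[rr, cc]
        if closer.any():
            rr, cc, zz = rr[closer], cc[closer], zz[closer]
            zbuf[rr, cc] = zz
            img[rr, cc] = shade[k]
            drawn = True
    if not drawn:
        raise RuntimeError("empty projection: object outside the frame")
    return StimulusImage(img, dict(meta or {}, orientation=spec.orientation_deg))


def render_stimulus(sk, form, orientation_deg: float, image_px: int = 128) -> StimulusImage:
    """Convenience: mesh a (skeleton, form) pair and render one orientation."""
    from .surface import apply_surface_form

    mesh = apply_surface_form(sk, form)
    spec = RenderSpec(orientation_deg=orientation_deg, image_px=image_px)
    return render(
        mesh, spec, meta={"skeleton_id": sk.id, "form_id": form.id}
    )


def render_image_set(
    skeletons,
    forms,
    orientations,
    image_px: int = 128,
) -> list[StimulusImage]:
    """Render every (skeleton, form, orientation) combination."""
    from .surface import apply_surface_form

    out = []
    for sk in skeletons:
        for form in forms:
            mesh = apply_surface_form(sk, form)
            for ori in orientations:
                spec = RenderSpec(orientation_deg=ori, image_px=image_px)
                out.append(
                    render(mesh, spec, meta={"skeleton_id": sk.id, "form_id": form.id})
                )
    return out


def save_png(img: StimulusImage, path) -> None:
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def load_png(path, meta: dict | None = None) -> StimulusImage:
    arr = np.asarray(Image.open(Path(path)).convert("L"), dtype=float) / 255.0
    return StimulusImage(arr, dict(meta or {}))
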