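"""HMAX S1 -> C1 -> S2 -> C2 feature hierarchy.

S1 convolves the image with Gabor filters at 8 sizes x 4 orientations
(normalized correlation, magnitude in [0, 1]).  C1 takes the maximum over
adjacent filter sizes (4 scale bands) and local spatial neighborhoods,
giving tolerance to position and scale.  S2 matches C1 patches against a
set of stored templates with a radial-basis function; C2 is the global
maximum of each template's response over all positions and bands, so the
final vector length equals the number of templates.

Templates are cropped at random C1 positions from a set of reference images
(deterministic given a seed); their provenance is recorded on the patch set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import fftconvolve

from .features import FeatureVector

#: S1 Gabor kernel sizes (px); adjacent pairs form the 4 C1 bands
_S1_SIZES = (7, 9, 11, 13, 15, 17, 19, 21)
_N_ORIENT = 4
#: C1 spatial pooling window per band (stride is half the window)
_C1_POOL = (8, 10, 12, 14)
#: S2 patch sizes in C1 units
PATCH_SIZES = (4, 8, 12)
#: RBF sharpness: response = exp(-d2 / (2 * sigma^2 * n_elements))
_S2_SIGMA2 = 0.5


def _s1_kernel(size: int, theta: float) -> np.ndarray:
    """Zero-mean, unit-norm Gabor of a given pixel size (standard-model
    sigma/wavelength parameterization)."""
    sigma = 0.0036 * size**2 + 0.35 * size + 0.18
    lam = sigma / 0.8
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    k = np.exp(-(xr**2 + 0.09 * yr**2) / (2.0 * sigma**2)) * np.cos(
        2.0 * np.pi * xr / lam
    )
    k -= k.mean()
    return k / np.linalg.norm(k)


_KERNELS = None


def _kernels():
    global _KERNELS
    if _KERNELS is None:
        _KERNELS = [
            [_s1_kernel(s, o * np.pi / _N_ORIENT) for o in range(_N_ORIENT)]
            for s in _S1_SIZES
        ]
    return _KERNELS


def s1_layer(pixels: np.ndarray) -> list[np.ndarray]:
    """Normalized-correlation S1 maps: one (H, W, 4) array per filter size."""
    pixels = np.asarray(pixels, dtype=float)
    sq = pixels**2
    out = []
    for size, kern_row in zip(_S1_SIZES, _kernels()):
        box = np.ones((size, size))
        local_norm = np.sqrt(np.clip(fftconvolve(sq, box, mode="same"), 0, None))
        maps = np.empty(pixels.shape + (_N_ORIENT,))
        for o, k in enumerate(kern_row):
            resp = fftconvolve(pixels, k, mode="same")
            maps[:, :, o] = np.abs(resp) / (local_norm + 1e-9)
        out.append(maps)
    return out


def c1_layer(s1_maps: list[np.ndarray]) -> list[np.ndarray]:
    """Max over adjacent sizes and local positions: 4 bands of (h, w, 4)."""
    bands = []
    for b in range(len(_S1_SIZES) // 2):
        merged = np.maximum(s1_maps[2 * b], s1_maps[2 * b + 1])
        pool = _C1_POOL[b]
        step = max(pool // 2, 1)
        pooled = maximum_filter(
            merged, size=(pool, pool, 1), mode="constant", cval=0.0
        )[pool // 2 :: step, pool // 2 :: step]
        bands.append(pooled)
    return bands


def c1_from_image(img) -> list[np.ndarray]:
    pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    return c1_layer(s1_layer(pixels))


@dataclass
class S2PatchSet:
    """Stored C1-space templates with provenance metadata."""

    patches: list = field(repr=False)  # list of (p, p, 4) arrays
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.patches:
            raise ValueError("patch set must be non-empty")
        for p in self.patches:
            if np.linalg.norm(p) <= 0:
                raise ValueError("patch with zero norm")

    def __len__(self):
        return len(self.patches)


def build_s2_patches(imgs, n_patches: int, rng_seed: int) -> S2PatchSet:
    """Crop ``n_patches`` random C1 patches from the given images.

    Blank (near-zero-norm) crops are rejected and redrawn.  Deterministic
    given the seed and image order.
    """
    if n_patches <= 0:
        raise ValueError("n_patches must be positive")
    if not len(imgs):
        raise ValueError("need at least one image")
    rng = np.random.default_rng(rng_seed)
    c1_sets = [c1_from_image(img) for img in imgs]
    patches = []
    attempts = 0
    while len(patches) < n_patches:
        attempts += 1
        if attempts > 100 * n_patches:
            raise RuntimeError("could not find enough non-blank patches")
        c1 = c1_sets[rng.integers(len(c1_sets))]
        band = c1[rng.integers(len(c1))]
        p = int(rng.choice(PATCH_SIZES))
        h, w = band.shape[:2]
        if h < p or w < p:
            continue
        r = rng.integers(h - p + 1)
        c = rng.integers(w - p + 1)
        crop = band[r : r + p, c : c + p].copy()
        if np.linalg.norm(crop) < 1e-6:
            continue
        patches.append(crop)
    return S2PatchSet(
        patches,
        provenance={"seed": int(rng_seed), "n_source_images": len(imgs)},
    )


def _s2_response_max(band: np.ndarray, patch: np.ndarray) -> float:
    """Maximum RBF template match of ``patch`` over all positions of a C1
    band; -inf when the patch does not fit."""
    p = patch.shape[0]
    h, w = band.shape[:2]
    if h < p or w < p:
        return -np.inf
    # squared distance via the convolution identity
    d2 = np.zeros((h - p + 1, w - p + 1))
    box = np.ones((p, p))
    for o in range(band.shape[2]):
        x = band[:, :, o]
        d2 += fftconvolve(x**2, box, mode="valid")
        d2 -= 2.0 * fftconvolve(x, patch[::-1, ::-1, o], mode="valid")
    d2 += float((patch**2).sum())
    d2 = np.clip(d2, 0.0, None)
    resp = np.exp(-d2 / (2.0 * _S2_SIGMA2 * patch.size))
    return float(resp.max())


def hmax_c2_features(img, patches: S2PatchSet) -> FeatureVector:
    """C2 vector: per template, the global max S2 response over positions
    and scale bands."""
    c1 = c1_from_image(img)
    values = np.array(
        [max(_s2_response_max(band, p) for band in c1) for p in patches.patches]
    )
    ref = img.image_ref if hasattr(img, "image_ref") else ()
    return FeatureVector("hmax_c2", values, ref)
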