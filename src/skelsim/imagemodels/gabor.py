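"""Gabor filter bank, Gabor-Jet (GBJ) and GIST feature extraction.

GBJ overlays a 12 x 12 grid of nodes on the image; at each node the complex
responses of 40 Gabor filters (5 scales x 8 orientations) are read out and
stored as magnitudes followed by phases (node-major, then scale, then
orientation): 12*12*5*8*2 = 11,520 values.

GIST convolves the image with 32 Gabor filters (4 scales x 8 orientations),
takes the magnitude (energy) map of each, and averages it within the 16
cells of a 4 x 4 grid: 4*8*16 = 512 values.

Gabor kernel constants (octave-spaced wavelengths, bandwidth sigma = 0.56
lambda, aspect ratio 0.5, even/odd phase pair) are conventional choices and
are recorded on the bank object.  Kernels are zero-mean after truncation, so
constant images produce (near) zero magnitudes and features are invariant to
adding a constant intensity offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .features import FeatureVector

#: base wavelength (px) of the finest scale; scales are octave-spaced
_BASE_WAVELENGTH = 4.0
_SIGMA_RATIO = 0.56
_ASPECT = 0.5
#: Gaussian support half-width in sigmas before truncation
_SUPPORT = 2.5


def gabor_kernel(wavelength: float, theta: float, max_size: int) -> np.ndarray:
    """Complex (even + i*odd) Gabor kernel, zero-mean and unit-norm.

    The kernel is truncated to at most ``max_size`` pixels per side; the
    even part is re-centered to zero mean after truncation.
    """
    sigma = _SIGMA_RATIO * wavelength
    half = int(np.ceil(_SUPPORT * sigma))
    half = min(half, (max_size - 1) // 2)
    if half < 1:
        raise ValueError("image too small for the requested Gabor kernel")
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-(xr**2 + (_ASPECT * yr) ** 2) / (2.0 * sigma**2))
    even = envelope * np.cos(2.0 * np.pi * xr / wavelength)
    odd = envelope * np.sin(2.0 * np.pi * xr / wavelength)
    even -= even.mean()
    odd -= odd.mean()
    k = even + 1j * odd
    return k / np.linalg.norm(k)


@dataclass
class GaborBank:
    """A fixed bank of complex Gabor kernels (scales x orientations)."""

    n_scales: int
    n_orientations: int
    max_kernel_size: int
    base_wavelength: float = _BASE_WAVELENGTH
    kernels: list = field(default_factory=list, repr=False)
    wavelengths: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.wavelengths is None:
            self.wavelengths = self.base_wavelength * 2.0 ** np.arange(self.n_scales)
        if not self.kernels:
            self.kernels = [
                [
                    gabor_kernel(
                        lam, o * np.pi / self.n_orientations, self.max_kernel_size
                    )
                    for o in range(self.n_orientations)
                ]
                for lam in self.wavelengths
            ]

    def responses(self, image: np.ndarray) -> np.ndarray:
        """Complex response maps, shape (n_scales, n_orientations, H, W).

        The image is edge-padded by the largest kernel half-width before
        convolution, so a constant image yields (near) zero magnitudes
        everywhere instead of spurious border responses.
        """
        image = np.asarray(image, dtype=float)
        pad = max(k.shape[0] for row in self.kernels for k in row) // 2
        padded = np.pad(image, pad, mode="edge")
        out = np.empty(
            (self.n_scales, self.n_orientations) + image.shape, dtype=complex
        )
        for s in range(self.n_scales):
            for o in range(self.n_orientations):
                full = fftconvolve(padded, self.kernels[s][o], mode="same")
                out[s, o] = full[pad : pad + image.shape[0], pad : pad + image.shape[1]]
        return out


_BANK_CACHE: dict = {}


def _bank(n_scales, n_orients, size) -> GaborBank:
    key = (n_scales, n_orients, size)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = GaborBank(n_scales, n_orients, size)
    return _BANK_CACHE[key]


def _grid_nodes(size: int, n: int) -> np.ndarray:
    """n node coordinates evenly spread with half-cell margins."""
    step = size / n
    return np.round(step / 2.0 + step * np.arange(n) - 0.5).astype(int)


def gbj_features(img, grid: int = 12, n_scales: int = 5, n_orientations: int = 8) -> FeatureVector:
    """Gabor-Jet features: magnitudes then phases at every grid node."""
    pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("GBJ expects a grayscale image")
    bank = _bank(n_scales, n_orientations, min(pixels.shape))
    resp = bank.responses(pixels)
    nodes = _grid_nodes(pixels.shape[0], grid)
    cols = _grid_nodes(pixels.shape[1], grid)
    # (node_row, node_col, scale, orientation)
    jets = resp[:, :, nodes][:, :, :, cols]  # (s, o, gr, gc)
    jets = np.moveaxis(jets, [0, 1], [2, 3]).reshape(-1)  # node-major
    values = np.concatenate([np.abs(jets), np.angle(jets)])
    ref = img.image_ref if hasattr(img, "image_ref") else ()
    return FeatureVector("gbj", values, ref)


def gist_features(img, grid: int = 4, n_scales: int = 4, n_orientations: int = 8) -> FeatureVector:
    """GIST features: regional mean Gabor energy on a 4 x 4 grid."""
    pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("GIST expects a grayscale image")
    bank = _bank(n_scales, n_orientations, min(pixels.shape))
    energy = np.abs(bank.responses(pixels))  # (s, o, H, W)
    h, w = pixels.shape
    row_edges = np.linspace(0, h, grid + 1).astype(int)
    col_edges = np.linspace(0, w, grid + 1).astype(int)
    vals = np.empty((n_scales, n_orientations, grid, grid))
    for i in range(grid):
        for j in range(grid):
            block = energy[
                :, :, row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]
            ]
            vals[:, :, i, j] = block.mean(axis=(2, 3))
    ref = img.image_ref if hasattr(img, "image_ref") else ()
    return FeatureVector("gist", vals.reshape(-1), ref)
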