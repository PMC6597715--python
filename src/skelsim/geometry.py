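"""Cubic Bezier curves and arc-length utilities.

Every skeletal segment in this package is a single cubic Bezier curve in 3D.
Arc-length quantities are computed from a dense polyline approximation of the
curve; the sampling density is fixed so that the same curve always yields the
same (deterministic) lengths.
"""

from __future__ import annotations

import numpy as np

#: number of samples used for arc-length tables; dense enough that chord-based
#: lengths are accurate to ~1e-8 for curves of unit scale
_ARC_SAMPLES = 2048


def bezier_point(control: np.ndarray, t) -> np.ndarray:
    """Evaluate a cubic Bezier at parameter(s) ``t``.

    Parameters
    ----------
    control : (4, 3) array of control points.
    t : scalar or (n,) array in [0, 1].

    Returns
    -------
    (3,) or (n, 3) array of curve points.
    """
    control = np.asarray(control, dtype=float)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)[:, None]
    u = 1.0 - t
    p = (
        u**3 * control[0]
        + 3.0 * u**2 * t * control[1]
        + 3.0 * u * t**2 * control[2]
        + t**3 * control[3]
    )
    return p[0] if scalar else p


def bezier_tangent(control: np.ndarray, t) -> np.ndarray:
    """Unnormalized derivative dB/dt of a cubic Bezier at ``t``."""
    control = np.asarray(control, dtype=float)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)[:, None]
    u = 1.0 - t
    d = (
        3.0 * u**2 * (control[1] - control[0])
        + 6.0 * u * t * (control[2] - control[1])
        + 3.0 * t**2 * (control[3] - control[2])
    )
    return d[0] if scalar else d


def unit_tangent(control: np.ndarray, t) -> np.ndarray:
    """Unit tangent vector at parameter ``t``."""
    d = bezier_tangent(control, t)
    n = np.linalg.norm(d, axis=-1, keepdims=d.ndim > 1)
    return d / (n if d.ndim > 1 else np.linalg.norm(d))


def arclength_table(control: np.ndarray, n: int = _ARC_SAMPLES):
    """Cumulative arc length at ``n`` equally spaced parameter values.

    Returns ``(t, s)`` where ``s[i]`` is the chord-summed length from the
    curve start to parameter ``t[i]``; ``s[-1]`` is the total length.
    """
    t = np.linspace(0.0, 1.0, n)
    pts = bezier_point(control, t)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return t, s


def arc_length(control: np.ndarray) -> float:
    """Total arc length of the curve."""
    return float(arclength_table(control)[1][-1])


def param_at_arclength(control: np.ndarray, s) -> np.ndarray:
    """Invert the arc-length map: parameter value(s) at arc length(s) ``s``.

    ``s`` may be a scalar or array; values are clipped to [0, total length].
    """
    t_tab, s_tab = arclength_table(control)
    s = np.clip(np.asarray(s, dtype=float), 0.0, s_tab[-1])
    return np.interp(s, s_tab, t_tab)


def resample_by_arclength(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at even arc-length steps.

    The first point is kept; subsequent points sit at arc lengths
    ``spacing, 2*spacing, ...`` up to the polyline's total length.  A polyline
    shorter than ``spacing`` collapses to its two endpoints.
    """
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < spacing:
        return points[[0, -1]].copy()
    n_steps = int(np.floor(total / spacing + 1e-12))
    targets = np.arange(n_steps + 1) * spacing
    out = np.empty((len(targets), 3))
    for k in range(3):
        out[:, k] = np.interp(targets, s, points[:, k])
    return out


def rotation_about_axis(axis: str, deg: float) -> np.ndarray:
    """3x3 rotation matrix about a coordinate axis ('x', 'y' or 'z')."""
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r}")


def perpendicular_unit(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to ``v``.

    Drawn uniformly on the circle of directions orthogonal to ``v``.
    """
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    # build an orthonormal basis of the perpendicular plane
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v @ helper) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(v, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phi) * e1 + np.sin(phi) * e2
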