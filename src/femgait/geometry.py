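"""Small rotation / vector helpers shared across the package.

Conventions: right-handed frames, X anterior, Y superior, Z to the subject's
right.  Angles are degrees at public interfaces and radians internally.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError


def unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    """Normalize ``v``; raise if it is (near) zero length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{name} has zero length")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix (or stack of matrices) about a unit axis.

    ``angle_rad`` may be a scalar or a 1-D array; the result has shape
    (3, 3) or (n, 3, 3) accordingly.
    """
    a = unit(axis, "rotation axis")
    angle = np.asarray(angle_rad, dtype=float)
    scalar = angle.ndim == 0
    angle = np.atleast_1d(angle)
    c = np.cos(angle)
    s = np.sin(angle)
    K = np.array([
        [0.0, -a[2], a[1]],
        [a[2], 0.0, -a[0]],
        [-a[1], a[0], 0.0],
    ])
    eye = np.eye(3)
    R = (
        eye[None, :, :] * c[:, None, None]
        + K[None, :, :] * s[:, None, None]
        + np.outer(a, a)[None, :, :] * (1.0 - c)[:, None, None]
    )
    return R[0] if scalar else R


def rotate_about_line(points: np.ndarray, axis: np.ndarray, origin: np.ndarray,
                      angle_rad: float) -> np.ndarray:
    """Rigidly rotate ``points`` (…, 3) about the line through ``origin``
    along ``axis`` by ``angle_rad``."""
    R = rotation_about_axis(axis, angle_rad)
    p = np.asarray(points, dtype=float)
    o = np.asarray(origin, dtype=float)
    return (p - o) @ R.T + o


def signed_angle_about(a: np.ndarray, b: np.ndarray, about: np.ndarray) -> float:
    """Signed angle (radians) from ``a`` to ``b`` about the unit axis
    ``about`` (right-hand rule), both projected perpendicular to the axis."""
    n = unit(about, "reference axis")
    a_p = a - np.dot(a, n) * n
    b_p = b - np.dot(b, n) * n
    if np.linalg.norm(a_p) < 1e-12 or np.linalg.norm(b_p) < 1e-12:
        raise DegenerateGeometryError("vector parallel to the reference axis")
    return float(np.arctan2(np.dot(n, np.cross(a_p, b_p)), np.dot(a_p, b_p)))


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle (radians) between two vectors, in [0, pi]."""
    ua, ub = unit(a), unit(b)
    return float(np.arccos(np.clip(np.dot(ua, ub), -1.0, 1.0)))
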