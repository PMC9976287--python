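"""Small rigid-motion helpers shared by the conformer and attachment stages."""

from __future__ import annotations

import numpy as np

__all__ = ["unit", "rotation_between", "rotation_about_axis"]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    # cross with the least-aligned coordinate axis
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(v)))] = 1.0
    return unit(np.cross(v, axis))


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R a/|a| = b/|b| (Rodrigues; antipodal-safe)."""
    a = unit(a)
    b = unit(b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180° about any axis perpendicular to a
        return rotation_about_axis(_any_perpendicular(a), np.pi)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    axis = axis / s
    return rotation_about_axis(axis, float(np.arctan2(s, c)))


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit ``axis`` by ``angle`` radians."""
    axis = unit(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )
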