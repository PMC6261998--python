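"""Small geometric primitives: rotations and ray-sphere chords.

Everything here works in physical (micrometre) coordinates; voxel-grid
conversions live with the renderer.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "check_rotation",
    "rotation_about_axis",
    "ray_sphere_exit_distance",
    "tissue_path_length",
]


def check_rotation(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Validate that ``matrix`` is a proper rotation (orthonormal, det +1)."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise InvalidParameterError(f"rotation must be 3x3, got shape {m.shape}")
    if not np.allclose(m @ m.T, np.eye(3), atol=atol):
        raise InvalidParameterError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(m), 1.0, atol=atol):
        raise InvalidParameterError("rotation matrix must have determinant +1")
    return m


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation of ``angle_deg`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise InvalidParameterError("rotation axis must be non-zero")
    x, y, z = axis / n
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def ray_sphere_exit_distance(
    point: np.ndarray, direction: np.ndarray, center: np.ndarray, radius: float
) -> float:
    """Distance from ``point`` (inside the sphere) to the surface along ``direction``.

    Returns 0.0 for points outside the sphere: a ray starting outside crosses
    no tissue before leaving (the emitter/detector side), which is the only
    use this package has for exterior points.
    """
    p = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # |p + t d|^2 = r^2  ->  t^2 + 2 (p.d) t + (|p|^2 - r^2) = 0
    b = float(p @ d)
    c = float(p @ p) - radius**2
    if c >= 0:
        return 0.0
    t = -b + np.sqrt(b * b - c)
    return float(t)


def tissue_path_length(
    points: np.ndarray, direction: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    """Vectorised chord length from each point to the sphere surface along ``direction``.

    ``points`` has shape (n, 3); points outside the sphere get 0.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    b = p @ d
    c = np.einsum("ij,ij->i", p, p) - radius**2
    out = np.zeros(len(p))
    inside = c < 0
    out[inside] = -b[inside] + np.sqrt(b[inside] ** 2 - c[inside])
    return out
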