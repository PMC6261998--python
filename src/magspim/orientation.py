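"""Tetrahedral electromagnet geometry and current-controlled orientation.

The model is purely geometric: four magnet tips point at the sample from
the vertices of a regular tetrahedron (pairwise 109.47 degrees apart), the
field direction is the current-weighted vector sum of the magnet
directions, and the sample axis aligns with it.  Reorientation time scales
inversely with the applied current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateFieldError,
    InsufficientDataError,
    InvalidParameterError,
    NoFieldError,
)

__all__ = [
    "MagnetArray",
    "OrientationState",
    "tetrahedral_directions",
    "resultant_direction",
    "transition_time",
    "fit_inverse_law",
]


def tetrahedral_directions() -> np.ndarray:
    """Unit vectors from the sample centre to the four magnet tips.

    Canonical orientation: the first vector points along lab +z; the other
    three sit at arccos(-1/3) from it, spread 120 degrees apart in azimuth.
    Pairwise dot products are all -1/3 and the four vectors sum to zero.
    """
    s = 2.0 * np.sqrt(2.0) / 3.0  # sin of the tetrahedral angle from +z
    c = -1.0 / 3.0
    dirs = [np.array([0.0, 0.0, 1.0])]
    for k in range(3):
        phi = 2.0 * np.pi * k / 3.0
        dirs.append(np.array([s * np.cos(phi), s * np.sin(phi), c]))
    return np.array(dirs)


@dataclass(frozen=True)
class MagnetArray:
    """Four magnet directions in regular-tetrahedral arrangement plus currents (A)."""

    directions: np.ndarray = field(default_factory=tetrahedral_directions)
    currents: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        d = np.asarray(self.directions, float)
        i = np.asarray(self.currents, float)
        if d.shape != (4, 3):
            raise InvalidParameterError("directions must be four 3-vectors")
        if i.shape != (4,):
            raise InvalidParameterError("currents must be four scalars")
        if np.any(i < 0):
            raise InvalidParameterError("currents must be non-negative")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise InvalidParameterError("magnet directions must be unit vectors")
        gram = d @ d.T
        off = gram[~np.eye(4, dtype=bool)]
        if not np.allclose(off, -1.0 / 3.0, atol=1e-9):
            raise InvalidParameterError("directions must form a regular tetrahedron")
        if not np.allclose(d.sum(axis=0), 0.0, atol=1e-9):
            raise InvalidParameterError("tetrahedral directions must sum to zero")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "currents", i)


@dataclass(frozen=True)
class OrientationState:
    """Direction along which the magnetically handled sample axis points."""

    axis: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.axis, float)
        n = np.linalg.norm(a)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise InvalidParameterError("axis must be unit-norm")
        object.__setattr__(self, "axis", a / n)

    def angles_to_magnets(self, directions=None) -> np.ndarray:
        """Angle in degrees from the axis to each magnet direction."""
        d = tetrahedral_directions() if directions is None else np.asarray(directions)
        return np.degrees(np.arccos(np.clip(d @ self.axis, -1.0, 1.0)))


def resultant_direction(array: MagnetArray) -> OrientationState:
    """Sample axis = normalised current-weighted sum of magnet directions."""
    if not np.any(array.currents > 0):
        raise NoFieldError("all currents are zero")
    v = array.currents @ array.directions
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateFieldError("current-weighted direction sum is zero")
    return OrientationState(axis=v / n)


def transition_time(current: float, k: float) -> float:
    """Reorientation time k / current (inverse proportionality)."""
    if current <= 0:
        raise InvalidParameterError("current must be positive")
    if k <= 0:
        raise InvalidParameterError("k must be positive")
    return k / current


def fit_inverse_law(observations) -> float:
    """Least-squares estimate of k for the model t = k / I.

    Minimising sum (t_i - k / I_i)^2 gives the closed form
    k = sum(t_i / I_i) / sum(1 / I_i^2).  Repeated current values are
    handled by the same formula (a current-weighted average of t * I).
    """
    obs = [(float(i), float(t)) for i, t in observations]
    usable = [(i, t) for i, t in obs if i > 0]
    if len(usable) < 2:
        raise InsufficientDataError("need at least two observations with positive current")
    inv = np.array([1.0 / i for i, _ in usable])
    t = np.array([t for _, t in usable])
    return float((t * inv).sum() / (inv**2).sum())
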