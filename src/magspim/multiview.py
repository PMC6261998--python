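"""Acquisition-mode simulation: single view, fused multi-view, multi-axis.

Three ways of imaging the same phantom are compared:

* ``single_view`` — animal pole up (cap axis along the vertical tube
  axis, y), one stack;
* ``multi_view``  — same orientation, four stacks at tube rotations
  0/45/180/225 degrees fused by their known transforms;
* ``multi_axis``  — the phantom pre-rotated so the animal pole faces the
  detection objective (cap axis along -z), one stack.

Quality profiles are evaluated along the animal-vegetal axis for every
mode: the single-view and fused volumes are resliced so that plane index
runs from the animal pole inward, matching the multi-axis stack's native
plane order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geometry import check_rotation, rotation_about_axis
from .errors import InvalidInputError, InvalidParameterError
from .phantom import EmbryoPhantom, ImageStack, OpticsModel, render_view, rotate_phantom
from .quality import QualityProfile, quality_profile

__all__ = [
    "TUBE_AXIS",
    "ViewConfig",
    "ComparisonTable",
    "acquire_views",
    "fuse_views",
    "reslice",
    "compare_modes",
    "cap_depth",
    "PAPER_TUBE_ANGLES",
]

#: Vertical sample-tube axis in the lab frame (x illumination, z detection).
TUBE_AXIS = np.array([0.0, 1.0, 0.0])

#: Tube rotations used for the four-view fusion, degrees.
PAPER_TUBE_ANGLES = (0.0, 45.0, 180.0, 225.0)


@dataclass(frozen=True)
class ViewConfig:
    """One acquisition: optional pre-rotation, then a tube rotation."""

    tube_rotation: float = 0.0  # degrees about TUBE_AXIS
    pre_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.tube_rotation < 360.0:
            raise InvalidParameterError("tube_rotation must be in [0, 360)")
        object.__setattr__(self, "pre_rotation", check_rotation(self.pre_rotation))

    def total_rotation(self) -> np.ndarray:
        """World-frame rotation applied to the phantom for this view."""
        return rotation_about_axis(TUBE_AXIS, self.tube_rotation) @ self.pre_rotation


def acquire_views(
    phantom: EmbryoPhantom,
    optics: OpticsModel,
    configs: Sequence[ViewConfig],
    shape,
    pixel_size: float,
    plane_spacing: float,
    seed: int,
) -> list[ImageStack]:
    """Render one stack per view config with deterministic per-view noise seeds."""
    if not configs:
        raise InvalidParameterError("configs must be non-empty")
    view_seeds = np.random.SeedSequence(seed).generate_state(len(configs))
    stacks = []
    for cfg, s in zip(configs, view_seeds):
        rotated = rotate_phantom(phantom, cfg.total_rotation())
        stacks.append(
            render_view(rotated, optics, shape, pixel_size, plane_spacing, seed=int(s))
        )
    return stacks


def _resample_to_reference(stack: ImageStack, rotation: np.ndarray):
    """Resample a view stack into the reference frame by its known rotation.

    The view was rendered from the phantom rotated by ``rotation`` about the
    volume centre, so the reference-frame estimate at world point p is the
    view sampled at ``rotation @ p``.  Returns (resampled, coverage) where
    coverage is the trilinear weight of in-volume support in [0, 1].
    """
    r = check_rotation(rotation)
    nz, ny, nx = stack.shape
    # World coordinates are (x, y, z); voxel indices are (z, y, x).
    p = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    r_zyx = p @ r @ p
    s = np.diag([stack.plane_spacing, stack.pixel_size, stack.pixel_size])
    matrix = np.linalg.inv(s) @ r_zyx @ s
    c0 = (np.array([nz, ny, nx], dtype=float) - 1) / 2
    offset = c0 - matrix @ c0
    resampled = ndimage.affine_transform(
        stack.voxels, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    coverage = ndimage.affine_transform(
        np.ones(stack.shape), matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    return resampled, coverage


def fuse_views(
    stacks: Sequence[ImageStack],
    known_rotations: Sequence[np.ndarray],
    coverage_threshold: float = 1e-6,
) -> ImageStack:
    """Mean-fuse views into the reference frame using their known rotations.

    Each stack is trilinearly resampled by the inverse of its rotation; the
    fused voxel is the coverage-weighted mean of all views supporting it,
    zero where no view reaches.
    """
    if len(stacks) < 2:
        raise InvalidInputError("need at least two stacks to fuse")
    if len(known_rotations) != len(stacks):
        raise InvalidInputError("one rotation per stack required")
    ref = stacks[0]
    for s in stacks[1:]:
        if s.shape != ref.shape or s.pixel_size != ref.pixel_size or s.plane_spacing != ref.plane_spacing:
            raise InvalidInputError("all stacks must share shape and spacing")

    acc = np.zeros(ref.shape)
    cov = np.zeros(ref.shape)
    for stack, rot in zip(stacks, known_rotations):
        resampled, coverage = _resample_to_reference(stack, rot)
        acc += resampled
        cov += coverage
    fused = np.where(cov > coverage_threshold, acc / np.maximum(cov, coverage_threshold), 0.0)
    np.clip(fused, 0.0, None, out=fused)
    return ImageStack(fused, pixel_size=ref.pixel_size, plane_spacing=ref.plane_spacing)


def reslice(stack: ImageStack, axis: str, reverse: bool = False) -> ImageStack:
    """Re-index a stack so planes run along ``axis`` ('z', 'y' or 'x').

    Requires isotropic voxels unless ``axis`` is 'z'.  With ``reverse``
    the plane order is flipped (used to start at the animal pole).
    """
    if axis == "z":
        vox = stack.voxels
        spacing = stack.plane_spacing
    elif axis in ("y", "x"):
        if stack.plane_spacing != stack.pixel_size:
            raise InvalidInputError("reslicing off the z axis requires isotropic voxels")
        vox = stack.voxels.transpose(1, 0, 2) if axis == "y" else stack.voxels.transpose(2, 0, 1)
        spacing = stack.pixel_size
    else:
        raise InvalidParameterError(f"unknown axis {axis!r}")
    if reverse:
        vox = vox[::-1]
    return ImageStack(np.ascontiguousarray(vox), pixel_size=stack.pixel_size, plane_spacing=spacing)


def _align_axis_rotation(from_axis: np.ndarray, to_axis: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``from_axis`` onto ``to_axis``."""
    a = np.asarray(from_axis, float)
    b = np.asarray(to_axis, float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # Antiparallel: rotate 180 degrees about any perpendicular axis.
        helper = np.array([1.0, 0.0, 0.0])
        if abs(helper @ a) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        perp = np.cross(a, helper)
        return rotation_about_axis(perp, 180.0)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k / (1 + c)


def cap_depth(phantom: EmbryoPhantom) -> float:
    """Axial extent (um) of the nucleus cap measured inward from the pole surface."""
    if phantom.n_nuclei == 0:
        return 0.0
    rel = phantom.positions - phantom.sphere_center
    proj = rel @ phantom.cap_axis
    return float(phantom.sphere_radius - proj.min())


@dataclass(frozen=True)
class ComparisonTable:
    """Quality profiles of the three acquisition modes on a common depth axis."""

    profiles: Dict[str, QualityProfile]
    cap_depth_um: float

    MODES = ("single_view", "multi_view", "multi_axis")

    def __post_init__(self):
        spacings = {p.plane_spacing for p in self.profiles.values()}
        if len(spacings) > 1:
            raise InvalidInputError("all profiles must share plane spacing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mode, prof in self.profiles.items():
            for p in prof.plane_scores:
                rows.append(
                    dict(
                        mode=mode,
                        z_index=p.z_index,
                        depth_um=p.depth_um,
                        score_bits=p.score,
                        omitted=p.omitted,
                    )
                )
        return pd.DataFrame(rows, columns=["mode", "z_index", "depth_um", "score_bits", "omitted"])

    def region_means(self, pole_fraction: float = 0.25) -> pd.DataFrame:
        """Mean valid score per mode over the pole region and the rest of the cap.

        The pole region is the first ``pole_fraction`` of depths intersecting
        the nucleus cap; 'away' is the remainder of the cap depth range.
        """
        split = pole_fraction * self.cap_depth_um
        rows = []
        for mode, prof in self.profiles.items():
            d = prof.depths()
            s = prof.scores()
            ok = prof.valid()
            pole = ok & (d <= split)
            away = ok & (d > split) & (d <= self.cap_depth_um)
            rows.append(
                dict(
                    mode=mode,
                    pole_mean=float(np.nanmean(s[pole])) if pole.any() else float("nan"),
                    away_mean=float(np.nanmean(s[away])) if away.any() else float("nan"),
                )
            )
        return pd.DataFrame(rows).set_index("mode")


def compare_modes(
    phantom: EmbryoPhantom,
    optics: OpticsModel,
    shape,
    pixel_size: float,
    plane_spacing: float,
    seed: int,
    radius: int = 5,
    corner_size: int = 100,
    tube_angles: Sequence[float] = PAPER_TUBE_ANGLES,
) -> ComparisonTable:
    """Simulate the three acquisition modes and profile each along the A-V axis."""
    if phantom.cap_half_angle >= 180:
        raise InvalidParameterError("phantom must have a nucleus cap (cap_half_angle < 180)")
    if pixel_size != plane_spacing:
        raise InvalidParameterError("mode comparison requires isotropic voxels")

    seeds = np.random.SeedSequence(seed).generate_state(3)

    # Pole-up orientation (cap axis along the tube axis) for modes a and b.
    pole_up = rotate_phantom(phantom, _align_axis_rotation(phantom.cap_axis, TUBE_AXIS))
    # Pole toward the detection objective (cap axis along -z) for mode c.
    pole_to_det = rotate_phantom(
        phantom, _align_axis_rotation(phantom.cap_axis, np.array([0.0, 0.0, -1.0]))
    )

    def profile(stack):
        return quality_profile(stack, radius=radius, corner_size=corner_size)

    # (a) single view, pole up; depth axis = A-V axis = +y, pole first.
    single = render_view(pole_up, optics, shape, pixel_size, plane_spacing, seed=int(seeds[0]))
    prof_single = profile(reslice(single, "y", reverse=True))

    # (b) four tube rotations of the pole-up phantom, fused, then resliced.
    configs = [ViewConfig(tube_rotation=a, label=f"{a:g}deg") for a in tube_angles]
    views = acquire_views(
        pole_up, optics, configs, shape, pixel_size, plane_spacing, seed=int(seeds[1])
    )
    fused = fuse_views(views, [c.total_rotation() for c in configs])
    prof_multi = profile(reslice(fused, "y", reverse=True))

    # (c) single multi-axis view, pole facing the detection objective.
    multi_axis = render_view(
        pole_to_det, optics, shape, pixel_size, plane_spacing, seed=int(seeds[2])
    )
    prof_axis = profile(multi_axis)

    return ComparisonTable(
        profiles={
            "single_view": prof_single,
            "multi_view": prof_multi,
            "multi_axis": prof_axis,
        },
        cap_depth_um=cap_depth(phantom),
    )
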