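"""Depth-resolved image quality from masked local entropy.

The pipeline, applied to a stack plane by plane:

1. maximum projection of the stack;
2. background threshold = worst-corner (mean + 3*SD) over four corner
   sub-images of the projection;
3. per-plane foreground mask (strictly above the background threshold);
4. local Shannon entropy (bits) over a disk neighbourhood of the
   256-level quantised plane;
5. plane score = sum of masked entropy / number of foreground pixels;
6. z = 0 boundary = first plane with any pixel strictly above the Otsu
   threshold of the projection; planes with no such pixel are omitted.

Quantisation uses 256 levels spanning the stack's global min-max range;
the standard deviation is the population estimate; disk neighbourhoods
are cropped to valid pixels at image borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import disk as _disk

from .errors import BoundaryNotFoundError, InvalidInputError
from .phantom import ImageStack

__all__ = [
    "BackgroundModel",
    "PlaneScore",
    "QualityProfile",
    "max_projection",
    "background_model",
    "foreground_mask",
    "quantize",
    "local_entropy",
    "plane_score",
    "boundary_plane",
    "quality_profile",
]

QUANTIZATION_LEVELS = 256
CORNER_ORDER = ("top_left", "top_right", "bottom_left", "bottom_right")


@dataclass(frozen=True)
class BackgroundModel:
    """Per-corner background statistics and the resulting foreground threshold."""

    corner_stats: tuple  # four (mean, sd) pairs in CORNER_ORDER
    threshold: float
    corner_size: int

    def __post_init__(self):
        if len(self.corner_stats) != 4:
            raise InvalidInputError("corner_stats must have four entries")


@dataclass(frozen=True)
class PlaneScore:
    z_index: int
    depth_um: float
    score: float  # NaN when omitted
    omitted: bool


@dataclass(frozen=True)
class QualityProfile:
    """Per-plane quality scores aligned to the detected z = 0 boundary."""

    plane_scores: Sequence[PlaneScore]
    z0_index: int
    otsu_threshold: float
    background: BackgroundModel
    plane_spacing: float

    def scores(self) -> np.ndarray:
        """Scores for all planes from z0 on (NaN where omitted)."""
        return np.array([p.score for p in self.plane_scores])

    def depths(self) -> np.ndarray:
        return np.array([p.depth_um for p in self.plane_scores])

    def valid(self) -> np.ndarray:
        return np.array([not p.omitted for p in self.plane_scores])


def max_projection(stack) -> np.ndarray:
    """Maximum-intensity projection along z."""
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if voxels.ndim != 3 or voxels.size == 0:
        raise InvalidInputError("stack must be a non-empty 3D array")
    return voxels.max(axis=0)


def background_model(projection: np.ndarray, corner_size: int = 100) -> BackgroundModel:
    """Worst-corner background statistics of a projection image.

    Four ``corner_size`` square sub-images are taken flush with the image
    corners; the threshold is the largest ``mean + 3*sd`` among them
    (population SD).  For images smaller than ``corner_size`` per side the
    corner size shrinks to ``floor(min_dim / 2)`` with a warning; corners
    that overlap (image smaller than twice the corner size) also warn.
    """
    img = np.asarray(projection, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("projection must be 2D")
    h, w = img.shape
    cs = int(corner_size)
    if min(h, w) < cs:
        cs = max(min(h, w) // 2, 1)
        warnings.warn(
            f"image smaller than corner_size={corner_size}; shrinking corners to {cs}",
            stacklevel=2,
        )
    elif min(h, w) < 2 * cs:
        warnings.warn("corner sub-images overlap; proceeding anyway", stacklevel=2)

    corners = (
        img[:cs, :cs],
        img[:cs, w - cs :],
        img[h - cs :, :cs],
        img[h - cs :, w - cs :],
    )
    stats = tuple((float(c.mean()), float(c.std())) for c in corners)
    threshold = max(m + 3 * s for m, s in stats)
    return BackgroundModel(corner_stats=stats, threshold=float(threshold), corner_size=cs)


def foreground_mask(plane: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask, true strictly above ``threshold``."""
    return np.asarray(plane) > threshold


def quantize(
    image: np.ndarray,
    vmin: Optional[float] = None,
    vmax: Optional[float] = None,
    levels: int = QUANTIZATION_LEVELS,
) -> np.ndarray:
    """Linearly rescale intensities into ``levels`` integer bins.

    ``vmin``/``vmax`` default to the image's own range; a constant image
    maps to level 0.  Values outside the range are clipped.
    """
    img = np.asarray(image, dtype=float)
    lo = img.min() if vmin is None else float(vmin)
    hi = img.max() if vmax is None else float(vmax)
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * (levels - 1)
    return np.clip(np.rint(scaled), 0, levels - 1).astype(np.uint8)


def local_entropy(
    plane: np.ndarray,
    radius: int = 5,
    vmin: Optional[float] = None,
    vmax: Optional[float] = None,
) -> np.ndarray:
    """Local Shannon entropy (bits) over a digital disk neighbourhood.

    The plane is quantised to 256 levels (over ``vmin``-``vmax`` when
    given, else its own range) and each pixel receives the entropy of the
    quantised-intensity histogram over the disk
    ``{(dy, dx): dy^2 + dx^2 <= radius^2}`` centred on it, cropped to
    valid pixels at the borders.
    """
    if radius < 1:
        raise InvalidInputError("radius must be >= 1")
    q = quantize(plane, vmin=vmin, vmax=vmax)
    return _rank_entropy(q, _disk(radius))


def plane_score(entropy_map: np.ndarray, mask: np.ndarray) -> float:
    """Masked mean entropy; NaN for an empty mask (undefined, never zero)."""
    emap = np.asarray(entropy_map, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if emap.shape != m.shape:
        raise InvalidInputError(f"shape mismatch: {emap.shape} vs {m.shape}")
    n = int(m.sum())
    if n == 0:
        return float("nan")
    return float(emap[m].sum() / n)


def _otsu(projection: np.ndarray) -> float:
    """Otsu threshold over 256 bins spanning the projection's min-max range."""
    img = np.asarray(projection, dtype=float)
    if img.min() == img.max():
        raise BoundaryNotFoundError("projection is constant; no Otsu threshold exists")
    return float(threshold_otsu(img, nbins=QUANTIZATION_LEVELS))


def boundary_plane(stack) -> tuple[int, float]:
    """First plane with any pixel strictly above the projection's Otsu threshold."""
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    thr = _otsu(max_projection(voxels))
    above = (voxels > thr).any(axis=(1, 2))
    if not above.any():
        raise BoundaryNotFoundError("no plane exceeds the Otsu threshold")
    return int(np.argmax(above)), thr


def quality_profile(
    stack,
    radius: int = 5,
    corner_size: int = 100,
    plane_spacing: Optional[float] = None,
) -> QualityProfile:
    """Run the full per-plane quality pipeline on a stack.

    Planes before z0 are not reported; planes at z >= z0 with no pixel
    above the Otsu threshold, or with an empty foreground mask, are
    flagged omitted and carry a NaN score.
    """
    if isinstance(stack, ImageStack):
        voxels = stack.voxels
        spacing = stack.plane_spacing if plane_spacing is None else plane_spacing
    else:
        voxels = np.asarray(stack, dtype=float)
        spacing = 1.0 if plane_spacing is None else plane_spacing

    proj = max_projection(voxels)
    bg = background_model(proj, corner_size=corner_size)
    z0, otsu_thr = boundary_plane(voxels)

    gmin, gmax = float(voxels.min()), float(voxels.max())
    scores = []
    for z in range(z0, voxels.shape[0]):
        plane = voxels[z]
        depth = (z - z0) * spacing
        if not (plane > otsu_thr).any():
            scores.append(PlaneScore(z, depth, float("nan"), True))
            continue
        mask = foreground_mask(plane, bg.threshold)
        emap = local_entropy(plane, radius=radius, vmin=gmin, vmax=gmax)
        s = plane_score(emap, mask)
        scores.append(PlaneScore(z, depth, s, bool(np.isnan(s))))

    return QualityProfile(
        plane_scores=tuple(scores),
        z0_index=z0,
        otsu_threshold=otsu_thr,
        background=bg,
        plane_spacing=spacing,
    )
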