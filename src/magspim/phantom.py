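"""Synthetic embryo phantoms and orientation-dependent SPIM stack rendering.

A phantom is a sphere (the embryo) carrying bright Gaussian nuclei confined
to a polar cap (the blastoderm).  Rendering degrades each nucleus with the
two depth-dependent effects a light-sheet geometry imposes:

* illumination attenuation — blob amplitude is scaled by
  ``exp(-l_illum / attenuation_length)`` where ``l_illum`` is the tissue
  chord from the (nearer) illumination side along the x axis;
* detection blur — blob sigma grows linearly with the tissue path toward
  the detection objective, ``blur_sigma0 + blur_growth * l_det``.

Conventions: the detection axis is z with plane index 0 nearest the
detection objective (depth increases with z); the illumination axis is x;
the vertical sample-tube axis is y.  The voxel grid is centred on the
sphere centre, so rotations about the sphere centre coincide with rotations
about the volume centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._geometry import check_rotation, tissue_path_length
from .errors import InvalidParameterError

__all__ = [
    "EmbryoPhantom",
    "OpticsModel",
    "ImageStack",
    "make_phantom",
    "rotate_phantom",
    "render_view",
]

#: Gaussian sigma of a rendered nucleus as a fraction of its nominal radius.
NUCLEUS_SIGMA_FRACTION = 0.5


@dataclass(frozen=True)
class EmbryoPhantom:
    """Spherical embryo with nuclei confined to a polar cap.

    Positions and sizes are in micrometres; intensities are arbitrary units.
    """

    sphere_center: np.ndarray
    sphere_radius: float
    positions: np.ndarray  # (n, 3) nucleus centres
    radii: np.ndarray  # (n,)
    intensities: np.ndarray  # (n,)
    cap_axis: np.ndarray  # unit vector, animal-vegetal axis
    cap_half_angle: float  # degrees
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sphere_center", np.asarray(self.sphere_center, float))
        object.__setattr__(self, "positions", np.asarray(self.positions, float).reshape(-1, 3))
        object.__setattr__(self, "radii", np.asarray(self.radii, float).reshape(-1))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, float).reshape(-1))
        axis = np.asarray(self.cap_axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise InvalidParameterError("cap_axis must be non-zero")
        object.__setattr__(self, "cap_axis", axis / n)
        self.validate()

    @property
    def n_nuclei(self) -> int:
        return len(self.radii)

    def validate(self) -> None:
        if self.sphere_radius <= 0:
            raise InvalidParameterError("sphere_radius must be positive")
        if not (len(self.positions) == len(self.radii) == len(self.intensities)):
            raise InvalidParameterError("nucleus arrays must have matching lengths")
        if self.n_nuclei == 0:
            return
        if np.any(self.radii <= 0):
            raise InvalidParameterError("nucleus radii must be positive")
        if np.any(self.intensities <= 0):
            raise InvalidParameterError("nucleus peak intensities must be positive")
        rel = self.positions - self.sphere_center
        dist = np.linalg.norm(rel, axis=1)
        if np.any(dist > self.sphere_radius * (1 + 1e-9)):
            raise InvalidParameterError("all nuclei must lie inside the sphere")
        with np.errstate(invalid="ignore"):
            cosang = np.clip((rel @ self.cap_axis) / np.where(dist > 0, dist, 1.0), -1, 1)
        ang = np.degrees(np.arccos(cosang))
        ang[dist == 0] = 0.0  # a nucleus at the centre has no direction
        if np.any(ang > self.cap_half_angle + 1e-9):
            raise InvalidParameterError("all nuclei must lie within the polar cap")


@dataclass(frozen=True)
class OpticsModel:
    """Parameters of the depth-dependent image degradations.

    ``attenuation_length`` may be ``numpy.inf`` for lossless illumination.
    """

    attenuation_length: float = 80.0  # um, 1/e decay of illumination
    blur_sigma0: float = 2.0  # um, blur at zero tissue depth
    blur_growth: float = 0.06  # um blur sigma added per um detection path
    background_mean: float = 100.0
    background_sd: float = 2.0
    dual_sided_illumination: bool = True

    def __post_init__(self):
        if not self.attenuation_length > 0:
            raise InvalidParameterError("attenuation_length must be positive")
        if self.blur_sigma0 < 0 or self.blur_growth < 0:
            raise InvalidParameterError("blur parameters must be non-negative")
        if self.background_sd < 0:
            raise InvalidParameterError("background_sd must be non-negative")


@dataclass(frozen=True)
class ImageStack:
    """3D intensity volume indexed (z, y, x) with physical spacings in um."""

    voxels: np.ndarray
    pixel_size: float
    plane_spacing: float
    z_direction: str = "toward_detection"  # plane 0 is nearest the detection lens

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise InvalidParameterError("voxels must be a non-empty 3D array")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidParameterError("intensities must be finite and non-negative")
        if self.pixel_size <= 0 or self.plane_spacing <= 0:
            raise InvalidParameterError("spacings must be positive")
        object.__setattr__(self, "voxels", v)

    @property
    def shape(self):
        return self.voxels.shape


def make_phantom(
    sphere_radius: float,
    n_nuclei: int,
    cap_half_angle: float,
    seed: int,
    *,
    sphere_center=(0.0, 0.0, 0.0),
    cap_axis=(0.0, 1.0, 0.0),
    shell_fraction=(0.75, 0.95),
    nucleus_radius: float = 8.0,
    nucleus_radius_jitter: float = 0.2,
    peak_intensity: float = 3000.0,
    peak_intensity_jitter: float = 0.2,
) -> EmbryoPhantom:
    """Sample a reproducible phantom with nuclei in a polar shell cap.

    Nucleus directions are drawn uniformly on the spherical cap of
    ``cap_half_angle`` degrees about ``cap_axis`` and radial positions
    uniformly in ``shell_fraction`` of the sphere radius, mimicking a
    blastoderm sitting on the yolk.  Identical arguments give bitwise
    identical phantoms.
    """
    if sphere_radius <= 0:
        raise InvalidParameterError("sphere_radius must be positive")
    if n_nuclei < 0:
        raise InvalidParameterError("n_nuclei must be non-negative")
    if not 0 < cap_half_angle <= 180:
        raise InvalidParameterError("cap_half_angle must be in (0, 180] degrees")

    axis = np.asarray(cap_axis, float)
    axis = axis / np.linalg.norm(axis)
    rng = np.random.default_rng(seed)

    # Uniform directions on the cap: cos(theta) uniform in [cos(alpha), 1].
    cos_alpha = math.cos(math.radians(cap_half_angle))
    cos_theta = rng.uniform(cos_alpha, 1.0, size=n_nuclei)
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n_nuclei)

    # Orthonormal frame (u, v, axis).
    helper = np.array([1.0, 0.0, 0.0])
    if abs(helper @ axis) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    dirs = (
        sin_theta[:, None] * np.cos(phi)[:, None] * u
        + sin_theta[:, None] * np.sin(phi)[:, None] * v
        + cos_theta[:, None] * axis
    )
    lo, hi = shell_fraction
    r = rng.uniform(lo, hi, size=n_nuclei) * sphere_radius
    positions = np.asarray(sphere_center, float) + r[:, None] * dirs

    radii = nucleus_radius * (1 + nucleus_radius_jitter * rng.uniform(-1, 1, n_nuclei))
    intensities = peak_intensity * (1 + peak_intensity_jitter * rng.uniform(-1, 1, n_nuclei))

    return EmbryoPhantom(
        sphere_center=np.asarray(sphere_center, float),
        sphere_radius=float(sphere_radius),
        positions=positions,
        radii=radii,
        intensities=intensities,
        cap_axis=axis,
        cap_half_angle=float(cap_half_angle),
        rng_seed=int(seed),
    )


def _as_matrix(rotation) -> np.ndarray:
    if hasattr(rotation, "as_matrix"):
        rotation = rotation.as_matrix()
    return check_rotation(rotation)


def rotate_phantom(phantom: EmbryoPhantom, rotation) -> EmbryoPhantom:
    """Rotate nuclei and cap axis rigidly about the sphere centre.

    ``rotation`` is a 3x3 proper rotation matrix or a
    ``scipy.spatial.transform.Rotation``.
    """
    m = _as_matrix(rotation)
    rel = phantom.positions - phantom.sphere_center
    return replace(
        phantom,
        positions=phantom.sphere_center + rel @ m.T,
        cap_axis=m @ phantom.cap_axis,
    )


def grid_coordinates(shape, pixel_size: float, plane_spacing: float, center):
    """World coordinates of the voxel-centre axes for a grid centred on ``center``.

    Returns ``(z, y, x)`` 1D arrays in micrometres.
    """
    nz, ny, nx = shape
    c = np.asarray(center, float)  # (x, y, z) ordering for world points
    z = (np.arange(nz) - (nz - 1) / 2) * plane_spacing + c[2]
    y = (np.arange(ny) - (ny - 1) / 2) * pixel_size + c[1]
    x = (np.arange(nx) - (nx - 1) / 2) * pixel_size + c[0]
    return z, y, x


def render_view(
    phantom: EmbryoPhantom,
    optics: OpticsModel,
    shape,
    pixel_size: float,
    plane_spacing: float,
    seed: int,
) -> ImageStack:
    """Render one SPIM acquisition of ``phantom`` under ``optics``.

    The voxel grid is centred on the phantom's sphere centre.  Each nucleus
    is a Gaussian emitter of sigma ``radius * NUCLEUS_SIGMA_FRACTION`` and
    peak ``intensity``, attenuated by ``exp(-l_illum / attenuation_length)``
    and convolved (analytically) with an isotropic Gaussian PSF of sigma
    ``blur_sigma0 + blur_growth * l_det``: the rendered blob has total sigma
    ``sqrt(sigma_n**2 + psf_sigma**2)`` and an energy-conserving peak scaled
    by ``(sigma_n / sigma_total)**3``.  Gaussian background noise is added
    everywhere and the result clipped at zero.
    """
    nz, ny, nx = shape
    if min(nz, ny, nx) < 1:
        raise InvalidParameterError("shape must be positive in every axis")
    if pixel_size <= 0 or plane_spacing <= 0:
        raise InvalidParameterError("spacings must be positive")

    center = phantom.sphere_center
    zax, yax, xax = grid_coordinates(shape, pixel_size, plane_spacing, center)

    vol = np.zeros((nz, ny, nx), dtype=float)

    if phantom.n_nuclei:
        # Tissue path lengths per nucleus (closed-form ray-sphere chords).
        l_det = tissue_path_length(
            phantom.positions, np.array([0.0, 0.0, -1.0]), center, phantom.sphere_radius
        )
        l_neg = tissue_path_length(
            phantom.positions, np.array([-1.0, 0.0, 0.0]), center, phantom.sphere_radius
        )
        if optics.dual_sided_illumination:
            l_pos = tissue_path_length(
                phantom.positions, np.array([1.0, 0.0, 0.0]), center, phantom.sphere_radius
            )
            l_illum = np.minimum(l_neg, l_pos)
        else:
            l_illum = l_neg

        if np.isinf(optics.attenuation_length):
            amp = phantom.intensities.copy()
        else:
            amp = phantom.intensities * np.exp(-l_illum / optics.attenuation_length)
        psf_sigma = optics.blur_sigma0 + optics.blur_growth * l_det
        sigma_n = phantom.radii * NUCLEUS_SIGMA_FRACTION
        sigma = np.sqrt(sigma_n**2 + psf_sigma**2)
        # blur conserves blob energy: convolving the Gaussian emitter with the
        # PSF widens it and dims the peak by (sigma_n / sigma_total)^3
        amp = amp * (sigma_n / sigma) ** 3

        for p, a, s in zip(phantom.positions, amp, sigma):
            _add_blob(vol, zax, yax, xax, p, a, s)

    rng = np.random.default_rng(seed)
    if optics.background_sd > 0:
        vol += rng.normal(optics.background_mean, optics.background_sd, vol.shape)
    else:
        vol += optics.background_mean
    np.clip(vol, 0.0, None, out=vol)
    return ImageStack(vol, pixel_size=pixel_size, plane_spacing=plane_spacing)


def _add_blob(vol, zax, yax, xax, pos, amplitude, sigma, extent: float = 4.0):
    """Accumulate one Gaussian blob into ``vol`` over a +-``extent`` sigma window."""
    px, py, pz = pos
    half = extent * sigma

    # symmetric cutoff: voxels with axis value in [p - half, p + half]
    z0, z1 = np.searchsorted(zax, pz - half, "left"), np.searchsorted(zax, pz + half, "right")
    y0, y1 = np.searchsorted(yax, py - half, "left"), np.searchsorted(yax, py + half, "right")
    x0, x1 = np.searchsorted(xax, px - half, "left"), np.searchsorted(xax, px + half, "right")
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return

    dz2 = ((zax[z0:z1] - pz) ** 2)[:, None, None]
    dy2 = ((yax[y0:y1] - py) ** 2)[None, :, None]
    dx2 = ((xax[x0:x1] - px) ** 2)[None, None, :]
    vol[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-(dz2 + dy2 + dx2) / (2 * sigma**2))
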