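"""Multi-page TIFF stack I/O.

Stacks are written one page per z plane in increasing-z order.  Float
volumes are linearly scaled to 16-bit unsigned range; the scale factor and
physical spacings travel in a JSON ImageDescription tag so reading
restores physical values (up to the documented 16-bit quantisation).
Integer volumes that already fit 16 bits are stored unscaled and
round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidInputError
from .phantom import ImageStack

__all__ = ["read_stack", "write_stack"]

_MAX16 = np.uint16(np.iinfo(np.uint16).max)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page 16-bit TIFF with a JSON metadata tag."""
    vox = stack.voxels
    if np.issubdtype(vox.dtype, np.integer) and vox.max(initial=0) <= int(_MAX16):
        data = vox.astype(np.uint16)
        scale = 1.0
    else:
        vmax = float(vox.max())
        scale = float(_MAX16) / vmax if vmax > 0 else 1.0
        data = np.rint(vox * scale).astype(np.uint16)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "plane_spacing_um": stack.plane_spacing,
        "z_direction": stack.z_direction,
        "intensity_scale": scale,
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_stack(path) -> ImageStack:
    """Read a multi-page grayscale TIFF written by :func:`write_stack`.

    Plain grayscale TIFFs from other sources are accepted too (unit
    spacings, no rescaling).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:  # truncated / not a TIFF
        raise InvalidInputError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise InvalidInputError(f"{path}: expected grayscale planes, got shape {data.shape}")

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    scale = float(meta.get("intensity_scale", 1.0))
    vox = data if scale == 1.0 else data.astype(float) / scale
    return ImageStack(
        vox,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        plane_spacing=float(meta.get("plane_spacing_um", 1.0)),
        z_direction=str(meta.get("z_direction", "toward_detection")),
    )
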