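"""Image and mask file I/O.

Supported inputs: NIfTI volumes (.nii / .nii.gz, with a slice index to pull
a 2-D slice) and sets of grayscale PNGs, one per channel, sorted by name.
PNG intensities are returned normalized by the dtype maximum, so a 16-bit
round trip through :func:`write_channel_pngs` is exact on the 1/65535 grid.
Masks are 8-bit PNGs with {0, 255} encoding.
"""

from __future__ import annotations

import glob
import os
from typing import Optional, Sequence

import imageio.v2 as imageio
import nibabel as nib
import numpy as np

from .errors import DataError

__all__ = [
    "read_image",
    "write_channel_pngs",
    "write_nifti",
    "write_mask",
    "read_mask",
]

_SUPPORTED = ".nii, .nii.gz (NIfTI) or .png channel sets"


def _read_pngs(paths: Sequence[str]) -> np.ndarray:
    channels = []
    for p in sorted(paths):
        arr = np.asarray(imageio.imread(p))
        if arr.ndim != 2:
            raise DataError(f"{p}: expected a grayscale PNG, got shape {arr.shape}")
        maxval = float(np.iinfo(arr.dtype).max) if arr.dtype.kind in "ui" else 1.0
        channels.append(arr.astype(float) / maxval)
    shapes = {c.shape for c in channels}
    if len(shapes) > 1:
        raise DataError(f"channel PNGs disagree in size: {sorted(shapes)}")
    return np.stack(channels)


def read_image(path, slice_index: Optional[int] = None) -> np.ndarray:
    """Read a channels-first (C, H, W) float image.

    ``path`` may be a NIfTI file, a directory of channel PNGs, a glob
    pattern, or an explicit list of PNG paths.
    """
    if isinstance(path, (list, tuple)):
        return _read_pngs([str(p) for p in path])
    path = str(path)
    if os.path.isdir(path):
        # channel files take precedence so a co-located mask.png is not
        # mistaken for a fifth channel
        pngs = sorted(glob.glob(os.path.join(path, "chan_*.png"))) or sorted(
            glob.glob(os.path.join(path, "*.png")))
        if not pngs:
            raise DataError(f"no PNG channels found in {path}")
        return _read_pngs(pngs)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(path).get_fdata())
        if data.ndim == 2:
            return data[None]
        if data.ndim == 3:
            z = data.shape[2] // 2 if slice_index is None else slice_index
            return data[:, :, z][None]
        if data.ndim == 4:
            z = data.shape[2] // 2 if slice_index is None else slice_index
            return np.moveaxis(data[:, :, z, :], -1, 0)
        raise DataError(f"unsupported NIfTI dimensionality {data.ndim}")
    if lower.endswith(".png"):
        return _read_pngs([path])
    if any(ch in path for ch in "*?["):
        pngs = sorted(glob.glob(path))
        if not pngs:
            raise DataError(f"glob {path!r} matched no files")
        return _read_pngs(pngs)
    raise DataError(f"unknown image format for {path!r}; supported: {_SUPPORTED}")


def write_channel_pngs(directory, image: np.ndarray, prefix: str = "chan") -> list:
    """Write a (C, H, W) image in [0, 1] as 16-bit grayscale PNGs."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise DataError("expected a (C, H, W) image")
    if img.min() < 0 or img.max() > 1:
        raise DataError("PNG export expects intensities in [0, 1]")
    os.makedirs(directory, exist_ok=True)
    paths = []
    for t, chan in enumerate(img):
        p = os.path.join(directory, f"{prefix}_{t:02d}.png")
        imageio.imwrite(p, np.round(chan * 65535).astype(np.uint16))
        paths.append(p)
    return paths


def write_nifti(path, image: np.ndarray) -> None:
    """Write a (C, H, W) image as an (H, W, 1, C) NIfTI volume."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3:
        raise DataError("expected a (C, H, W) image")
    vol = np.moveaxis(img, 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with {0, 255} values."""
    m = np.asarray(mask)
    if m.dtype != bool and not np.all(np.isin(m, (0, 1))):
        raise DataError("mask must be binary")
    imageio.imwrite(str(path), (m.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    """Read a mask PNG; values above 127 map to 1."""
    arr = np.asarray(imageio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)
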