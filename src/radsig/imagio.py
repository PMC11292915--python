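"""Medical image I/O and tumor-crop preprocessing.

Axis convention: all in-memory grids are indexed ``(slice, row, column)``
(z, y, x), 0-based. ``spacing`` is stored in the same axis order, in mm.
SimpleITK handles DICOM series and NIfTI on disk; its array view already
matches this convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "AlignmentError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "minmax_normalize",
    "largest_tumor_slice",
    "crop_resize",
]


class AlignmentError(ValueError):
    """Raised when a mask does not geometrically match its volume."""


@dataclass
class ImageVolume:
    """A 3D intensity grid in Hounsfield-like units.

    Parameters
    ----------
    data : ndarray, shape (n_slices, n_rows, n_cols)
        Intensities, float.
    spacing : tuple of float
        Voxel spacing in mm, ``(slice, row, column)`` order.
    origin : tuple of float
        Physical origin in mm (same order).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = field(default="zyx", repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SegmentationMask:
    """Binary tumor mask aligned voxel-for-voxel with an :class:`ImageVolume`."""

    data: np.ndarray
    observer: str = "obs1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        if not self.data.any():
            raise ValueError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())


def _sitk_to_volume(img: sitk.Image) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    sp = img.GetSpacing()  # (x, y, z)
    og = img.GetOrigin()
    return ImageVolume(arr, spacing=(sp[2], sp[1], sp[0]), origin=(og[2], og[1], og[0]))


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a DICOM series directory or a NIfTI file into an ImageVolume."""
    path = os.fspath(path)
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        names = reader.GetGDCMSeriesFileNames(path)
        if not names:
            raise FileNotFoundError(f"no DICOM series found in {path!r}")
        reader.SetFileNames(names)
        return _sitk_to_volume(reader.Execute())
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return _sitk_to_volume(sitk.ReadImage(path))


def read_mask(path: str | os.PathLike, volume: ImageVolume, observer: str = "obs1") -> SegmentationMask:
    """Read a mask and validate geometry against its volume."""
    raw = read_volume(path)
    if raw.shape != volume.shape:
        raise AlignmentError(
            f"mask shape {raw.shape} does not match volume shape {volume.shape}"
        )
    if not np.allclose(raw.spacing, volume.spacing, rtol=1e-4):
        raise AlignmentError(
            f"mask spacing {raw.spacing} does not match volume spacing {volume.spacing}"
        )
    return SegmentationMask(raw.data > 0.5, observer=observer)


def _volume_to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing((spacing[2], spacing[1], spacing[0]))
    img.SetOrigin((origin[2], origin[1], origin[0]))
    return img


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write an ImageVolume as NIfTI (extension decides the format)."""
    sitk.WriteImage(_volume_to_sitk(volume.data, volume.spacing, volume.origin), os.fspath(path))


def write_mask(mask: SegmentationMask, volume: ImageVolume, path: str | os.PathLike) -> None:
    data = mask.data.astype(np.uint8)
    sitk.WriteImage(_volume_to_sitk(data, volume.spacing, volume.origin), os.fspath(path))


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affine rescale into [-1, 1]: ``2 (x - min) / (max - min) - 1``.

    The minimum maps exactly to -1 and the maximum to +1.  Raises on a
    constant grid, whose range is degenerate.
    """
    x = np.asarray(values, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("cannot min-max normalize a constant grid (max == min)")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def largest_tumor_slice(mask: SegmentationMask) -> int:
    """Index of the axial slice with the most foreground voxels.

    Ties go to the lowest slice index.  Depends only on the mask, never on
    intensities.
    """
    areas = mask.data.reshape(mask.shape[0], -1).sum(axis=1)
    if areas.sum() == 0:
        raise ValueError("mask is empty")
    return int(np.argmax(areas))


def crop_resize(
    slice2d: np.ndarray,
    mask_slice: np.ndarray,
    out_size: int = 224,
    margin_px: int = 8,
) -> np.ndarray:
    """Crop a 2D slice to the mask bounding box (+margin) and resize.

    Bilinear interpolation with the half-pixel-center convention: output
    pixel ``i`` samples input coordinate ``(i + 0.5) * scale - 0.5``,
    clamped at the borders.  A constant crop therefore stays constant.
    """
    img = np.asarray(slice2d, dtype=np.float64)
    m = np.asarray(mask_slice).astype(bool)
    if img.shape != m.shape:
        raise ValueError("slice and mask slice shapes differ")
    if not m.any():
        raise ValueError("mask slice has no foreground pixels")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0 = max(rows[0] - margin_px, 0)
    r1 = min(rows[-1] + margin_px + 1, img.shape[0])
    c0 = max(cols[0] - margin_px, 0)
    c1 = min(cols[-1] + margin_px + 1, img.shape[1])
    crop = img[r0:r1, c0:c1]

    h, w = crop.shape
    ri = (np.arange(out_size) + 0.5) * (h / out_size) - 0.5
    ci = (np.arange(out_size) + 0.5) * (w / out_size) - 0.5
    rr, cc = np.meshgrid(ri, ci, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    out = ndimage.map_coordinates(crop, coords, order=1, mode="nearest")
    return out.reshape(out_size, out_size)
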