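"""Volume and mask data model with NIfTI / MetaImage readers and writers.

The internal axis convention is fixed at (z, y, x) with z the axial slice
axis; spacing and origin tuples follow the same order.  Calcium scoring is
defined per axial slice, so keeping one convention throughout the package
avoids silent transposition between the image grid and the score.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

HU_MIN = -1024.0
HU_MAX = 3071.0

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class CTVolume:
    """A 3D scalar field of Hounsfield units on an anisotropic grid.

    Parameters
    ----------
    data
        3D array of HU values, axes ordered (z, y, x): slice, row, column.
    spacing
        Voxel spacing (dz, dy, dx) in millimetres; all components > 0.
    origin
        Physical position (z, y, x) of the first voxel centre, in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane (axial) pixel area dy*dx in mm^2."""
        return self.spacing[1] * self.spacing[2]

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) (z,y,x) grid indices to mm coordinates."""
        return np.asarray(index, float) * np.array(self.spacing) + np.array(self.origin)

    def physical_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(point_mm, float) - np.array(self.origin)) / np.array(self.spacing)


@dataclass
class VoxelMask:
    """Binary voxel membership on the same grid as a parent :class:`CTVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @classmethod
    def like(cls, volume: CTVolume, data: np.ndarray | None = None) -> "VoxelMask":
        if data is None:
            data = np.zeros(volume.shape, bool)
        if data.shape != volume.shape:
            raise ValueError("mask shape must match parent volume")
        return cls(data=data, spacing=volume.spacing, origin=volume.origin)

    def volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return float(self.data.sum()) * dz * dy * dx


def _check_path(path: str | os.PathLike) -> str:
    path = os.fspath(path)
    low = path.lower()
    if not any(low.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported image format for {path!r}; expected one of {_SUPPORTED_SUFFIXES}"
        )
    return path


def load_volume(path: str | os.PathLike, clip_hu: bool = True) -> CTVolume:
    """Read a NIfTI or MetaImage scalar volume as a :class:`CTVolume`.

    Spacing and origin are taken from the image header (reordered from the
    ITK (x,y,z) convention to (z,y,x)).  HU values outside [-1024, 3071] are
    clipped with a logged warning: low-dose reconstructions routinely
    overshoot the nominal range and rejecting them would refuse real scans.

    Raises
    ------
    IOError
        If the file does not exist or cannot be read.
    ValueError
        If the image is not a 3D scalar volume.
    """
    path = _check_path(path)
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise IOError(f"could not read image {path}: {exc}") from exc
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(
            f"{path}: expected a 3D scalar volume, got dimension "
            f"{img.GetDimension()} with {img.GetNumberOfComponentsPerPixel()} components"
        )
    data = sitk.GetArrayFromImage(img)  # already (z, y, x)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.int16) if data.dtype.itemsize <= 2 else data.astype(np.int32)
    if clip_hu and (data.min() < HU_MIN or data.max() > HU_MAX):
        logger.warning(
            "%s: HU range [%s, %s] outside [%s, %s]; clipping",
            path, data.min(), data.max(), HU_MIN, HU_MAX,
        )
        data = np.clip(data, HU_MIN, HU_MAX)
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    return CTVolume(data=data, spacing=(sz, sy, sx), origin=(oz, oy, ox))


def save_volume(volume: CTVolume | VoxelMask, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI / MetaImage; masks as unsigned 8-bit.

    The written file round-trips through :func:`load_volume` (or
    :func:`load_mask`) with identical data, spacing and origin.
    """
    path = _check_path(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    data = volume.data
    if isinstance(volume, VoxelMask):
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(data)
    dz, dy, dx = volume.spacing
    oz, oy, ox = volume.origin
    img.SetSpacing((dx, dy, dz))
    img.SetOrigin((ox, oy, oz))
    try:
        sitk.WriteImage(img, path)
    except RuntimeError as exc:
        raise IOError(f"could not write image {path}: {exc}") from exc


def load_mask(path: str | os.PathLike) -> VoxelMask:
    vol = load_volume(path, clip_hu=False)
    return VoxelMask(data=vol.data != 0, spacing=vol.spacing, origin=vol.origin)
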