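"""NIfTI volume/mask containers, Hounsfield windowing and grid standardisation.

Array axes follow NIfTI i,j,k order with 0-based indices; world coordinates
are carried by the 4x4 affine (voxel spacing on its diagonal for the
axis-aligned volumes this package produces). Intensities are either raw
Hounsfield units (HU) or fixed-window normalised values in [0, 1]: the
normalisation map is global, ``x -> (x - lo) / (hi - lo)`` with the same
window for every volume, so intensity scale is comparable across cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

HU_WINDOW = (-1000.0, 2000.0)


def _spacing_affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class CBCTVolume:
    """A 3D scalar intensity grid with voxel spacing (mm) and affine."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    affine: np.ndarray | None = None
    units: str = "HU"  # "HU" | "normalized"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all volume extents must be >= 1")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.affine is None:
            self.affine = _spacing_affine(self.spacing_mm)
        if self.units not in ("HU", "normalized"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "normalized":
            dmin, dmax = float(self.data.min()), float(self.data.max())
            if dmin < -1e-6 or dmax > 1 + 1e-6:
                raise ValueError(
                    f"normalized volume outside [0,1]: [{dmin}, {dmax}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask3D:
    """A boolean grid co-registered with a :class:`CBCTVolume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got {arr.ndim}D")
        if min(arr.shape) < 1:
            raise ValueError("all mask extents must be >= 1")
        if arr.dtype != bool:
            arr = arr > 0
        self.data = arr
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.affine is None:
            self.affine = _spacing_affine(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing_mm))


def read_nifti(path, as_mask: bool = False):
    """Read a single-file NIfTI image as a volume or (thresholded > 0) mask."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if as_mask:
        return BinaryMask3D(data > 0, spacing, np.asarray(img.affine))
    return CBCTVolume(data.astype(np.float32), spacing,
                      np.asarray(img.affine))


def write_nifti(obj, path) -> None:
    """Write a volume (float32) or mask (uint8 {0,1}, label intent)."""
    path = Path(path)
    if isinstance(obj, BinaryMask3D):
        img = nib.Nifti1Image(obj.data.astype(np.uint8), obj.affine)
        img.header.set_intent("label")
    elif isinstance(obj, CBCTVolume):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img.header.set_zooms(obj.spacing_mm)
    nib.save(img, str(path))


def window_hu(vol: CBCTVolume, lo: float = HU_WINDOW[0],
              hi: float = HU_WINDOW[1]) -> CBCTVolume:
    """Clip HU intensities to [lo, hi] (skeletal-structure window)."""
    if vol.units != "HU":
        raise ValueError("window_hu expects a volume in HU")
    if lo >= hi:
        raise ValueError(f"degenerate window [{lo}, {hi}]")
    return CBCTVolume(np.clip(vol.data, lo, hi), vol.spacing_mm,
                      vol.affine.copy(), "HU")


def normalize_intensity(vol: CBCTVolume, lo: float = HU_WINDOW[0],
                        hi: float = HU_WINDOW[1]) -> CBCTVolume:
    """Map the windowed HU range affinely onto [0, 1]."""
    if vol.units != "HU":
        raise ValueError("normalize_intensity expects a volume in HU")
    if lo >= hi:
        raise ValueError(f"degenerate window [{lo}, {hi}]")
    data = (np.clip(vol.data, lo, hi) - lo) / (hi - lo)
    return CBCTVolume(data.astype(np.float32), vol.spacing_mm,
                      vol.affine.copy(), "normalized")


def standardize_grid(obj, target_shape):
    """Resample to a fixed grid, preserving physical extent.

    Intensities are interpolated trilinearly, masks nearest-neighbour (so
    they stay strictly binary). Spacing is rescaled by old/new extent.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or min(target_shape) < 1:
        raise ValueError(f"bad target shape {target_shape}")
    src_shape = obj.shape
    if target_shape == tuple(src_shape):
        return obj
    factors = [t / s for t, s in zip(target_shape, src_shape)]
    new_spacing = tuple(sp * s / t for sp, s, t in
                        zip(obj.spacing_mm, src_shape, target_shape))
    if isinstance(obj, BinaryMask3D):
        out = ndimage.zoom(obj.data.astype(np.uint8), factors, order=0,
                           mode="grid-constant", grid_mode=True)
        return BinaryMask3D(out > 0, new_spacing)
    out = ndimage.zoom(obj.data.astype(np.float32), factors, order=1,
                       mode="nearest", grid_mode=True)
    return CBCTVolume(np.clip(out, obj.data.min(), obj.data.max())
                      if obj.units == "normalized" else out,
                      new_spacing, units=obj.units)
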