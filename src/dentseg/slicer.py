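"""2.5D decomposition: volume -> 2D slices -> per-slice predictions -> volume.

A volume is cut along one or more grid axes into :class:`SliceRecord`
objects carrying exact provenance (source axis, index, native in-plane
shape), so a complete single-axis stack can be reassembled voxel-exactly.
Slice pixel ordering is row-major in the two remaining axes taken in
ascending axis order. Predictions from several axes can be fused by
voxel-wise averaging or majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize as _sk_resize

from .volume_io import BinaryMask3D, CBCTVolume


@dataclass
class SliceRecord:
    image: np.ndarray            # 2D
    axis: int                    # source axis in {0, 1, 2}
    index: int                   # slice index along that axis
    native_shape: tuple[int, int]
    case_id: str = ""
    is_mask: bool = False
    resized: bool = False

    def __post_init__(self):
        if self.image.ndim != 2:
            raise ValueError("slice image must be 2D")
        if self.axis not in (0, 1, 2):
            raise ValueError(f"axis must be in {{0,1,2}}, got {self.axis}")
        self.native_shape = tuple(int(v) for v in self.native_shape)


@dataclass
class SliceStack:
    records: list[SliceRecord]
    source_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def slice_volume(obj: CBCTVolume | BinaryMask3D, axes=(0, 1, 2),
                 case_id: str = "") -> SliceStack:
    """Cut a volume/mask into 2D slices along each requested axis."""
    axes = sorted(set(int(a) for a in np.atleast_1d(list(axes))))
    if not axes:
        raise ValueError("axes set must be non-empty")
    if any(a not in (0, 1, 2) for a in axes):
        raise ValueError(f"axes must be a subset of {{0,1,2}}, got {axes}")
    data = obj.data
    is_mask = isinstance(obj, BinaryMask3D)
    records = []
    for axis in axes:
        moved = np.moveaxis(data, axis, 0)
        native = moved.shape[1:]
        for idx in range(moved.shape[0]):
            records.append(SliceRecord(image=np.ascontiguousarray(moved[idx]),
                                       axis=axis, index=idx,
                                       native_shape=native,
                                       case_id=case_id, is_mask=is_mask))
    return SliceStack(records, tuple(data.shape), obj.spacing_mm)


def resize_slice(rec: SliceRecord, target=(24, 24)) -> SliceRecord:
    """Resize to the network grid: bilinear for images, nearest for masks."""
    target = tuple(int(t) for t in target)
    if min(target) < 1:
        raise ValueError(f"bad target shape {target}")
    if rec.image.shape == target:
        return rec
    if rec.is_mask:
        out = _sk_resize(rec.image.astype(np.float32), target, order=0,
                         preserve_range=True, anti_aliasing=False) > 0.5
    else:
        out = _sk_resize(rec.image.astype(np.float32), target, order=1,
                         preserve_range=True, anti_aliasing=False)
    return replace(rec, image=out.astype(rec.image.dtype if rec.is_mask
                                         else np.float32), resized=True)


def restore_slice(rec: SliceRecord) -> SliceRecord:
    """Resize a (probability) slice back to its native in-plane shape."""
    if rec.native_shape is None:
        raise ValueError("record carries no native-shape provenance")
    if rec.image.shape == rec.native_shape:
        return rec
    out = _sk_resize(rec.image.astype(np.float32), rec.native_shape, order=1,
                     preserve_range=True, anti_aliasing=False)
    return replace(rec, image=np.clip(out, 0.0, 1.0).astype(np.float32),
                   resized=False)


def stack_slices(stack: SliceStack) -> np.ndarray:
    """Reassemble a complete single-axis stack into a 3D array.

    Record order is irrelevant: voxels are placed by index provenance.
    Raises on a missing or duplicated index, naming it.
    """
    if not stack.records:
        raise ValueError("empty stack")
    axes = {r.axis for r in stack.records}
    if len(axes) != 1:
        raise ValueError(f"stack mixes axes {sorted(axes)}")
    axis = axes.pop()
    extent = stack.source_shape[axis]
    native = tuple(e for a, e in enumerate(stack.source_shape) if a != axis)
    out = np.empty((extent,) + native,
                   dtype=stack.records[0].image.dtype)
    seen = np.zeros(extent, dtype=bool)
    for rec in stack.records:
        if not 0 <= rec.index < extent:
            raise ValueError(f"slice index {rec.index} outside 0..{extent-1}")
        if seen[rec.index]:
            raise ValueError(f"duplicate slice index {rec.index}")
        if rec.image.shape != native:
            raise ValueError(
                f"slice {rec.index} has shape {rec.image.shape}, "
                f"expected native {native}")
        out[rec.index] = rec.image
        seen[rec.index] = True
    missing = np.where(~seen)[0]
    if missing.size:
        raise ValueError(f"missing slice index {missing[0]}")
    return np.moveaxis(out, 0, axis)


def fuse_axis_predictions(per_axis_volumes, mode: str = "single_axis",
                          designated: int = 0,
                          threshold: float = 0.5) -> np.ndarray:
    """Fuse 1-3 co-registered probability volumes into one.

    ``single_axis`` returns the designated volume; ``mean`` averages
    voxel-wise; ``majority`` votes on per-axis binarisations at
    ``threshold`` with ties broken toward foreground.
    """
    vols = [np.asarray(v) for v in per_axis_volumes]
    if not vols:
        raise ValueError("no volumes to fuse")
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"volumes disagree in shape: {shapes}")
    if mode == "single_axis":
        return vols[designated]
    if mode == "mean":
        return np.mean(vols, axis=0)
    if mode == "majority":
        votes = np.sum([v >= threshold for v in vols], axis=0)
        return (votes >= (len(vols) + 1) // 2).astype(np.float32)
    raise ValueError(f"unknown fusion mode {mode!r}")
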