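"""Segmentation evaluation: overlap, surface-distance and volume metrics.

Conventions
-----------
* ``A`` is the ground truth, ``B`` the prediction; both binary grids of
  equal shape.
* Boundary voxels are foreground voxels with at least one face-adjacent
  (6-connected) background neighbour inside the grid.
* Distances are Euclidean between boundary voxel centres, scaled by the
  voxel spacing when ``units_mode="mm"`` (the default) and unscaled in
  ``"voxel"`` mode. ``msd`` follows the squared-distance form
  ``(1/N) * sum(d^2)``; the conventional mean absolute surface distance is
  additionally reported as ``masd``. ``hd95`` is the 95th percentile
  (linear interpolation) of the symmetric distance multiset.
* Volumetric similarity ``vs`` is the volumetric *dissimilarity*
  ``|FN - FP| / (2 TP + FP + FN)``: 0 for identical volumes, 1 for
  disjoint ones.
* ``volume_error_rate`` is ``| |B| - |A| | / |A| * 100`` (percent).

Metrics whose denominator vanishes are flagged in
``MetricsReport.flags`` and set to ``nan`` rather than silently zeroed;
Dice/Jaccard of two empty masks are defined as 1.0 (perfect agreement)
with a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

#: report column order (the conventional 12-column layout)
REPORT_COLUMNS = ["dice", "jaccard", "precision", "recall", "fpr", "fnr",
                  "vs", "hd", "msd", "stdsd", "hd95", "volume_error_rate"]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


class EmptyMaskError(ValueError):
    """Surface metrics are undefined for an empty mask."""


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class SurfaceDistanceSet:
    distances: np.ndarray
    direction: str  # "A_to_B" | "B_to_A" | "symmetric"

    @property
    def n(self) -> int:
        return int(self.distances.size)


@dataclass
class MetricsReport:
    dice: float
    jaccard: float
    precision: float
    recall: float
    fpr: float
    fnr: float
    vs: float
    hd: float
    msd: float
    stdsd: float
    hd95: float
    volume_error_rate: float
    masd: float = float("nan")
    units_mode: str = "mm"
    flags: dict = field(default_factory=dict)

    def to_row(self) -> list[float]:
        return [getattr(self, c) for c in REPORT_COLUMNS]

    def to_dict(self) -> dict:
        d = {c: getattr(self, c) for c in REPORT_COLUMNS}
        d["masd"] = self.masd
        d["units_mode"] = self.units_mode
        return d


def _as_bool(a) -> np.ndarray:
    a = a.data if hasattr(a, "data") and hasattr(a, "spacing_mm") else a
    a = np.asarray(a)
    return a.astype(bool) if a.dtype != bool else a


def _pair(a, b):
    A, B = _as_bool(a), _as_bool(b)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    return A, B


def confusion_counts(a, b) -> ConfusionCounts:
    A, B = _pair(a, b)
    tp = int(np.count_nonzero(A & B))
    fp = int(np.count_nonzero(~A & B))
    fn = int(np.count_nonzero(A & ~B))
    tn = int(A.size - tp - fp - fn)
    return ConfusionCounts(tp, fp, fn, tn)


def dice(a, b) -> float:
    A, B = _pair(a, b)
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((A & B).sum()) / (na + nb)


def jaccard(a, b) -> float:
    A, B = _pair(a, b)
    union = int((A | B).sum())
    if union == 0:
        warnings.warn("Jaccard of two empty masks defined as 1.0")
        return 1.0
    return int((A & B).sum()) / union


def precision(a, b) -> float:
    c = confusion_counts(a, b)
    if c.tp + c.fp == 0:
        return float("nan")
    return c.tp / (c.tp + c.fp)


def recall(a, b) -> float:
    c = confusion_counts(a, b)
    if c.tp + c.fn == 0:
        return float("nan")
    return c.tp / (c.tp + c.fn)


def fpr(a, b) -> float:
    c = confusion_counts(a, b)
    if c.fp + c.tn == 0:
        return float("nan")
    return c.fp / (c.fp + c.tn)


def fnr(a, b) -> float:
    c = confusion_counts(a, b)
    if c.tp + c.fn == 0:
        return float("nan")
    return c.fn / (c.tp + c.fn)


def volumetric_similarity(a, b) -> float:
    """Volumetric dissimilarity |FN - FP| / (2 TP + FP + FN); 0 = identical."""
    c = confusion_counts(a, b)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 0.0
    return abs(c.fn - c.fp) / denom


def boundary_voxels(mask) -> np.ndarray:
    """Indices (k, 3) of foreground voxels with an in-grid 6-neighbour
    background voxel."""
    M = _as_bool(mask)
    eroded = ndimage.binary_erosion(M, structure=_FACE_STRUCT,
                                    border_value=1)
    return np.argwhere(M & ~eroded)


def _spacing_of(a, spacing):
    if spacing is not None:
        return tuple(float(s) for s in spacing)
    if hasattr(a, "spacing_mm"):
        return tuple(float(s) for s in a.spacing_mm)
    return (1.0, 1.0, 1.0)


def surface_distances(a, b, spacing=None,
                      direction: str = "symmetric") -> SurfaceDistanceSet:
    """Nearest-boundary distances between two masks.

    For each boundary voxel of the source, the minimum Euclidean distance
    (voxel centres scaled by ``spacing``) to any boundary voxel of the
    target; ``symmetric`` pools both directions.
    """
    A, B = _pair(a, b)
    if not A.any() or not B.any():
        raise EmptyMaskError("surface distances undefined for empty masks")
    sp = np.asarray(_spacing_of(a, spacing))
    pa = boundary_voxels(A) * sp
    pb = boundary_voxels(B) * sp
    if len(pa) == 0 or len(pb) == 0:
        # an all-foreground grid has no in-grid boundary
        raise EmptyMaskError("a mask has no boundary voxels")
    if direction == "A_to_B":
        d = cKDTree(pb).query(pa)[0]
    elif direction == "B_to_A":
        d = cKDTree(pa).query(pb)[0]
    elif direction == "symmetric":
        d = np.concatenate([cKDTree(pb).query(pa)[0],
                            cKDTree(pa).query(pb)[0]])
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return SurfaceDistanceSet(np.asarray(d, dtype=float), direction)


def hausdorff(a, b, spacing=None) -> float:
    """max(h(A,B), h(B,A)) over directed maximum boundary distances."""
    dab = surface_distances(a, b, spacing, "A_to_B").distances
    dba = surface_distances(a, b, spacing, "B_to_A").distances
    return float(max(dab.max(), dba.max()))


def msd(a, b, spacing=None) -> float:
    """Mean squared symmetric surface distance, (1/N) * sum(d^2)."""
    d = surface_distances(a, b, spacing).distances
    return float(np.mean(d ** 2))


def masd(a, b, spacing=None) -> float:
    """Conventional mean absolute symmetric surface distance."""
    d = surface_distances(a, b, spacing).distances
    return float(np.mean(d))


def stdsd(a, b, spacing=None) -> float:
    """Population standard deviation of the symmetric surface distances."""
    d = surface_distances(a, b, spacing).distances
    return float(np.sqrt(np.mean((d - d.mean()) ** 2)))


def hd95(a, b, spacing=None) -> float:
    """95th percentile (linear interpolation) of the symmetric distances."""
    d = surface_distances(a, b, spacing).distances
    return float(np.percentile(d, 95.0))


def volume_error_rate(a, b) -> float:
    """| |B| - |A| | / |A| in percent."""
    A, B = _pair(a, b)
    na = int(A.sum())
    if na == 0:
        return float("nan")
    return abs(int(B.sum()) - na) / na * 100.0


def full_report(a, b, spacing=None, units_mode: str = "mm") -> MetricsReport:
    """All 12 metrics for one (ground truth, prediction) pair.

    ``units_mode="voxel"`` ignores spacing for the distance metrics.
    Undefined metrics are flagged and set to nan, except Dice/Jaccard of
    two empty masks (1.0, flagged) and the distance block for an empty
    mask (nan, flagged).
    """
    A, B = _pair(a, b)
    if units_mode not in ("mm", "voxel"):
        raise ValueError(f"unknown units_mode {units_mode!r}")
    sp = ((1.0, 1.0, 1.0) if units_mode == "voxel"
          else _spacing_of(a, spacing))
    flags: dict[str, str] = {}
    c = confusion_counts(A, B)

    def guarded(num, den, name):
        if den == 0:
            flags[name] = "undefined (zero denominator)"
            return float("nan")
        return num / den

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dc, jc = dice(A, B), jaccard(A, B)
    if c.tp + c.fp + c.fn == 0:
        flags["dice"] = flags["jaccard"] = "both masks empty; defined as 1.0"
    vals = dict(
        dice=dc, jaccard=jc,
        precision=guarded(c.tp, c.tp + c.fp, "precision"),
        recall=guarded(c.tp, c.tp + c.fn, "recall"),
        fpr=guarded(c.fp, c.fp + c.tn, "fpr"),
        fnr=guarded(c.fn, c.tp + c.fn, "fnr"),
        vs=volumetric_similarity(A, B),
    )
    try:
        if not A.any() or not B.any():
            raise EmptyMaskError("empty mask")
        spv = np.asarray(sp)
        pa = boundary_voxels(A) * spv
        pb = boundary_voxels(B) * spv
        if len(pa) == 0 or len(pb) == 0:
            raise EmptyMaskError("no boundary voxels")
        ta, tb = cKDTree(pa), cKDTree(pb)
        dab = tb.query(pa)[0]
        dba = ta.query(pb)[0]
        d = np.concatenate([dab, dba])
        vals.update(hd=float(max(dab.max(), dba.max())),
                    msd=float(np.mean(d ** 2)),
                    stdsd=float(np.sqrt(np.mean((d - d.mean()) ** 2))),
                    hd95=float(np.percentile(d, 95.0)))
        extra_masd = float(np.mean(d))
    except EmptyMaskError:
        flags["surface"] = "empty mask or boundary; surface metrics undefined"
        vals.update(hd=float("nan"), msd=float("nan"),
                    stdsd=float("nan"), hd95=float("nan"))
        extra_masd = float("nan")
    ver = volume_error_rate(A, B)
    if np.isnan(ver):
        flags["volume_error_rate"] = "empty ground truth"
    return MetricsReport(**vals, volume_error_rate=ver, masd=extra_masd,
                         units_mode=units_mode, flags=flags)
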