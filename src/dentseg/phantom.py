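"""Synthetic dental-CBCT jaw phantoms with paired ground-truth masks.

Each phantom is a simplified lower jaw: a horizontal bone slab (the
alveolar ridge) carrying an arch of tooth-like cylinders whose roots are
embedded in the slab, with exactly one tooth missing. Two ground-truth
masks accompany the intensity volume:

* the **missing-tooth bone region** — the block of slab bone spanning the
  edentulous gap plus a configurable margin on each side, the target of
  the first segmentation stage;
* the **implant ROI** — an axis-aligned cylinder of standard implant
  dimensions (default 4.1 mm diameter x 10 mm length) seated in that gap
  with its axis along the slab normal (grid axis 2), the target of the
  second stage.

Intensities are region-wise Hounsfield plateaus (air, soft tissue, bone,
enamel) plus i.i.d. Gaussian noise, clipped to the skeletal window
[-1000, 2000] HU so that windowing is the identity on phantoms. A voxel
belongs to a solid iff its centre lies inside the continuous solid, which
makes voxel-count oracles exact.

The generator emulates the statistical shape of a standardized clinical
CBCT cohort (fixed grid, ~0.3 mm spacing, one edentulous site per scan,
mild anatomical variation); it does not attempt photorealism (no beam
hardening, scatter or metal artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .volume_io import BinaryMask3D, CBCTVolume, write_nifti

DEFAULT_HU_LEVELS = {
    "air": -1000.0,
    "soft_tissue": 40.0,
    "bone": 1100.0,
    "tooth": 1900.0,
}


class GeometryError(ValueError):
    """A phantom solid does not fit the requested grid."""


@dataclass
class PhantomSpec:
    """Full geometric and radiometric description of one phantom.

    Lengths are in mm. ``missing_tooth_index`` selects which arch position
    is edentulous. ``gap_margin_tooth_widths`` is the margin of the
    bone-region ground truth on each side of the gap, in units of one
    tooth width (2 x ``tooth_radius_mm``).
    """

    grid_shape: tuple[int, int, int] = (79, 112, 135)
    voxel_spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    arch_radius_mm: float = 9.0
    n_teeth: int = 6
    tooth_radius_mm: float = 1.5
    tooth_height_mm: float = 7.0
    root_depth_mm: float = 11.0
    slab_thickness_mm: float = 13.0
    missing_tooth_index: int = 2
    implant_diameter_mm: float = 4.1
    implant_length_mm: float = 10.0
    gap_margin_tooth_widths: float = 1.0
    arch_span_deg: tuple[float, float] = (20.0, 160.0)
    hu_levels: dict = field(default_factory=lambda: dict(DEFAULT_HU_LEVELS))
    noise_sd_hu: float = 40.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if min(self.grid_shape) < 1:
            raise ValueError("grid extents must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.n_teeth < 2:
            raise ValueError("need at least 2 teeth to define an arch")
        if not 0 <= self.missing_tooth_index < self.n_teeth:
            raise ValueError(
                f"missing_tooth_index {self.missing_tooth_index} outside "
                f"[0, {self.n_teeth})")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be nonnegative")
        lo, hi = -1000.0, 2000.0
        for name, hu in self.hu_levels.items():
            if not lo <= hu <= hi:
                raise ValueError(
                    f"hu_levels[{name!r}] = {hu} outside [{lo}, {hi}]")
        if self.implant_length_mm > self.root_depth_mm:
            raise GeometryError(
                "implant longer than the bone-region depth (axis 2): "
                f"{self.implant_length_mm} > {self.root_depth_mm} mm")

    # --- derived continuous geometry (mm, in world coordinates) --------
    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in
                     zip(self.grid_shape, self.voxel_spacing_mm))

    @property
    def slab_top_mm(self) -> float:
        return 0.76 * self.extent_mm[2]

    @property
    def arch_center_mm(self) -> tuple[float, float]:
        ex, ey, _ = self.extent_mm
        return (0.5 * ex, 0.30 * ey)

    def tooth_centers_mm(self) -> np.ndarray:
        """(n_teeth, 2) x-y centres along the arch."""
        a0, a1 = np.deg2rad(self.arch_span_deg)
        ang = np.linspace(a0, a1, self.n_teeth)
        cx, cy = self.arch_center_mm
        return np.stack([cx + self.arch_radius_mm * np.cos(ang),
                         cy + self.arch_radius_mm * np.sin(ang)], axis=1)

    @property
    def gap_half_width_mm(self) -> float:
        return self.tooth_radius_mm * (1.0 +
                                       2.0 * self.gap_margin_tooth_widths)


@dataclass
class PhantomCase:
    """One phantom: intensity volume plus the two ground-truth masks."""

    volume: CBCTVolume
    bone_region_mask: BinaryMask3D
    implant_mask: BinaryMask3D
    case_id: str
    spec: PhantomSpec

    def __post_init__(self):
        shapes = {self.volume.shape, self.bone_region_mask.shape,
                  self.implant_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"grids disagree: {shapes}")
        if not self.implant_mask.data.any():
            raise ValueError("implant mask is empty")
        if (self.implant_mask.data & ~self.bone_region_mask.data).any():
            raise ValueError("implant mask escapes the bone-region mask")


def _check_cylinder_fits(spec: PhantomSpec, cx: float, cy: float,
                         r: float, z0: float, z1: float) -> None:
    ex, ey, ez = spec.extent_mm
    for axis, lo, hi, bound in ((0, cx - r, cx + r, ex),
                                (1, cy - r, cy + r, ey),
                                (2, z0, z1, ez)):
        if lo < 0 or hi > bound:
            raise GeometryError(
                f"implant cylinder exceeds grid bounds along axis {axis}: "
                f"[{lo:.2f}, {hi:.2f}] mm vs [0, {bound:.2f}] mm")


def generate_phantom(spec: PhantomSpec, case_id: str = "case000"
                     ) -> PhantomCase:
    """Rasterize one phantom; deterministic for a fixed ``spec.seed``."""
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.voxel_spacing_mm
    # voxel-centre world coordinates
    x = (np.arange(nx, dtype=np.float64) + 0.5) * sx
    y = (np.arange(ny, dtype=np.float64) + 0.5) * sy
    z = (np.arange(nz, dtype=np.float64) + 0.5) * sz
    X = x[:, None]          # broadcast over (x, y)
    Y = y[None, :]
    Zin = None  # computed lazily per z-interval

    z_top = spec.slab_top_mm
    slab_lo = z_top - spec.slab_thickness_mm
    roots_lo = z_top - spec.root_depth_mm
    crown_hi = z_top + spec.tooth_height_mm

    centers = spec.tooth_centers_mm()
    gx, gy = centers[spec.missing_tooth_index]
    imp_r = spec.implant_diameter_mm / 2.0
    imp_z0, imp_z1 = z_top - spec.implant_length_mm, z_top
    _check_cylinder_fits(spec, gx, gy, imp_r, imp_z0, imp_z1)

    hw = spec.gap_half_width_mm
    if hw < imp_r:
        raise GeometryError(
            "bone-region half-width smaller than the implant radius")
    if (gx - hw < 0 or gx + hw > spec.extent_mm[0]
            or gy - hw < 0 or gy + hw > spec.extent_mm[1]):
        raise GeometryError(
            "bone-region block exceeds grid bounds around the gap")

    z_slab = (z >= slab_lo) & (z <= z_top)
    z_roots = (z >= roots_lo) & (z <= z_top)
    z_crown = (z > z_top) & (z <= crown_hi)
    z_impl = (z >= imp_z0) & (z <= imp_z1)
    z_below = z < slab_lo

    # x-y footprints
    teeth_fp = np.zeros((nx, ny), dtype=bool)
    for t, (tx, ty) in enumerate(centers):
        if t == spec.missing_tooth_index:
            continue
        teeth_fp |= (X - tx) ** 2 + (Y - ty) ** 2 <= spec.tooth_radius_mm ** 2
    imp_fp = (X - gx) ** 2 + (Y - gy) ** 2 <= imp_r ** 2
    box_fp = (np.abs(X - gx) <= hw) & (np.abs(Y - gy) <= hw)

    hu = spec.hu_levels
    vol = np.full(spec.grid_shape, hu["air"], dtype=np.float32)
    vol[:, :, z_below] = hu["soft_tissue"]
    vol[:, :, z_slab] = hu["bone"]
    tooth_solid = teeth_fp[:, :, None] & (z_roots | z_crown)[None, None, :]
    vol[tooth_solid] = hu["tooth"]

    bone_region = box_fp[:, :, None] & z_roots[None, None, :]
    bone_region &= ~tooth_solid  # margin may clip a neighbouring root
    implant = imp_fp[:, :, None] & z_impl[None, None, :]

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd_hu,
                               size=vol.shape).astype(np.float32)
    vol = np.clip(vol, -1000.0, 2000.0)

    spacing = spec.voxel_spacing_mm
    return PhantomCase(
        volume=CBCTVolume(vol.astype(np.float32), spacing, units="HU"),
        bone_region_mask=BinaryMask3D(bone_region, spacing),
        implant_mask=BinaryMask3D(implant, spacing),
        case_id=case_id,
        spec=spec,
    )


def generate_cohort(n_cases: int, base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> list[PhantomCase]:
    """Deterministic cohort with per-case geometric jitter.

    Per-case seeds derive from the master seed; arch and tooth radii are
    jittered by +/-10% (uniform) and the missing-tooth position cycles
    over the interior arch positions so the edentulous site varies while
    the ground-truth block always stays inside the grid.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2 ** 31 - 1, size=n_cases)
    interior = list(range(1, base_spec.n_teeth - 1)) or [0]
    cases = []
    for i in range(n_cases):
        rng = np.random.default_rng(case_seeds[i])
        jitter = lambda v: float(v * rng.uniform(0.9, 1.1))  # noqa: E731
        spec = replace(
            base_spec,
            arch_radius_mm=jitter(base_spec.arch_radius_mm),
            tooth_radius_mm=jitter(base_spec.tooth_radius_mm),
            missing_tooth_index=interior[int(rng.integers(len(interior)))],
            seed=int(case_seeds[i]),
        )
        cases.append(generate_phantom(spec, case_id=f"case{i:03d}"))
    return cases


def write_case(case: PhantomCase, out_dir) -> dict[str, Path]:
    """Write volume + both masks as NIfTI; returns the three paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / f"{case.case_id}_volume.nii.gz",
        "bone_region_mask": out / f"{case.case_id}_bone_region.nii.gz",
        "implant_mask": out / f"{case.case_id}_implant.nii.gz",
    }
    write_nifti(case.volume, paths["volume"])
    write_nifti(case.bone_region_mask, paths["bone_region_mask"])
    write_nifti(case.implant_mask, paths["implant_mask"])
    return paths
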