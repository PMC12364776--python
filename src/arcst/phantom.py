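"""Virtual phantom construction and geometric/SPR perturbations.

The phantom is an ellipsoidal water body (half-axes 10 x 8.5 x 10 cm in the
patient frame x = left, y = anterior, z = superior) containing an air cylinder,
a cortical-bone cylinder, an ellipsoidal organ-at-risk and one of three
clinical target volumes (a 3 cm cube, or one of two H-shaped targets cut from
4.5 cm / 6 cm cubes).  Everything lives on an isotropic voxel grid of
stopping-power ratios (SPR); voxel (i, j, k) spans the half-open box
[origin + i*spacing, origin + (i+1)*spacing) per axis.

An "asymmetric" variant adds a shoulder-like half-cylinder protrusion so that
anatomy-change scenarios (sub-volume displacement) can be exercised without a
patient CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SPR_WATER = 1.0
SPR_AIR = 0.001
SPR_BONE = 1.6

TARGET_NAMES = ("CTV_small", "CTV_4.5H", "CTV_6H")
ROI_NAMES = ("External", "AirCyl", "BoneCyl", "OAR") + TARGET_NAMES


@dataclass
class SprGrid:
    """Voxelized stopping-power-ratio map.

    Attributes
    ----------
    spacing : float
        Isotropic voxel pitch in cm.
    origin : ndarray, shape (3,)
        Position (cm) of the corner of voxel (0, 0, 0).
    spr : ndarray, shape (nx, ny, nz)
        Dimensionless stopping-power ratio per voxel (water = 1.0).
    """

    spacing: float
    origin: np.ndarray
    spr: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spr = np.asarray(self.spr, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not np.all(np.isfinite(self.spr)) or np.any(self.spr < 0):
            raise ValueError("spr must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.spr.shape

    @property
    def extent(self) -> np.ndarray:
        """Physical size (cm) of the grid per axis."""
        return np.asarray(self.shape) * self.spacing

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.voxel_centers(a) for a in range(3)), indexing="ij")

    def points_to_indices(self, points: np.ndarray) -> np.ndarray:
        """Map points (n, 3) to integer voxel indices (floor convention)."""
        return np.floor((points - self.origin) / self.spacing).astype(np.int64)

    def copy(self) -> "SprGrid":
        return SprGrid(self.spacing, self.origin.copy(), self.spr.copy())


@dataclass
class RoiMask:
    """A named region of interest as a boolean voxel mask on an SprGrid."""

    name: str
    mask: np.ndarray

    def volume(self, spacing: float) -> float:
        """Volume in cm^3."""
        return float(np.count_nonzero(self.mask)) * spacing**3

    @property
    def indices(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class PhantomSpec:
    """Dimensions and placement of every phantom structure, in cm.

    Placement of the inclusions is a declared convention: the air and bone
    cylinders have their axes along the patient left-right direction and sit
    laterally off-axis, while the OAR ellipsoid abuts the target from the
    anterior side, so that some beam directions of a full arc traverse air,
    bone and the OAR.
    """

    body_half_axes: tuple[float, float, float] = (10.0, 8.5, 10.0)
    air_cyl_center: tuple[float, float, float] = (5.5, 3.0, 0.0)
    air_cyl_diameter: float = 2.0
    air_cyl_length: float = 5.0
    bone_cyl_center: tuple[float, float, float] = (-5.0, -3.0, 0.0)
    bone_cyl_diameter: float = 3.5
    bone_cyl_length: float = 8.0
    oar_center: tuple[float, float, float] = (0.0, 5.0, 0.0)
    oar_half_axes: tuple[float, float, float] = (2.0, 3.0, 4.0)
    # CTV_small: cube side; H-targets: (cube side, cutout width) with cutouts
    # running the full cube height (z) and opening toward +/- y.
    ctv_small_side: float = 3.0
    ctv_45h: tuple[float, float] = (4.5, 1.5)
    ctv_6h: tuple[float, float] = (6.0, 2.0)
    asymmetric: bool = False
    shoulder_center: tuple[float, float] = (8.0, -5.0)  # (x, z); axis along y
    shoulder_radius: float = 4.0
    shoulder_half_length: float = 4.0
    padding: float = 1.0

    def analytic_target_volume(self, name: str) -> float:
        if name == "CTV_small":
            return self.ctv_small_side**3
        if name == "CTV_4.5H":
            s, c = self.ctv_45h
            return s**3 - 2 * c * c * s
        if name == "CTV_6H":
            s, c = self.ctv_6h
            return s**3 - 2 * c * c * s
        raise ValueError(f"unknown target {name!r}")

    def analytic_body_volume(self) -> float:
        a, b, c = self.body_half_axes
        return 4.0 / 3.0 * np.pi * a * b * c


def _cube_mask(x, y, z, side: float) -> np.ndarray:
    h = side / 2.0
    return (np.abs(x) <= h) & (np.abs(y) <= h) & (np.abs(z) <= h)


def _h_target_mask(x, y, z, side: float, cut: float) -> np.ndarray:
    """Cube of the given side with two cutout cuboids (cut x cut x side),
    removed symmetrically from the +y and -y faces, forming an H in axial view."""
    h = side / 2.0
    cube = _cube_mask(x, y, z, side)
    notch = (np.abs(x) <= cut / 2.0) & (np.abs(y) >= h - cut) & (np.abs(y) <= h)
    return cube & ~notch


def build_phantom(
    spec: PhantomSpec | None = None,
    spacing: float = 0.25,
    target_choice: str = "CTV_small",
) -> tuple[SprGrid, dict[str, RoiMask]]:
    """Rasterize the phantom onto an isotropic voxel grid.

    Returns the SPR grid (water body inside the External contour, air outside,
    with the air/bone inclusions overridden) and a dict of ROI masks keyed by
    name.  Exactly one CTV mask (``target_choice``) is produced.
    """
    if spec is None:
        spec = PhantomSpec()
    if not 0 < spacing <= 1.0:
        raise ValueError("spacing must be in (0, 1] cm")
    if target_choice not in TARGET_NAMES:
        raise ValueError(
            f"unknown target_choice {target_choice!r}; expected one of {TARGET_NAMES}"
        )

    a, b, c = spec.body_half_axes
    pad = spec.padding
    lo = np.array([-a - pad, -b - pad, -c - pad])
    hi = np.array([a + pad, b + pad, c + pad])
    if spec.asymmetric:
        hi[0] = max(hi[0], spec.shoulder_center[0] + spec.shoulder_radius + pad)
    shape = np.ceil((hi - lo) / spacing).astype(int)
    origin = lo
    grid = SprGrid(spacing, origin, np.full(shape, SPR_AIR))

    x, y, z = grid.center_mesh()

    external = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    if spec.asymmetric:
        cx, cz = spec.shoulder_center
        shoulder = (
            ((x - cx) ** 2 + (z - cz) ** 2 <= spec.shoulder_radius**2)
            & (np.abs(y) <= spec.shoulder_half_length)
        )
        external = external | shoulder

    acx, acy, acz = spec.air_cyl_center
    air_cyl = (
        ((y - acy) ** 2 + (z - acz) ** 2 <= (spec.air_cyl_diameter / 2.0) ** 2)
        & (np.abs(x - acx) <= spec.air_cyl_length / 2.0)
    ) & external

    bcx, bcy, bcz = spec.bone_cyl_center
    bone_cyl = (
        ((y - bcy) ** 2 + (z - bcz) ** 2 <= (spec.bone_cyl_diameter / 2.0) ** 2)
        & (np.abs(x - bcx) <= spec.bone_cyl_length / 2.0)
    ) & external

    ox, oy, oz = spec.oar_center
    oa, ob, oc = spec.oar_half_axes
    oar = (
        ((x - ox) / oa) ** 2 + ((y - oy) / ob) ** 2 + ((z - oz) / oc) ** 2 <= 1.0
    ) & external

    if target_choice == "CTV_small":
        ctv = _cube_mask(x, y, z, spec.ctv_small_side)
    elif target_choice == "CTV_4.5H":
        ctv = _h_target_mask(x, y, z, *spec.ctv_45h)
    else:
        ctv = _h_target_mask(x, y, z, *spec.ctv_6h)
    ctv = ctv & external

    grid.spr[external] = SPR_WATER
    grid.spr[bone_cyl] = SPR_BONE
    grid.spr[air_cyl] = SPR_AIR

    rois = {
        "External": RoiMask("External", external),
        "AirCyl": RoiMask("AirCyl", air_cyl),
        "BoneCyl": RoiMask("BoneCyl", bone_cyl),
        "OAR": RoiMask("OAR", oar),
        target_choice: RoiMask(target_choice, ctv),
    }
    return grid, rois


def scale_spr(grid: SprGrid, factor: float, region: RoiMask | None = None) -> SprGrid:
    """Multiply SPR by ``factor`` inside ``region`` (whole grid if None).

    The input grid is left untouched.  Because WET is a line integral of SPR,
    a whole-body scale by ``factor`` scales every WET through the body by
    exactly ``factor``.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    out = grid.copy()
    if region is None:
        out.spr *= factor
    else:
        out.spr[region.mask] *= factor
    return out


def shift_geometry(grid: SprGrid, vector: np.ndarray) -> SprGrid:
    """Rigidly translate the SPR content by ``vector`` (cm).

    Nearest-neighbour resampling on the voxel lattice; voxels entering from
    outside the grid are filled with air SPR.  Nearest-neighbour is chosen to
    preserve the discrete material classes (air/water/bone).
    """
    vector = np.asarray(vector, dtype=float)
    if np.any(np.abs(vector) > grid.extent):
        raise ValueError("shift vector exceeds grid extent")
    # Source index for voxel i is the voxel containing (center_i - vector):
    # an integer offset per axis since the lattice is uniform.
    offset = np.floor(0.5 - vector / grid.spacing).astype(int)
    out = grid.copy()
    src = grid.spr
    dst = np.full_like(src, SPR_AIR)
    slices_src, slices_dst = [], []
    for ax, k in enumerate(offset):
        n = src.shape[ax]
        s0 = max(0, k)
        s1 = min(n, n + k)
        d0 = max(0, -k)
        d1 = d0 + (s1 - s0)
        if s1 <= s0:
            out.spr = dst
            return out
        slices_src.append(slice(s0, s1))
        slices_dst.append(slice(d0, d1))
    dst[tuple(slices_dst)] = src[tuple(slices_src)]
    out.spr = dst
    return out


def displace_subvolume(grid: SprGrid, region: RoiMask, vector: np.ndarray) -> SprGrid:
    """Move the SPR content of ``region`` rigidly by ``vector`` (cm).

    Vacated voxels are set to air; voxels at the destination are overwritten
    with the moved values.  Used for anatomy-change scenarios such as a
    shoulder displacement.
    """
    vector = np.asarray(vector, dtype=float)
    idx = np.argwhere(region.mask)
    out = grid.copy()
    if idx.size == 0:
        return out
    shift = np.round(vector / grid.spacing).astype(int)
    dest = idx + shift
    if np.any(dest < 0) or np.any(dest >= np.asarray(grid.shape)):
        raise ValueError("destination of displaced sub-volume lies outside the grid")
    vals = grid.spr[tuple(idx.T)]
    out.spr[tuple(idx.T)] = SPR_AIR
    out.spr[tuple(dest.T)] = vals
    return out
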