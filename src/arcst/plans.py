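"""Static-arc and fixed-beam plan skeletons.

A plan is a set of beam directions, each carrying energy layers, each carrying
a lattice of spots in beam's-eye-view coordinates.  Shoot-through (ST) layers
are extra layers at the machine maximum energy (230 MeV) whose spots fill the
full target projection including margins; where they end up carrying weight is
decided later by the optimizer.  Collimated plans attach a per-layer aperture
(layer-by-layer collimation) that trims the spot penumbra at the field edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from skimage import measure

from .beam import BeamModel
from .dose import beam_frame, wed_for_points
from .phantom import RoiMask, SprGrid

#: default rectangular spot lattice pitch (cm), ~1.5x the finest in-air sigma
DEFAULT_SPOT_SPACING = 0.6
#: BEV pixel pitch (cm) used to rasterize aperture contours
APERTURE_PITCH = 0.1


class Spot(NamedTuple):
    direction_index: int
    energy: float
    u: float
    v: float
    mu: float
    is_st: bool


@dataclass
class Aperture:
    """Beam's-eye-view aperture as a signed-distance field plus its contour.

    ``sdf[i, j]`` is the signed distance (cm, positive inside) at BEV point
    ``origin_uv + (i + 0.5, j + 0.5) * pitch``; ``contours`` are closed
    polygon vertex lists in (u, v) cm for serialization and leaf-travel
    computations.
    """

    origin_uv: np.ndarray
    pitch: float
    sdf: np.ndarray
    contours: list[np.ndarray]
    margin: float = 0.0

    def signed_distance(self, u, v):
        from scipy.ndimage import map_coordinates

        iu = (np.asarray(u, dtype=float) - self.origin_uv[0]) / self.pitch - 0.5
        iv = (np.asarray(v, dtype=float) - self.origin_uv[1]) / self.pitch - 0.5
        return map_coordinates(
            self.sdf, np.vstack([np.atleast_1d(iu), np.atleast_1d(iv)]),
            order=1, mode="nearest",
        )

    def contour_points(self) -> np.ndarray:
        if not self.contours:
            return np.empty((0, 2))
        return np.vstack(self.contours)

    def to_dict(self) -> dict:
        return {
            "origin_uv": self.origin_uv.tolist(),
            "pitch": self.pitch,
            "sdf": self.sdf.tolist(),
            "margin": self.margin,
            "contours": [c.tolist() for c in self.contours],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Aperture":
        return cls(
            origin_uv=np.asarray(d["origin_uv"], dtype=float),
            pitch=float(d["pitch"]),
            sdf=np.asarray(d["sdf"], dtype=float),
            contours=[np.asarray(c, dtype=float) for c in d["contours"]],
            margin=float(d["margin"]),
        )


@dataclass
class EnergyLayer:
    """One energy layer of one direction: parallel spots on a BEV lattice."""

    direction_index: int
    energy: float
    u: np.ndarray
    v: np.ndarray
    mu: np.ndarray
    is_st: bool = False
    aperture: Aperture | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)

    @property
    def n_spots(self) -> int:
        return self.u.size

    @property
    def total_mu(self) -> float:
        return float(self.mu.sum())


@dataclass
class ArcPlan:
    """Directions -> energy layers -> spots; the central plan object.

    ``angles`` are beam azimuths in degrees (0 = entering from anterior,
    clockwise viewed from superior), sorted and unique; a full arc has uniform
    spacing 360/N.
    """

    angles: np.ndarray
    layers: list[EnergyLayer] = field(default_factory=list)
    collimated: bool = False
    prescription: float = 60.0
    fractions: int = 30
    margin_factor: float = 1.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size != np.unique(self.angles).size:
            raise ValueError("plan angles must be unique")
        if np.any(np.diff(self.angles) < 0):
            raise ValueError("plan angles must be sorted")

    # --- spot bookkeeping ----------------------------------------------------

    @property
    def spot_count(self) -> int:
        return int(sum(l.n_spots for l in self.layers))

    @property
    def weights(self) -> np.ndarray:
        """Concatenated MU per spot, in layer order."""
        if not self.layers:
            return np.empty(0)
        return np.concatenate([l.mu for l in self.layers])

    @weights.setter
    def weights(self, w: np.ndarray) -> None:
        w = np.asarray(w, dtype=float)
        if w.size != self.spot_count:
            raise ValueError("weight vector length does not match spot count")
        off = 0
        for l in self.layers:
            l.mu = w[off : off + l.n_spots].copy()
            off += l.n_spots

    def iter_spots(self) -> Iterator[Spot]:
        for l in self.layers:
            for j in range(l.n_spots):
                yield Spot(l.direction_index, l.energy, l.u[j], l.v[j], l.mu[j], l.is_st)

    def spot_table(self) -> dict[str, np.ndarray]:
        """Per-spot flat arrays (direction_index, layer_index, energy, u, v,
        mu, is_st), aligned with the weight vector."""
        n = self.spot_count
        out = {
            "direction_index": np.empty(n, dtype=int),
            "layer_index": np.empty(n, dtype=int),
            "energy": np.empty(n),
            "u": np.empty(n),
            "v": np.empty(n),
            "mu": np.empty(n),
            "is_st": np.zeros(n, dtype=bool),
        }
        off = 0
        for li, l in enumerate(self.layers):
            s = slice(off, off + l.n_spots)
            out["direction_index"][s] = l.direction_index
            out["layer_index"][s] = li
            out["energy"][s] = l.energy
            out["u"][s] = l.u
            out["v"][s] = l.v
            out["mu"][s] = l.mu
            out["is_st"][s] = l.is_st
            off += l.n_spots
        return out

    def st_layers(self) -> list[EnergyLayer]:
        return [l for l in self.layers if l.is_st]

    def layers_of_direction(self, direction_index: int) -> list[EnergyLayer]:
        return [l for l in self.layers if l.direction_index == direction_index]

    # --- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "angles": self.angles.tolist(),
            "collimated": self.collimated,
            "prescription": self.prescription,
            "fractions": self.fractions,
            "margin_factor": self.margin_factor,
            "layers": [
                {
                    "direction_index": l.direction_index,
                    "energy": l.energy,
                    "u": l.u.tolist(),
                    "v": l.v.tolist(),
                    "mu": l.mu.tolist(),
                    "is_st": l.is_st,
                    "aperture": l.aperture.to_dict() if l.aperture else None,
                }
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArcPlan":
        plan = cls(
            angles=np.asarray(d["angles"], dtype=float),
            collimated=d["collimated"],
            prescription=d["prescription"],
            fractions=d["fractions"],
            margin_factor=d["margin_factor"],
        )
        for ld in d["layers"]:
            plan.layers.append(
                EnergyLayer(
                    direction_index=int(ld["direction_index"]),
                    energy=float(ld["energy"]),
                    u=np.asarray(ld["u"], dtype=float),
                    v=np.asarray(ld["v"], dtype=float),
                    mu=np.asarray(ld["mu"], dtype=float),
                    is_st=bool(ld["is_st"]),
                    aperture=Aperture.from_dict(ld["aperture"]) if ld["aperture"] else None,
                )
            )
        return plan


# --------------------------------------------------------------------------
# Construction operations
# --------------------------------------------------------------------------

def make_arc_directions(n: int, full_arc: bool = True, start: float = 0.0) -> np.ndarray:
    """``n`` uniformly spaced azimuths with spacing 360/n starting at 0 deg."""
    if n < 1:
        raise ValueError("n must be >= 1")
    span = 360.0 if full_arc else 180.0
    return (start + np.arange(n) * span / n) % 360.0


def target_projection(
    grid: SprGrid, target: RoiMask, angle: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BEV coordinates (u, v) and water-equivalent depth of every target
    voxel center for a beam azimuth."""
    idx = np.argwhere(target.mask)
    if idx.size == 0:
        raise ValueError("target projection is empty")
    pts = grid.origin + (idx + 0.5) * grid.spacing
    d, e_u, e_v = beam_frame(angle)
    u = pts @ e_u
    v = pts @ e_v
    wet = wed_for_points(grid, pts, d)
    return u, v, wet


def select_energy_layers(
    grid: SprGrid,
    target: RoiMask,
    angle: float,
    n_layers: int,
    beam: BeamModel,
) -> np.ndarray:
    """Machine energies whose ranges sample the target's WET interval
    [WETmin - sigma_R, WETmax + sigma_R] uniformly in range, snapped to
    deliverable levels and deduplicated (ascending)."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    _, _, wet = target_projection(grid, target, angle)
    w_lo, w_hi = float(wet.min()), float(wet.max())
    sig = float(beam.sigma_range(max(w_hi, 1e-6)))
    r_min_machine = float(beam.energy_table[0, 1])
    r_max_machine = float(beam.energy_table[-1, 1])
    lo = max(w_lo - sig, r_min_machine)
    hi = min(w_hi + sig, r_max_machine)
    if n_layers == 1:
        ranges = np.array([0.5 * (lo + hi)])
    else:
        ranges = np.linspace(lo, hi, n_layers)
    energies = beam.nearest_level_for_range(ranges)
    return np.unique(np.atleast_1d(energies))


def _lattice_covering(
    u: np.ndarray, v: np.ndarray, margin: float, spot_spacing: float, footprint: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular lattice (anchored at the BEV origin) covering the point
    cloud (u, v) dilated by ``margin``; a lattice node is kept if it lies
    within margin + footprint of some projected voxel center."""
    if u.size == 0:
        return np.empty(0), np.empty(0)
    pad = margin + footprint + spot_spacing
    ku = np.arange(np.floor((u.min() - pad) / spot_spacing), np.ceil((u.max() + pad) / spot_spacing) + 1)
    kv = np.arange(np.floor((v.min() - pad) / spot_spacing), np.ceil((v.max() + pad) / spot_spacing) + 1)
    gu, gv = np.meshgrid(ku * spot_spacing, kv * spot_spacing, indexing="ij")
    nodes = np.column_stack([gu.ravel(), gv.ravel()])
    tree = cKDTree(np.column_stack([u, v]))
    dist, _ = tree.query(nodes, k=1)
    keep = dist <= margin + footprint
    return nodes[keep, 0], nodes[keep, 1]


def place_spots(
    grid: SprGrid,
    target: RoiMask,
    angle: float,
    energy: float,
    beam: BeamModel,
    margin_factor: float = 1.0,
    spot_spacing: float = DEFAULT_SPOT_SPACING,
    wet_window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spot positions on a rectangular BEV lattice covering the projection of
    the target (restricted to the layer's WET slab when ``wet_window`` is
    given), dilated by ``margin_factor * sigma_air(energy)``.

    An empty slab projection yields an empty layer, not an error.
    """
    if spot_spacing <= 0:
        raise ValueError("spot_spacing must be > 0")
    u, v, wet = target_projection(grid, target, angle)
    if wet_window is not None:
        sel = (wet >= wet_window[0]) & (wet <= wet_window[1])
        u, v = u[sel], v[sel]
    margin = margin_factor * beam.entrance_sigma(energy)
    footprint = grid.spacing * np.sqrt(2.0) / 2.0
    return _lattice_covering(u, v, margin, spot_spacing, footprint)


def add_st_layer(
    plan: ArcPlan,
    direction_index: int,
    grid: SprGrid,
    target: RoiMask,
    beam: BeamModel,
    spot_spacing: float = DEFAULT_SPOT_SPACING,
    margin_factor: float | None = None,
    initial_mu: float | None = None,
) -> ArcPlan:
    """Append the shoot-through layer (machine maximum energy) for one
    direction: spots fill the FULL target projection including margins."""
    if direction_index < 0 or direction_index >= plan.angles.size:
        raise ValueError("direction not in plan")
    if any(l.is_st and l.direction_index == direction_index for l in plan.layers):
        raise ValueError(f"duplicate ST layer for direction {direction_index}")
    if margin_factor is None:
        margin_factor = plan.margin_factor
    if initial_mu is None:
        initial_mu = 2.0 * beam.min_spot_mu
    u, v = place_spots(
        grid, target, plan.angles[direction_index], beam.e_max, beam,
        margin_factor=margin_factor, spot_spacing=spot_spacing,
    )
    plan.layers.append(
        EnergyLayer(
            direction_index=direction_index,
            energy=beam.e_max,
            u=u,
            v=v,
            mu=np.full(u.size, initial_mu),
            is_st=True,
        )
    )
    return plan


def make_aperture(
    grid: SprGrid,
    target: RoiMask,
    angle: float,
    margin: float,
    wet_window: tuple[float, float] | None = None,
    pitch: float = APERTURE_PITCH,
) -> Aperture | None:
    """Layer aperture: the BEV projection of the layer's target slab dilated
    by ``margin``, stored as a signed-distance field plus contour polygons.

    The contour is not required to be convex (H-shaped targets give
    non-convex apertures).  Returns None for an empty slab projection.
    """
    u, v, wet = target_projection(grid, target, angle)
    if wet_window is not None:
        sel = (wet >= wet_window[0]) & (wet <= wet_window[1])
        u, v = u[sel], v[sel]
    if u.size == 0:
        return None
    footprint = grid.spacing * np.sqrt(2.0) / 2.0
    pad = margin + footprint + 10 * pitch
    origin_uv = np.array([u.min() - pad, v.min() - pad])
    nu = int(np.ceil((u.max() + pad - origin_uv[0]) / pitch))
    nv = int(np.ceil((v.max() + pad - origin_uv[1]) / pitch))
    gu = origin_uv[0] + (np.arange(nu) + 0.5) * pitch
    gv = origin_uv[1] + (np.arange(nv) + 0.5) * pitch
    mu_, mv_ = np.meshgrid(gu, gv, indexing="ij")
    tree = cKDTree(np.column_stack([u, v]))
    dist, _ = tree.query(np.column_stack([mu_.ravel(), mv_.ravel()]), k=1)
    inside = (dist <= margin + footprint).reshape(nu, nv)
    # signed distance: positive inside the open field
    d_out = distance_transform_edt(~inside) * pitch
    d_in = distance_transform_edt(inside) * pitch
    sdf = np.where(inside, d_in, -d_out)
    contours = [
        np.column_stack([
            origin_uv[0] + (c[:, 0] + 0.5) * pitch,
            origin_uv[1] + (c[:, 1] + 0.5) * pitch,
        ])
        for c in measure.find_contours(sdf, 0.0)
    ]
    return Aperture(origin_uv=origin_uv, pitch=pitch, sdf=sdf, contours=contours, margin=margin)


# --------------------------------------------------------------------------
# Full plan assembly
# --------------------------------------------------------------------------

@dataclass
class PlanSettings:
    """Plan-construction knobs with the study defaults: 20 uniformly spaced
    directions, 60 GyRBE in 30 fractions, 480 initial energy layers filtered
    to 240, margin factor 1.0 uncollimated / 1.25 collimated."""

    n_directions: int = 20
    angles: np.ndarray | None = None  # overrides n_directions (e.g. 3-beam IMPT)
    shoot_through: bool = True
    collimated: bool = False
    margin_factor: float | None = None
    spot_spacing: float = DEFAULT_SPOT_SPACING
    layers_initial: int = 480
    layers_final: int = 240
    prescription: float = 60.0
    fractions: int = 30

    def resolved_margin_factor(self) -> float:
        if self.margin_factor is not None:
            return self.margin_factor
        return 1.25 if self.collimated else 1.0


def build_arc_plan(
    grid: SprGrid,
    target: RoiMask,
    beam: BeamModel,
    settings: PlanSettings | None = None,
) -> ArcPlan:
    """Assemble the full plan skeleton: directions, Bragg layers on WET
    slabs, optional ST layer and apertures per direction.  All spots start at
    2x the minimum spot MU (the optimizer reweights them)."""
    if settings is None:
        settings = PlanSettings()
    if settings.angles is not None:
        angles = np.sort(np.asarray(settings.angles, dtype=float))
    else:
        angles = make_arc_directions(settings.n_directions)
    margin_factor = settings.resolved_margin_factor()
    plan = ArcPlan(
        angles=angles,
        collimated=settings.collimated,
        prescription=settings.prescription,
        fractions=settings.fractions,
        margin_factor=margin_factor,
    )
    n_dirs = angles.size
    per_dir = max(1, int(np.ceil(settings.layers_initial / n_dirs)))
    initial_mu = 2.0 * beam.min_spot_mu

    for di, angle in enumerate(angles):
        energies = select_energy_layers(grid, target, angle, per_dir, beam)
        ranges = beam.range_in_water(energies)
        if ranges.size > 1:
            half = float(np.max(np.diff(ranges))) / 2.0
        else:
            _, _, wet = target_projection(grid, target, angle)
            half = max(float(wet.max() - wet.min()) / 2.0, beam.sigma_range(ranges[0]))
        for energy, r in zip(energies, ranges):
            window = (r - half, r + half)
            u, v = place_spots(
                grid, target, angle, energy, beam,
                margin_factor=margin_factor, spot_spacing=settings.spot_spacing,
                wet_window=window,
            )
            if u.size == 0:
                continue
            aperture = None
            if settings.collimated:
                aperture = make_aperture(
                    grid, target, angle,
                    margin=margin_factor * beam.entrance_sigma(energy),
                    wet_window=window,
                )
            plan.layers.append(
                EnergyLayer(
                    direction_index=di,
                    energy=float(energy),
                    u=u,
                    v=v,
                    mu=np.full(u.size, initial_mu),
                    aperture=aperture,
                )
            )
        if settings.shoot_through:
            add_st_layer(
                plan, di, grid, target, beam,
                spot_spacing=settings.spot_spacing,
                margin_factor=margin_factor,
                initial_mu=initial_mu,
            )
            if settings.collimated:
                plan.layers[-1].aperture = make_aperture(
                    grid, target, angle,
                    margin=margin_factor * beam.entrance_sigma(beam.e_max),
                )
    return plan
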