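"""Step-and-shoot delivery time model for the upright positioner and nozzle.

Components, with the machine parameters used throughout the study:

* positioner rotation between discrete directions: trapezoidal velocity
  profile with speed 6 deg/s and acceleration 5 deg/s^2 (triangular profile
  for steps too short to reach full speed);
* energy switching: a constant 0.2 s per layer;
* spot scanning: serpentine raster travel at 600 mm/s;
* beam-on: spot charge (protons x elementary charge) over a delivery current
  of 55 nC/s;
* adaptive-aperture leaf travel for collimated layers at 500 mm/s, measured
  as the largest boundary displacement between consecutive apertures.

Beam-on charge is the per-fraction share (course MU / fractions); a delivery
time is per fraction.  Rotation from the park position to the first direction
is counted as one arc step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .beam import BeamModel
from .plans import Aperture, ArcPlan, EnergyLayer

#: half-width (cm) of the fully open aperture the leaves start from
OPEN_FIELD_HALFWIDTH = 10.0


@dataclass(frozen=True)
class TimeModel:
    rot_speed: float = 6.0       # deg/s
    rot_accel: float = 5.0       # deg/s^2
    scan_speed: float = 600.0    # mm/s
    beam_current: float = 55.0   # nC/s
    energy_switch: float = 0.2   # s
    leaf_speed: float = 500.0    # mm/s

    def __post_init__(self) -> None:
        for name in ("rot_speed", "rot_accel", "scan_speed", "beam_current",
                     "energy_switch", "leaf_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class TimeBreakdown:
    rotation: float = 0.0
    energy_switch: float = 0.0
    scanning: float = 0.0
    beam_on: float = 0.0
    collimator: float = 0.0

    @property
    def total(self) -> float:
        return (self.rotation + self.energy_switch + self.scanning
                + self.beam_on + self.collimator)

    def to_dict(self) -> dict:
        return {
            "rotation_s": self.rotation,
            "energy_switch_s": self.energy_switch,
            "scanning_s": self.scanning,
            "beam_on_s": self.beam_on,
            "collimator_s": self.collimator,
            "total_s": self.total,
        }


def rotation_time(delta_angle: float, model: TimeModel | None = None) -> float:
    """Time to rotate by ``delta_angle`` degrees: trapezoidal profile
    t = delta/v + v/a when the step reaches full speed (delta >= v^2/a),
    triangular t = 2*sqrt(delta/a) otherwise."""
    if model is None:
        model = TimeModel()
    if delta_angle < 0:
        raise ValueError("delta_angle must be >= 0")
    if delta_angle == 0:
        return 0.0
    v, a = model.rot_speed, model.rot_accel
    if delta_angle >= v**2 / a:
        return delta_angle / v + v / a
    return 2.0 * np.sqrt(delta_angle / a)


def _serpentine_order(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Spot delivery order: rows of constant v bottom-up, u alternating
    left-to-right / right-to-left (minimizes raster travel)."""
    rows = np.round(v / 1e-6) * 1e-6
    order = np.lexsort((u, rows))
    out = []
    i = 0
    flip = False
    while i < order.size:
        j = i
        while j < order.size and rows[order[j]] == rows[order[i]]:
            j += 1
        chunk = order[i:j]
        out.append(chunk[::-1] if flip else chunk)
        flip = not flip
        i = j
    return np.concatenate(out) if out else order


def _aperture_travel(prev: Aperture | None, cur: Aperture) -> float:
    """Largest leaf displacement (cm) between consecutive apertures
    (symmetric Hausdorff distance of the contours); the first collimated
    layer pays the travel from the fully open field."""
    pts = cur.contour_points()
    if pts.size == 0:
        return 0.0
    if prev is None:
        h = OPEN_FIELD_HALFWIDTH
        t = np.linspace(-h, h, 81)
        edge = np.vstack([
            np.column_stack([t, np.full_like(t, -h)]),
            np.column_stack([t, np.full_like(t, h)]),
            np.column_stack([np.full_like(t, -h), t]),
            np.column_stack([np.full_like(t, h), t]),
        ])
        prev_pts = edge
    else:
        prev_pts = prev.contour_points()
        if prev_pts.size == 0:
            return 0.0
    d1 = directed_hausdorff(prev_pts, pts)[0]
    d2 = directed_hausdorff(pts, prev_pts)[0]
    return float(max(d1, d2))


def layer_time(
    layer: EnergyLayer,
    model: TimeModel,
    beam: BeamModel,
    fractions: int = 1,
    prev_aperture: Aperture | None = None,
    use_collimator: bool | None = None,
) -> TimeBreakdown:
    """Energy switch + serpentine scanning travel + beam-on + optional leaf
    travel for one layer.  Only spots with nonzero MU are delivered."""
    tb = TimeBreakdown(energy_switch=model.energy_switch)
    live = layer.mu > 0
    if np.any(live):
        u, v, mu = layer.u[live], layer.v[live], layer.mu[live]
        order = _serpentine_order(u, v)
        du = np.diff(u[order])
        dv = np.diff(v[order])
        travel_cm = float(np.sum(np.hypot(du, dv)))
        tb.scanning = travel_cm * 10.0 / model.scan_speed  # cm -> mm
        charge = beam.protons_to_charge(beam.mu_to_protons(mu / fractions))
        tb.beam_on = float(np.sum(charge)) / model.beam_current
    if use_collimator is None:
        use_collimator = layer.aperture is not None
    if use_collimator and layer.aperture is not None:
        travel_cm = _aperture_travel(prev_aperture, layer.aperture)
        tb.collimator = travel_cm * 10.0 / model.leaf_speed
    return tb


def plan_time(
    plan: ArcPlan,
    model: TimeModel | None = None,
    beam: BeamModel | None = None,
    use_collimator: bool | None = None,
) -> TimeBreakdown:
    """Per-fraction delivery time of a plan with a per-component breakdown.

    Rotations take the shortest angular path between consecutive directions;
    the move from the park position to the first direction is counted as one
    step of the mean inter-direction spacing (18 deg for a 20-direction full
    arc).  ``use_collimator=False`` evaluates the same plan without aperture
    movements (the uncollimated delivery of an otherwise identical plan).
    """
    if model is None:
        model = TimeModel()
    if beam is None:
        beam = BeamModel()
    tb = TimeBreakdown()
    angles = plan.angles
    if angles.size > 1:
        steps = np.diff(np.sort(angles))
        steps = np.minimum(steps, 360.0 - steps)
        park = float(np.mean(steps))
        all_steps = np.concatenate([[park], steps])
    else:
        all_steps = np.array([360.0 / 20.0])
    for s in all_steps:
        tb.rotation += rotation_time(float(s), model)
    for di in range(angles.size):
        prev_ap = None
        for layer in plan.layers_of_direction(di):
            lt = layer_time(
                layer, model, beam, fractions=plan.fractions,
                prev_aperture=prev_ap, use_collimator=use_collimator,
            )
            tb.energy_switch += lt.energy_switch
            tb.scanning += lt.scanning
            tb.beam_on += lt.beam_on
            tb.collimator += lt.collimator
            if layer.aperture is not None:
                prev_ap = layer.aperture
    return tb
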