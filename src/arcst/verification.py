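"""Residual-range verification with the shoot-through (ST) protons.

ST protons exit the patient with a residual range in water
``r = R_max - WET``, where R_max is the range in water of the machine's
maximum energy (an intrinsic machine property) and WET is the
water-equivalent thickness traversed.  A fixed range detector behind the
patient measures r for every ST spot at every treatment angle; comparing the
measured value against the value predicted on the planning geometry gives the
per-spot relative WET discrepancy

    dWET/WET = (r_plan - r_measured) / (R_max - r_plan)

which is positive when the measured range is shorter than planned (more WET
in the patient than at planning).  Here the "measurement" is simulated by ray
tracing the perturbed geometry, a conceptual stand-in for a real detector.

Geometry is parallel-beam: every ST spot ray runs along the direction axis
through its lateral lattice position, and WET is evaluated with the exact
voxel-walking ray tracer, so a global SPR scale by (1 + s) yields
dWET/WET = s for every body-crossing spot up to floating-point error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beam import BeamModel
from .dose import beam_frame, ray_entry_point, wet_along_ray
from .phantom import SprGrid
from .plans import ArcPlan

#: display cap for spot-map color scales (15 %)
DISPLAY_CAP = 0.15


@dataclass
class RangeRecord:
    """Per-ST-spot residual-range comparison."""

    spot_id: int
    angle: float
    u: float
    v: float
    r_plan: float        # residual range (cm water) on the planning geometry
    r_measured: float    # residual range (cm water) on the perturbed geometry
    r_max: float         # range in water of the ST protons
    delta_wet_rel: float
    valid: bool = True
    flag: str = ""


@dataclass
class AngleSummary:
    """Box-plot statistics of dWET/WET for one beam angle: whiskers reach the
    extreme data points within 1.5 IQR of the quartiles."""

    angle: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_spots: int


def residual_range(
    grid: SprGrid, through: np.ndarray, direction: np.ndarray, r_max: float
) -> float:
    """Residual range in water (cm) behind the patient for an ST ray:
    r = R_max - WET along the full ray.  Negative values mean the proton
    stops inside the patient (callers should flag and exclude)."""
    origin, length = ray_entry_point(grid, through, direction)
    wet = wet_along_ray(grid, origin, direction, length)
    return r_max - wet


def delta_wet(r_plan: float, r_measured: float, r_max: float) -> float:
    """Relative WET difference (r_plan - r_measured)/(R_max - r_plan).

    Undefined when R_max = r_plan (the planned ray saw no material)."""
    denom = r_max - r_plan
    if denom <= 0:
        raise ZeroDivisionError("R_max must exceed r_plan (zero planned WET)")
    return (r_plan - r_measured) / denom


def run_verification(
    plan: ArcPlan,
    nominal_grid: SprGrid,
    perturbed_grid: SprGrid,
    beam: BeamModel | None = None,
    include_zero_mu: bool = False,
) -> list[RangeRecord]:
    """One record per ST spot with nonzero MU: residual range on the planning
    geometry and on the perturbed geometry, plus the per-spot dWET/WET.

    Spots whose planned ray misses the body entirely (r_plan = R_max) carry
    delta 0 and are flagged invalid, as are spots whose protons would stop
    inside the patient; invalid records are excluded from summaries.
    """
    if beam is None:
        beam = BeamModel()
    st_layers = plan.st_layers()
    if not st_layers:
        raise ValueError("plan contains no shoot-through layers")
    r_max = beam.range_in_water(beam.e_max)
    records: list[RangeRecord] = []
    spot_id = 0
    # spot ids are global plan spot indices
    offsets = {}
    off = 0
    for li, layer in enumerate(plan.layers):
        offsets[li] = off
        off += layer.n_spots
    for li, layer in enumerate(plan.layers):
        if not layer.is_st:
            continue
        angle = float(plan.angles[layer.direction_index])
        d, e_u, e_v = beam_frame(angle)
        for j in range(layer.n_spots):
            if not include_zero_mu and layer.mu[j] <= 0:
                continue
            through = layer.u[j] * e_u + layer.v[j] * e_v
            r_plan = residual_range(nominal_grid, through, d, r_max)
            r_meas = residual_range(perturbed_grid, through, d, r_max)
            spot_id = offsets[li] + j
            flag = ""
            valid = True
            if r_plan >= r_max - 1e-9:
                flag, valid, dw = "missed_body", False, 0.0
            elif r_plan < 0 or r_meas < 0:
                flag, valid, dw = "stops_inside", False, 0.0
            else:
                dw = delta_wet(r_plan, r_meas, r_max)
            records.append(
                RangeRecord(
                    spot_id=spot_id, angle=angle,
                    u=float(layer.u[j]), v=float(layer.v[j]),
                    r_plan=r_plan, r_measured=r_meas, r_max=r_max,
                    delta_wet_rel=dw, valid=valid, flag=flag,
                )
            )
    return records


def summarize_by_angle(records: list[RangeRecord]) -> list[AngleSummary]:
    """Per-angle median/quartiles of dWET/WET with 1.5-IQR whiskers
    (whisker_high = largest datum <= Q3 + 1.5 IQR, mirrored for the low
    whisker).  Invalid records are excluded."""
    valid = [r for r in records if r.valid]
    if not valid:
        raise ValueError("no valid records to summarize")
    out = []
    angles = sorted({r.angle for r in valid})
    for a in angles:
        vals = np.array([r.delta_wet_rel for r in valid if r.angle == a])
        q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
        iqr = q3 - q1
        hi_cand = vals[vals <= q3 + 1.5 * iqr]
        lo_cand = vals[vals >= q1 - 1.5 * iqr]
        out.append(
            AngleSummary(
                angle=a, median=float(med), q1=float(q1), q3=float(q3),
                whisker_low=float(lo_cand.min()), whisker_high=float(hi_cand.max()),
                n_spots=vals.size,
            )
        )
    return out


def spot_map(records: list[RangeRecord], cap: float = DISPLAY_CAP) -> pd.DataFrame:
    """Per-spot table of (u, v, dWET/WET) over all angles, with a display
    column capped at +/- ``cap`` (15 %) for color scales."""
    df = pd.DataFrame(
        {
            "spot_id": [r.spot_id for r in records],
            "angle": [r.angle for r in records],
            "u": [r.u for r in records],
            "v": [r.v for r in records],
            "r_plan": [r.r_plan for r in records],
            "r_measured": [r.r_measured for r in records],
            "delta_wet_rel": [r.delta_wet_rel for r in records],
            "valid": [r.valid for r in records],
            "flag": [r.flag for r in records],
        }
    )
    df["delta_wet_display"] = df["delta_wet_rel"].clip(-cap, cap)
    return df


def records_to_csv(records: list[RangeRecord], path) -> None:
    spot_map(records).to_csv(path, index=False)


def plot_angle_boxes(records: list[RangeRecord], ax=None):
    """Box plot of dWET/WET (in percent) versus beam angle, whiskers at
    1.5 IQR, matching the summary convention."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    valid = [r for r in records if r.valid]
    angles = sorted({r.angle for r in valid})
    data = [
        [100.0 * r.delta_wet_rel for r in valid if r.angle == a] for a in angles
    ]
    ax.boxplot(data, positions=angles, widths=0.6 * min(np.diff(angles), default=10.0),
               whis=1.5, manage_ticks=False)
    ax.set_xlabel("beam angle (deg)")
    ax.set_ylabel("dWET/WET (%)")
    return ax
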