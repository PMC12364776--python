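"""Standard-format I/O: NRRD voxel grids, JSON plans and metrics reports.

Grids and masks are written as NRRD scalar volumes (spacing and origin in the
header) through SimpleITK; plans serialize losslessly to JSON; metrics
reports are written both as JSON (sorted keys, stable formatting, so repeated
deterministic runs are byte-identical) and as a human-readable table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .evaluate import PlanMetrics
from .phantom import RoiMask, SprGrid
from .plans import ArcPlan


def write_grid(grid: SprGrid, path) -> None:
    # SimpleITK arrays are indexed (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.spr.T))
    img.SetSpacing((grid.spacing,) * 3)
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


def read_grid(path) -> SprGrid:
    img = sitk.ReadImage(str(path))
    sx, sy, sz = img.GetSpacing()
    if not np.allclose([sx, sy, sz], sx):
        raise ValueError(f"{path}: anisotropic spacing is not supported")
    arr = sitk.GetArrayFromImage(img).T.astype(float)
    return SprGrid(spacing=float(sx), origin=np.asarray(img.GetOrigin()), spr=arr)


def write_mask(mask: RoiMask, spacing: float, origin: np.ndarray, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.mask.T).astype(np.uint8))
    img.SetSpacing((spacing,) * 3)
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def read_mask(path, name: str | None = None) -> RoiMask:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T.astype(bool)
    return RoiMask(name=name or Path(path).stem, mask=arr)


def write_plan(plan: ArcPlan, path) -> None:
    Path(path).write_text(json.dumps(plan.to_dict(), sort_keys=True))


def read_plan(path) -> ArcPlan:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed plan JSON ({e})") from e
    for key in ("angles", "layers", "collimated", "prescription"):
        if key not in d:
            raise ValueError(f"{path}: plan file missing field {key!r}")
    return ArcPlan.from_dict(d)


def write_metrics(metrics: PlanMetrics | dict, path) -> None:
    d = metrics.to_dict() if isinstance(metrics, PlanMetrics) else dict(metrics)
    Path(path).write_text(json.dumps(d, sort_keys=True, indent=1))


def format_report(metrics_by_plan: dict[str, PlanMetrics]) -> str:
    """Plan-comparison table: energy layers, spots, ST %, protons, delivery
    time, CI, HI, worst-case CTV D95 and External mean dose."""
    if not metrics_by_plan:
        raise ValueError("no plans to report")
    cols = [
        ("No. EL", lambda m: f"{m.n_energy_layers_incl_st}"),
        ("No. spots", lambda m: f"{m.n_spots}"),
        ("% ST", lambda m: f"{m.st_fraction_pct:.1f}"),
        ("Protons (1e9)", lambda m: f"{m.total_protons / 1e9:.1f}"),
        ("Time [s]", lambda m: "-" if m.delivery_time_s is None else f"{m.delivery_time_s:.0f}"),
        ("CI", lambda m: f"{m.ci:.2f}"),
        ("HI", lambda m: f"{m.hi:.2f}"),
        ("WC D95 [%]", lambda m: "-" if m.worst_case_d95_pct is None else f"{m.worst_case_d95_pct:.1f}"),
        ("Ext Dmean", lambda m: f"{m.external_mean:.2f}"),
    ]
    name_w = max(len(k) for k in metrics_by_plan) + 2
    header = "Plan".ljust(name_w) + "  ".join(c[0].rjust(12) for c in cols)
    lines = [header, "-" * len(header)]
    for name, m in metrics_by_plan.items():
        lines.append(name.ljust(name_w) + "  ".join(c[1](m).rjust(12) for c in cols))
    return "\n".join(lines)


def write_report(metrics_by_plan: dict[str, PlanMetrics], path) -> None:
    Path(path).write_text(format_report(metrics_by_plan) + "\n")
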