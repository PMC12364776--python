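"""Plan-quality metrics and the 28-scenario worst-case robustness evaluation.

Conventions
-----------
* DVH values are computed on raw voxel dose samples without interpolation:
  D_v is the descending-sorted dose at 0-based index floor(v * N / 100)
  (clipped to the last sample), i.e. the dose just below the v % volume rank.
  For a uniform dose D95 = D5 = the dose; HI = D95/D5 = 1.
* Paddick CI = |TV intersect PIV|^2 / (|TV| * |PIV|) with PIV the set of
  voxels at or above the prescription dose; CI = 0 (with a warning) when the
  prescription isodose volume is empty.
* EUD_A = (mean(d^A))^(1/A), the generalized mean; A = 1 is the mean dose.
* The robustness evaluation uses 28 scenarios: 14 setup-shift directions
  (6 axial + 8 body diagonals, all normalized to 3 mm) crossed with SPR
  scales 0.965 and 1.035; the reported value is the worst-case CTV D95 over
  the set, as a percentage of the prescription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .beam import BeamModel
from .dose import Scenario, compute_dose
from .phantom import RoiMask, SprGrid
from .plans import ArcPlan


@dataclass
class Dvh:
    """Empirical cumulative dose-volume histogram on voxel samples."""

    roi: str
    doses_desc: np.ndarray  # sorted descending

    @property
    def n(self) -> int:
        return self.doses_desc.size

    def d_at_volume(self, volume_pct: float) -> float:
        """Dose level D_v (GyRBE) for a volume percentage v."""
        idx = min(int(np.floor(volume_pct / 100.0 * self.n)), self.n - 1)
        return float(self.doses_desc[idx])

    def curve(self, dose_axis: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(dose, volume fraction receiving >= dose), non-increasing 1 -> 0."""
        if dose_axis is None:
            dose_axis = np.linspace(0.0, float(self.doses_desc[0]) * 1.05 + 1e-9, 200)
        frac = np.searchsorted(-self.doses_desc, -dose_axis, side="right") / self.n
        return dose_axis, frac


def dvh(dose: np.ndarray, roi: RoiMask) -> Dvh:
    """DVH of a dose grid restricted to an ROI."""
    samples = np.asarray(dose)[roi.mask]
    if samples.size == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    return Dvh(roi=roi.name, doses_desc=np.sort(samples)[::-1])


def d_at_volume(h: Dvh, volume_pct: float) -> float:
    return h.d_at_volume(volume_pct)


def homogeneity_index(dose: np.ndarray, roi: RoiMask) -> float:
    """HI = D95/D5 for the CTV; 1 is perfectly flat."""
    h = dvh(dose, roi)
    d5 = h.d_at_volume(5.0)
    return h.d_at_volume(95.0) / d5 if d5 > 0 else 0.0


def paddick_ci(dose: np.ndarray, target: RoiMask, prescription: float) -> float:
    """Paddick conformity index at the prescription isodose."""
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    piv = np.asarray(dose) >= prescription
    tv = target.mask
    n_piv = int(np.count_nonzero(piv))
    n_tv = int(np.count_nonzero(tv))
    if n_piv == 0:
        warnings.warn("prescription isodose volume is empty; CI defined as 0")
        return 0.0
    overlap = int(np.count_nonzero(piv & tv))
    return overlap**2 / (n_tv * n_piv)


def eud(dose: np.ndarray, roi: RoiMask, a: float) -> float:
    """Generalized-mean dose (mean(d^A))^(1/A)."""
    if a == 0:
        raise ValueError("EUD exponent A = 0 (geometric mean) is unsupported")
    d = np.asarray(dose)[roi.mask].astype(float)
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    return float(np.mean(np.maximum(d, 1e-12) ** a) ** (1.0 / a))


# --------------------------------------------------------------------------
# Robustness evaluation
# --------------------------------------------------------------------------

def evaluation_scenarios(
    shift_cm: float = 0.3, spr_error: float = 0.035
) -> list[Scenario]:
    """The 28 evaluation scenarios: {6 axial + 8 diagonal setup shifts, all
    of norm 3 mm} x {SPR x 0.965, SPR x 1.035}."""
    dirs = []
    for ax in range(3):
        for sgn in (1.0, -1.0):
            e = np.zeros(3)
            e[ax] = sgn
            dirs.append(e)
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            for sz in (1.0, -1.0):
                dirs.append(np.array([sx, sy, sz]) / np.sqrt(3.0))
    scenarios = []
    for i, e in enumerate(dirs):
        for scale in (1.0 - spr_error, 1.0 + spr_error):
            scenarios.append(
                Scenario(
                    label=f"shift{i:02d}_spr{scale:.3f}",
                    shift=tuple(shift_cm * e),
                    spr_scale=scale,
                )
            )
    return scenarios


def worst_case_d95(
    grid: SprGrid,
    plan: ArcPlan,
    beam: BeamModel,
    target: RoiMask,
    weights: np.ndarray | None = None,
    scenarios: list[Scenario] | None = None,
) -> float:
    """Minimum over the evaluation scenarios of D95(CTV) as a percentage of
    the prescription.  Dose is recomputed per scenario on the CTV voxels."""
    if scenarios is None:
        scenarios = evaluation_scenarios()
    if weights is None:
        weights = plan.weights
    worst = np.inf
    for sc in scenarios:
        dose = compute_dose(grid, plan, beam, weights=weights, scenario=sc,
                            rows_mask=target.mask)
        d95 = dvh(dose, target).d_at_volume(95.0)
        worst = min(worst, d95)
    return 100.0 * worst / plan.prescription


# --------------------------------------------------------------------------
# Plan composition metrics
# --------------------------------------------------------------------------

def st_fraction(plan: ArcPlan, weights: np.ndarray | None = None) -> float:
    """Percentage of irradiated protons delivered by shoot-through spots.

    MU is proportional to protons, so the MU fraction and the proton fraction
    are identical."""
    table = plan.spot_table()
    w = np.asarray(weights, dtype=float) if weights is not None else table["mu"]
    total = w.sum()
    if total <= 0:
        return 0.0
    return 100.0 * float(w[table["is_st"]].sum()) / float(total)


def total_protons(
    plan: ArcPlan, beam: BeamModel, weights: np.ndarray | None = None
) -> float:
    """Total irradiated protons for the full course (all fractions)."""
    w = np.asarray(weights, dtype=float) if weights is not None else plan.weights
    return beam.mu_to_protons(float(w.sum()))


@dataclass
class PlanMetrics:
    """Table-style plan metrics."""

    n_energy_layers: int
    n_energy_layers_incl_st: int
    n_spots: int
    st_fraction_pct: float
    total_protons: float
    ci: float
    hi: float
    external_mean: float
    worst_case_d95_pct: float | None = None
    delivery_time_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_energy_layers": self.n_energy_layers,
            "n_energy_layers_incl_st": self.n_energy_layers_incl_st,
            "n_spots": self.n_spots,
            "st_fraction_pct": self.st_fraction_pct,
            "total_protons": self.total_protons,
            "ci": self.ci,
            "hi": self.hi,
            "external_mean": self.external_mean,
            "worst_case_d95_pct": self.worst_case_d95_pct,
            "delivery_time_s": self.delivery_time_s,
        }


def compute_plan_metrics(
    grid: SprGrid,
    rois: dict[str, RoiMask],
    target_name: str,
    plan: ArcPlan,
    beam: BeamModel,
    weights: np.ndarray | None = None,
    include_worst_case: bool = True,
    scenarios: list[Scenario] | None = None,
    dose: np.ndarray | None = None,
) -> PlanMetrics:
    """Evaluate CI, HI, External mean dose, ST fraction, proton and layer
    counts (and optionally the 28-scenario worst-case CTV D95) for a plan."""
    if weights is None:
        weights = plan.weights
    external = rois["External"]
    target = rois[target_name]
    if dose is None:
        dose = compute_dose(grid, plan, beam, weights=weights, rows_mask=external.mask)
    table = plan.spot_table()
    w = np.asarray(weights, dtype=float)
    layer_active = np.zeros(len(plan.layers), dtype=bool)
    layer_active[np.unique(table["layer_index"][w > 0])] = True
    n_bragg = sum(
        1 for i, l in enumerate(plan.layers) if layer_active[i] and not l.is_st
    )
    wc = None
    if include_worst_case:
        wc = worst_case_d95(grid, plan, beam, target, weights=w, scenarios=scenarios)
    return PlanMetrics(
        n_energy_layers=n_bragg,
        n_energy_layers_incl_st=int(layer_active.sum()),
        n_spots=int(np.count_nonzero(w)),
        st_fraction_pct=st_fraction(plan, w),
        total_protons=total_protons(plan, beam, w),
        ci=paddick_ci(dose, target, plan.prescription),
        hi=homogeneity_index(dose, target),
        external_mean=float(np.asarray(dose)[external.mask].mean()),
        worst_case_d95_pct=wc,
    )
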