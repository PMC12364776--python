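"""High-level Model/Results interface around plan building and optimization.

``ArcPlanModel`` bundles a geometry (SPR grid + ROI masks), a beam model and
the plan settings; ``fit()`` builds the plan skeleton, assembles the
influence matrices, runs the two-phase spot-weight optimization and returns
an ``ArcPlanResults`` carrying the optimized weights, plan-quality metrics,
the delivery-time breakdown and range-verification helpers, with a
``summary()`` table in the style of a plan report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .beam import BeamModel
from .dose import NOMINAL, InfluenceMatrix, Scenario, compute_dose, influence_matrix
from .evaluate import PlanMetrics, compute_plan_metrics, dvh
from .optimize import (
    Objective,
    ObjectiveTerm,
    OptimizationProblem,
    OptimizationResult,
    optimize_weights,
    phantom_objectives,
    robust_scenario_set_for_optimization,
)
from .phantom import PhantomSpec, RoiMask, SprGrid, build_phantom
from .plans import ArcPlan, PlanSettings, build_arc_plan
from .timing import TimeBreakdown, TimeModel, plan_time
from .verification import RangeRecord, run_verification, summarize_by_angle


class ArcPlanModel:
    """An optimizable treatment-plan model for one geometry and target.

    Parameters
    ----------
    grid, rois : phantom geometry (SPR grid and ROI masks)
    target : CTV name; must be a key of ``rois``
    settings : plan-construction settings (directions, ST, collimation, ...)
    objectives : objective terms; defaults to the study's phantom set
    robust : optimize robust terms over the 9-scenario worst-case composite
    beam : machine model
    """

    def __init__(
        self,
        grid: SprGrid,
        rois: dict[str, RoiMask],
        target: str,
        settings: PlanSettings | None = None,
        objectives: list[ObjectiveTerm] | None = None,
        falloff_weight_factor: float = 1.0,
        robust: bool = False,
        beam: BeamModel | None = None,
    ) -> None:
        if target not in rois:
            raise ValueError(f"target {target!r} not among ROIs {sorted(rois)}")
        self.grid = grid
        self.rois = rois
        self.target = target
        self.settings = settings if settings is not None else PlanSettings()
        self.beam = beam if beam is not None else BeamModel()
        self.robust = robust
        if objectives is None:
            objectives = phantom_objectives(
                target, falloff_weight_factor=falloff_weight_factor, robust=robust
            )
        elif not robust:
            objectives = [replace(t, robust=False) for t in objectives]
        self.objectives = objectives
        self._plan: ArcPlan | None = None
        self._matrices: list[InfluenceMatrix] | None = None

    @classmethod
    def from_phantom(
        cls,
        target: str = "CTV_small",
        spacing: float = 0.25,
        spec: PhantomSpec | None = None,
        **kwargs,
    ) -> "ArcPlanModel":
        """Build the virtual phantom at the given spacing and wrap it."""
        grid, rois = build_phantom(spec=spec, spacing=spacing, target_choice=target)
        return cls(grid, rois, target, **kwargs)

    # ------------------------------------------------------------------

    def build_plan(self) -> ArcPlan:
        if self._plan is None:
            self._plan = build_arc_plan(self.grid, self.rois[self.target], self.beam, self.settings)
        return self._plan

    def influence(self) -> list[InfluenceMatrix]:
        """Influence matrices (nominal first, plus the robust scenario set
        when robust optimization is enabled), rows on the External volume."""
        if self._matrices is None:
            plan = self.build_plan()
            rows = self.rois["External"].mask
            scenarios = [NOMINAL]
            if self.robust:
                scenarios = robust_scenario_set_for_optimization()
            self._matrices = [
                influence_matrix(self.grid, plan, self.beam, scenario=sc, rows_mask=rows)
                for sc in scenarios
            ]
        return self._matrices

    def fit(
        self,
        maxiter: int = 200,
        tol: float = 1e-6,
        seed: int = 17,
        normalize_coverage: bool = True,
    ) -> "ArcPlanResults":
        """Run the two-phase optimization and return the results object.

        With ``normalize_coverage`` (the default) the final plan is
        normalized to target coverage: all spot weights are scaled by one
        global factor so that the nominal CTV D95 equals the prescription, the
        usual clinical convention that makes prescription-isodose metrics
        (Paddick CI) comparable across plans.  The factor is typically within
        a percent of unity.
        """
        plan = self.build_plan()
        mats = self.influence()
        objective = Objective(
            self.objectives, self.grid, self.rois, self.target,
            rows_mask=self.rois["External"].mask,
        )
        problem = OptimizationProblem(
            plan=plan, matrices=mats, objective=objective, beam=self.beam,
            layers_final=self.settings.layers_final, maxiter=maxiter, tol=tol,
            seed=seed,
        )
        result = optimize_weights(problem)
        factor = 1.0
        if normalize_coverage:
            ctv = self.rois[self.target]
            dose_ctv = compute_dose(
                self.grid, plan, self.beam, weights=result.weights,
                rows_mask=ctv.mask,
            )
            d95 = dvh(dose_ctv, ctv).d_at_volume(95.0)
            if d95 > 0:
                factor = plan.prescription / d95
                result.weights = result.weights * factor
        plan.weights = result.weights
        return ArcPlanResults(
            model=self, plan=plan, result=result, normalization_factor=factor
        )


@dataclass
class ArcPlanResults:
    """Optimized plan with lazy metrics and reporting helpers."""

    model: ArcPlanModel
    plan: ArcPlan
    result: OptimizationResult
    normalization_factor: float = 1.0
    _dose: np.ndarray | None = field(default=None, repr=False)
    _metrics: PlanMetrics | None = field(default=None, repr=False)

    @property
    def weights(self) -> np.ndarray:
        return self.result.weights

    @property
    def objective_history(self) -> list[float]:
        return self.result.full_history

    def dose(self) -> np.ndarray:
        """Nominal dose grid (GyRBE) inside the External contour."""
        if self._dose is None:
            self._dose = compute_dose(
                self.model.grid, self.plan, self.model.beam,
                weights=self.weights,
                rows_mask=self.model.rois["External"].mask,
            )
        return self._dose

    def dvh(self, roi: str):
        return dvh(self.dose(), self.model.rois[roi])

    def metrics(self, include_worst_case: bool = False) -> PlanMetrics:
        if self._metrics is None or (
            include_worst_case and self._metrics.worst_case_d95_pct is None
        ):
            m = compute_plan_metrics(
                self.model.grid, self.model.rois, self.model.target,
                self.plan, self.model.beam, weights=self.weights,
                include_worst_case=include_worst_case, dose=self.dose(),
            )
            m.delivery_time_s = self.delivery_time().total
            self._metrics = m
        return self._metrics

    def delivery_time(self, model: TimeModel | None = None) -> TimeBreakdown:
        return plan_time(self.plan, model=model, beam=self.model.beam)

    def verify_range(self, perturbed_grid: SprGrid) -> list[RangeRecord]:
        """Residual-range verification of the ST spots against a perturbed
        geometry."""
        return run_verification(self.plan, self.model.grid, perturbed_grid, self.model.beam)

    def summary(self, include_worst_case: bool = False) -> str:
        m = self.metrics(include_worst_case=include_worst_case)
        s = self.model.settings
        mode = "Arc" if s.angles is None else f"{len(s.angles)}-beam"
        if s.shoot_through:
            mode += "+ST"
        if s.collimated:
            mode += "+Coll"
        lines = [
            "Plan summary",
            "=" * 56,
            f"{'plan type':<28}{mode}",
            f"{'target':<28}{self.model.target}",
            f"{'prescription [GyRBE]':<28}{self.plan.prescription:.1f} in {self.plan.fractions} fx",
            f"{'directions':<28}{self.plan.angles.size}",
            f"{'energy layers (Bragg)':<28}{m.n_energy_layers}",
            f"{'energy layers (incl. ST)':<28}{m.n_energy_layers_incl_st}",
            f"{'spots':<28}{m.n_spots}",
            f"{'ST fraction [%]':<28}{m.st_fraction_pct:.1f}",
            f"{'protons (1e9)':<28}{m.total_protons / 1e9:.2f}",
            f"{'delivery time [s]':<28}{m.delivery_time_s:.1f}",
            f"{'CI (Paddick)':<28}{m.ci:.3f}",
            f"{'HI (D95/D5)':<28}{m.hi:.3f}",
            f"{'External Dmean [GyRBE]':<28}{m.external_mean:.2f}",
        ]
        if m.worst_case_d95_pct is not None:
            lines.append(f"{'worst-case CTV D95 [%]':<28}{m.worst_case_d95_pct:.1f}")
        lines.append(
            f"{'final objective':<28}{self.result.objective_value:.4g}"
        )
        return "\n".join(lines)
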