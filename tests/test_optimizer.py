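"""Objective terms, robust composite, solver behaviour and the
deliverability filters."""

import numpy as np
import pytest
import scipy.sparse as sp

from arcst import (
    ArcPlan,
    BeamModel,
    EnergyLayer,
    Objective,
    ObjectiveTerm,
    OptimizationProblem,
    optimize_weights,
    phantom_objectives,
    robust_scenario_set_for_optimization,
)
from arcst.dose import InfluenceMatrix
from arcst.optimize import _projected_gradient, filter_layers, filter_spots
from arcst.phantom import RoiMask, SprGrid


def term_value(t, d, dist=None):
    return Objective._term_value_grad(t, np.asarray(d, float), dist)[0]


class TestObjectiveTerms:
    def test_uniform_zero_at_target_dose(self):
        t = ObjectiveTerm("uniform", "CTV", 20.0, dose=60.0)
        assert term_value(t, np.full(10, 60.0)) == 0.0
        assert term_value(t, np.full(10, 59.0)) == pytest.approx(1.0)

    def test_max_eud_quadratic_excess(self):
        # A = 1 EUD is the mean dose: d = 6 vs limit 4 -> (6-4)^2
        t = ObjectiveTerm("max_eud", "OAR", 3.0, dose=4.0, eud_a=1.0)
        assert term_value(t, np.full(5, 6.0)) == pytest.approx(4.0)
        assert term_value(t, np.full(5, 3.0)) == 0.0

    def test_max_dvh_penalizes_cheapest_violators(self):
        # at most 25 % may exceed 10; doses {12, 11, 9, 8}: two violators but
        # one is allowed, and the cheaper one (the 11) pays the penalty
        t = ObjectiveTerm("max_dvh", "CTV", 1.0, dose=10.0, volume=25.0)
        assert term_value(t, [12.0, 11.0, 9.0, 8.0]) == pytest.approx((11.0 - 10.0) ** 2 / 4)
        # exactly at the allowed volume: no penalty
        t50 = ObjectiveTerm("max_dvh", "CTV", 1.0, dose=10.0, volume=50.0)
        assert term_value(t50, [12.0, 11.0, 9.0, 8.0]) == 0.0

    def test_min_dvh_penalizes_cold_required_voxels(self):
        # at least 75 % must reach 10; doses {12, 11, 9, 1}: the 9 (inside the
        # required top-3) is penalized, the 1 is allowed to stay cold
        t = ObjectiveTerm("min_dvh", "CTV", 1.0, dose=10.0, volume=75.0)
        assert term_value(t, [12.0, 11.0, 9.0, 1.0]) == pytest.approx(1.0 / 4)
        assert term_value(t, [12.0, 11.0, 10.0, 1.0]) == 0.0

    def test_falloff_reference_dose_interpolates_with_distance(self):
        # 60 -> 0 over 1 cm: at 0.5 cm the allowed dose is 30 GyRBE
        t = ObjectiveTerm("falloff", "External", 0.5, dose=60.0, dose_low=0.0, distance=1.0)
        dist = np.array([0.5])
        assert term_value(t, [30.0], dist) == 0.0
        assert term_value(t, [40.0], dist) == pytest.approx(100.0)
        # beyond the falloff distance the floor applies
        assert term_value(t, [5.0], np.array([3.0])) == pytest.approx(25.0)

    def test_eud_a_zero_rejected(self):
        t = ObjectiveTerm("max_eud", "OAR", 1.0, dose=4.0, eud_a=0.0)
        with pytest.raises(ValueError):
            term_value(t, [1.0, 2.0])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveTerm("median_dose", "CTV", 1.0)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(20.0, 80.0, size=16)
        dist = rng.uniform(0.0, 2.0, size=16)
        terms = [
            ObjectiveTerm("uniform", "CTV", 1.0, dose=60.0),
            ObjectiveTerm("max_eud", "OAR", 1.0, dose=40.0, eud_a=3.0),
            ObjectiveTerm("falloff", "External", 1.0, dose=60.0, dose_low=10.0, distance=0.5),
        ]
        for t in terms:
            f0, g = Objective._term_value_grad(t, d, dist)
            eps = 1e-6
            for i in (0, 7, 15):
                dp = d.copy()
                dp[i] += eps
                f1, _ = Objective._term_value_grad(t, dp, dist)
                assert (f1 - f0) / eps == pytest.approx(g[i], rel=1e-3, abs=1e-8)


def _toy_problem(influence_cols, terms, target_rows=None):
    """A 1-D 'grid' whose voxels are the influence rows; CTV/OAR/External all
    alias the same voxels unless overridden."""
    a = np.atleast_2d(np.asarray(influence_cols, float))
    n_vox = a.shape[0]
    grid = SprGrid(1.0, np.zeros(3), np.ones((n_vox, 1, 1)))
    full = np.ones((n_vox, 1, 1), dtype=bool)
    mask = full if target_rows is None else np.zeros_like(full)
    if target_rows is not None:
        mask[target_rows, 0, 0] = True
    rois = {
        "External": RoiMask("External", full),
        "CTV": RoiMask("CTV", mask),
        "OAR": RoiMask("OAR", full),
    }
    obj = Objective(terms, grid, rois, "CTV", rows_mask=full)
    im = InfluenceMatrix(sp.csr_matrix(a), np.arange(n_vox), (n_vox, 1, 1))
    return obj, im


class TestSolver:
    def test_single_spot_recovers_analytic_weight(self):
        a = 0.25
        obj, im = _toy_problem([[a]], [ObjectiveTerm("uniform", "CTV", 1.0, dose=60.0)])
        w, hist = _projected_gradient(
            lambda w: obj.value_and_grad(w, [im])[:2], np.array([1.0]),
            np.zeros(1), maxiter=500, tol=1e-12,
        )
        assert w[0] == pytest.approx(60.0 / a, rel=1e-3)

    def test_two_identical_spots_stay_symmetric(self):
        a = np.array([[0.3, 0.3], [0.2, 0.2]])
        obj, im = _toy_problem(a, [ObjectiveTerm("uniform", "CTV", 1.0, dose=60.0)])
        w, _ = _projected_gradient(
            lambda w: obj.value_and_grad(w, [im])[:2],
            np.array([1.0, 1.0]), np.zeros(2), maxiter=300, tol=1e-12,
        )
        assert w[0] == pytest.approx(w[1], rel=1e-9)

    def test_history_non_increasing_within_each_phase(self, small_fit):
        # the objective may jump at the filtering step between phases, but is
        # monotone across accepted iterates inside each phase
        for phase in ("phase1", "phase2"):
            h = np.asarray(small_fit.result.history[phase])
            assert np.all(np.diff(h) <= 1e-9)

    def test_robust_term_takes_worst_scenario(self):
        terms = [ObjectiveTerm("uniform", "CTV", 1.0, dose=60.0, robust=True)]
        obj, im_nom = _toy_problem([[0.5]], terms)
        im_bad = InfluenceMatrix(sp.csr_matrix([[0.25]]), im_nom.rows, im_nom.grid_shape, "bad")
        w = np.array([100.0])
        f_nom = obj.value(w, [im_nom, im_nom])
        f_rob = obj.value(w, [im_nom, im_bad])
        # the degraded scenario (dose 25 vs target 60) dominates
        assert f_rob == pytest.approx((25.0 - 60.0) ** 2)
        assert f_rob > f_nom

    def test_robust_problem_requires_extra_scenarios(self, water_slab, beam):
        from arcst import build_arc_plan, PlanSettings
        from arcst.dose import influence_matrix

        grid, target = water_slab
        plan = build_arc_plan(grid, target, beam, PlanSettings(
            n_directions=1, layers_initial=2, layers_final=2))
        im = influence_matrix(grid, plan, beam, rows_mask=target.mask)
        terms = [ObjectiveTerm("uniform", "cube", 1.0, dose=60.0, robust=True)]
        obj = Objective(terms, grid, {"External": target, "cube": target},
                        "cube", rows_mask=target.mask)
        with pytest.raises(ValueError, match="robust"):
            OptimizationProblem(plan=plan, matrices=[im], objective=obj, beam=beam)


class TestScenarioSet:
    def test_nine_scenarios_nominal_once(self):
        scen = robust_scenario_set_for_optimization()
        assert len(scen) == 9
        assert sum(1 for s in scen if s.is_nominal) == 1

    def test_shift_magnitudes_are_3mm(self):
        scen = robust_scenario_set_for_optimization()
        shifts = [s for s in scen if not np.allclose(s.shift, 0.0)]
        assert len(shifts) == 6
        for s in shifts:
            assert np.linalg.norm(s.shift) == pytest.approx(0.3)
        sprs = sorted(s.spr_scale for s in scen if s.spr_scale != 1.0)
        assert sprs == pytest.approx([0.965, 1.035])


def _plan_with_layer_mus(mus, st_flags=None, direction_indices=None):
    st_flags = st_flags or [False] * len(mus)
    direction_indices = direction_indices or [0] * len(mus)
    plan = ArcPlan(angles=np.array([0.0, 90.0, 180.0, 270.0]))
    for mu, st, di in zip(mus, st_flags, direction_indices):
        plan.layers.append(
            EnergyLayer(di, 100.0 + mu, np.array([0.0]), np.array([0.0]),
                        np.array([float(mu)]), is_st=st)
        )
    return plan


class TestFilters:
    def test_keep_all_is_identity(self):
        plan = _plan_with_layer_mus([5.0, 3.0, 1.0])
        keep = filter_layers(plan, plan.weights, 3)
        assert keep.all()

    def test_lowest_mu_layer_removed(self):
        plan = _plan_with_layer_mus([5.0, 3.0, 1.0])
        keep = filter_layers(plan, plan.weights, 2)
        np.testing.assert_array_equal(keep, [True, True, False])

    def test_st_layers_exempt_from_removal(self):
        plan = _plan_with_layer_mus([5.0, 0.01, 3.0], st_flags=[False, True, False])
        keep = filter_layers(plan, plan.weights, 1)
        assert keep[1]  # ST survives despite tiny MU
        np.testing.assert_array_equal(keep, [True, True, False])

    def test_each_direction_keeps_its_best_bragg_layer(self):
        plan = _plan_with_layer_mus(
            [5.0, 4.0, 3.0, 0.5], direction_indices=[0, 0, 0, 1]
        )
        keep = filter_layers(plan, plan.weights, 2)
        # direction 1's only layer survives even though its MU is smallest
        assert keep[3]
        assert keep[0]

    def test_spot_floor(self):
        w = np.array([0.05, 0.0683, 1.0, 0.01])
        np.testing.assert_array_equal(
            filter_spots(w, 0.0683), [False, True, True, False]
        )

    def test_weights_respect_floor_after_full_optimization(self, small_fit):
        bm = BeamModel()
        w = small_fit.weights
        nz = w[w > 0]
        assert np.all(nz >= bm.min_spot_mu - 1e-12)

    def test_reoptimization_beats_naive_clipping(self, small_fit):
        # the phase-2 objective is no worse than clipping phase-1 weights
        res = small_fit.result
        assert res.history["phase2"][-1] <= res.history["phase2"][0] + 1e-12


class TestObjectiveDefaults:
    def test_phantom_objective_set_composition(self):
        terms = phantom_objectives("CTV_small", falloff_weight_factor=2.0)
        kinds = sorted(t.kind for t in terms)
        assert kinds == ["falloff", "falloff", "max_dvh", "max_eud", "min_dvh", "uniform"]
        by_kind = {t.kind: t for t in terms if t.kind != "falloff"}
        assert by_kind["uniform"].weight == 20.0 and by_kind["uniform"].dose == 60.0
        assert by_kind["min_dvh"].volume == 95.0 and by_kind["min_dvh"].weight == 5.0
        assert by_kind["max_dvh"].volume == 2.0 and by_kind["max_dvh"].weight == 10.0
        assert by_kind["max_eud"].dose == 4.0 and by_kind["max_eud"].weight == 3.0
        falloffs = [t for t in terms if t.kind == "falloff"]
        assert {(t.dose, t.dose_low, t.distance) for t in falloffs} == {
            (60.0, 0.0, 1.0), (60.0, 10.0, 0.5)
        }
        # fall-off weights scale with the sweep factor
        assert sorted(t.weight for t in falloffs) == [1.0, 2.0]
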