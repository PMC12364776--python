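"""Spot-weight optimization with DVH/EUD/fall-off objectives and robustness.

The optimization problem is the study's objective set: a quadratic uniform-dose
term on the CTV, one-sided min/max-DVH terms, a max-EUD term on the OAR and
two dose fall-off terms on the External volume, each weighted.  Robust terms
take the worst value over a small scenario set (minimax composite): nominal,
six 3 mm axial setup shifts and +/-3.5 % SPR scales (9 scenarios).

Optimization runs in two phases around the machine's deliverability filters:
phase 1 reweights all spots (nonnegativity only); energy layers are then
filtered to the final budget by total MU (shoot-through layers are structural
and exempt) and spots below the minimum spot meter (0.0683 MU) are removed;
phase 2 re-optimizes the survivors with the spot floor as a hard lower bound,
so clipping can only be improved on, never worsened.

The solver is a monotone projected-gradient method (Barzilai-Borwein step with
Armijo backtracking), so the objective history is non-increasing across
accepted iterates by construction and the run is deterministic for a given
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import distance_transform_edt

from .beam import BeamModel
from .dose import NOMINAL, InfluenceMatrix, Scenario
from .phantom import RoiMask, SprGrid
from .plans import ArcPlan

VALID_KINDS = ("uniform", "min_dvh", "max_dvh", "max_eud", "falloff")


@dataclass(frozen=True)
class ObjectiveTerm:
    """One weighted objective term.

    kind        one of uniform / min_dvh / max_dvh / max_eud / falloff
    roi         ROI name the term acts on (falloff acts on roi minus the CTV)
    dose        D0 (GyRBE): target level (uniform/DVH), E0 (max_eud),
                D_high (falloff)
    dose_low    falloff D_low (GyRBE)
    volume      DVH volume parameter in %
    eud_a       generalized-mean exponent A
    distance    falloff distance L in cm
    weight      term weight (>= 0)
    robust      evaluate as worst case over the optimization scenario set
    """

    kind: str
    roi: str
    weight: float
    dose: float | None = None
    dose_low: float | None = None
    volume: float | None = None
    eud_a: float | None = None
    distance: float | None = None
    robust: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def phantom_objectives(
    target_name: str,
    falloff_weight_factor: float = 1.0,
    robust: bool = True,
) -> list[ObjectiveTerm]:
    """The study's phantom objective set: uniform 60 GyRBE (w 20) on the CTV,
    min DVH 60 GyRBE to 95 % (w 5), max DVH 60 GyRBE to 2 % (w 10), max EUD
    (A = 1) 4 GyRBE (w 3) on the OAR, and External fall-offs 60->0 over 1 cm
    (w 0.5) and 60->10 over 0.5 cm (w 1), the last two scaled by the fall-off
    weight factor (1-4)."""
    f = falloff_weight_factor
    return [
        ObjectiveTerm("uniform", target_name, 20.0, dose=60.0, robust=robust),
        ObjectiveTerm("min_dvh", target_name, 5.0, dose=60.0, volume=95.0, robust=robust),
        ObjectiveTerm("max_dvh", target_name, 10.0, dose=60.0, volume=2.0, robust=robust),
        ObjectiveTerm("max_eud", "OAR", 3.0, dose=4.0, eud_a=1.0, robust=robust),
        ObjectiveTerm("falloff", "External", 0.5 * f, dose=60.0, dose_low=0.0, distance=1.0),
        ObjectiveTerm("falloff", "External", 1.0 * f, dose=60.0, dose_low=10.0, distance=0.5),
    ]


class Objective:
    """Evaluates the weighted objective set on influence-matrix rows.

    Bound to a grid, ROI set and target so that per-term row subsets and the
    distance-to-CTV map for fall-off terms are precomputed once.
    """

    def __init__(
        self,
        terms: list[ObjectiveTerm],
        grid: SprGrid,
        rois: dict[str, RoiMask],
        target_name: str,
        rows_mask: np.ndarray,
    ) -> None:
        self.terms = list(terms)
        self.target_name = target_name
        rows = np.flatnonzero(rows_mask.ravel())
        lookup = np.full(int(np.prod(grid.shape)), -1, dtype=np.int64)
        lookup[rows] = np.arange(rows.size)

        def roi_rows(mask: np.ndarray) -> np.ndarray:
            r = lookup[np.flatnonzero(mask.ravel())]
            return r[r >= 0]

        ctv = rois[target_name].mask
        # Euclidean distance (cm) from every voxel to the CTV surface
        dist = distance_transform_edt(~ctv, sampling=grid.spacing)
        self._term_rows: list[np.ndarray] = []
        self._term_dist: list[np.ndarray | None] = []
        for t in self.terms:
            if t.roi not in rois:
                raise ValueError(f"objective ROI {t.roi!r} not available")
            mask = rois[t.roi].mask
            if t.kind == "falloff":
                mask = mask & ~ctv
            r = roi_rows(mask)
            if r.size == 0:
                raise ValueError(f"objective ROI {t.roi!r} is empty on the dose rows")
            self._term_rows.append(r)
            if t.kind == "falloff":
                d = dist.ravel()[np.flatnonzero((rois[t.roi].mask & ~ctv).ravel())]
                keep = lookup[np.flatnonzero((rois[t.roi].mask & ~ctv).ravel())] >= 0
                self._term_dist.append(d[keep])
            else:
                self._term_dist.append(None)

    # -- single-term value/gradient on its own rows ---------------------------

    @staticmethod
    def _term_value_grad(
        t: ObjectiveTerm, d: np.ndarray, dist: np.ndarray | None
    ) -> tuple[float, np.ndarray]:
        n = d.size
        if t.kind == "uniform":
            diff = d - t.dose
            return float(np.mean(diff**2)), 2.0 * diff / n
        if t.kind == "max_dvh":
            allowed = int(np.floor(t.volume / 100.0 * n))
            order = np.argsort(-d, kind="stable")
            g = np.zeros(n)
            sel = order[allowed:]
            sel = sel[d[sel] > t.dose]
            if sel.size == 0:
                return 0.0, g
            diff = d[sel] - t.dose
            g[sel] = 2.0 * diff / n
            return float(np.sum(diff**2) / n), g
        if t.kind == "min_dvh":
            required = int(np.floor(t.volume / 100.0 * n))
            order = np.argsort(-d, kind="stable")
            g = np.zeros(n)
            sel = order[:required]
            sel = sel[d[sel] < t.dose]
            if sel.size == 0:
                return 0.0, g
            diff = d[sel] - t.dose
            g[sel] = 2.0 * diff / n
            return float(np.sum(diff**2) / n), g
        if t.kind == "max_eud":
            a = t.eud_a
            if a == 0:
                raise ValueError("EUD exponent A = 0 is unsupported")
            d_safe = np.maximum(d, 1e-12)
            m = float(np.mean(d_safe**a))
            eud = m ** (1.0 / a)
            excess = eud - t.dose
            if excess <= 0:
                return 0.0, np.zeros(n)
            # d(eud)/dd_i = (1/n) d_i^(a-1) m^(1/a - 1)
            g = 2.0 * excess * (d_safe ** (a - 1.0)) * m ** (1.0 / a - 1.0) / n
            return float(excess**2), g
        if t.kind == "falloff":
            dref = np.maximum(
                t.dose_low, t.dose - (t.dose - t.dose_low) * dist / t.distance
            )
            over = np.maximum(0.0, d - dref)
            return float(np.mean(over**2)), 2.0 * over / n
        raise AssertionError(t.kind)

    # -- full objective --------------------------------------------------------

    def value_and_grad(
        self, w: np.ndarray, matrices: list[InfluenceMatrix]
    ) -> tuple[float, np.ndarray, dict[str, float]]:
        """Total objective, its gradient w.r.t. the weights, and per-term
        values.  ``matrices[0]`` must be the nominal scenario; robust terms
        take the worst case over all matrices."""
        any_robust = any(t.robust for t in self.terms)
        doses = [matrices[0].dose(w)]
        if any_robust:
            doses += [m.dose(w) for m in matrices[1:]]
        n_rows = doses[0].size
        grad_rows = [np.zeros(n_rows) for _ in doses]
        total = 0.0
        per_term: dict[str, float] = {}
        for k, (t, rows, dist) in enumerate(
            zip(self.terms, self._term_rows, self._term_dist)
        ):
            scen_ids = range(len(doses)) if t.robust else (0,)
            best_f, best_g, best_s = -np.inf, None, 0
            for s in scen_ids:
                f, g = self._term_value_grad(t, doses[s][rows], dist)
                if f > best_f:
                    best_f, best_g, best_s = f, g, s
            total += t.weight * best_f
            per_term[f"{k}:{t.kind}:{t.roi}"] = t.weight * best_f
            grad_rows[best_s][rows] += t.weight * best_g
        grad_w = np.zeros(w.size)
        for s, g in enumerate(grad_rows):
            if np.any(g):
                grad_w += matrices[s].matrix.T @ g
        return total, grad_w, per_term

    def value(self, w: np.ndarray, matrices: list[InfluenceMatrix]) -> float:
        return self.value_and_grad(w, matrices)[0]


def objective_value(
    objective: Objective, w: np.ndarray, matrices: list[InfluenceMatrix]
) -> float:
    """Scalar objective for a weight vector (robust terms worst-case)."""
    return objective.value(w, matrices)


# --------------------------------------------------------------------------
# Scenario set for robust optimization
# --------------------------------------------------------------------------

def robust_scenario_set_for_optimization(
    shift_cm: float = 0.3, spr_error: float = 0.035
) -> list[Scenario]:
    """Nominal + six 3 mm axial setup shifts + SPR x (1 +/- 3.5 %):
    nine scenarios, worst-case composite applied to robust terms."""
    scenarios = [NOMINAL]
    for ax, name in enumerate("xyz"):
        for sgn, tag in ((1.0, "+"), (-1.0, "-")):
            shift = [0.0, 0.0, 0.0]
            shift[ax] = sgn * shift_cm
            scenarios.append(Scenario(label=f"shift{tag}{name}", shift=tuple(shift)))
    scenarios.append(Scenario(label="spr+", spr_scale=1.0 + spr_error))
    scenarios.append(Scenario(label="spr-", spr_scale=1.0 - spr_error))
    return scenarios


# --------------------------------------------------------------------------
# Solver
# --------------------------------------------------------------------------

def _projected_gradient(
    fun_grad,
    w0: np.ndarray,
    lower: np.ndarray,
    maxiter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list[float]]:
    """Monotone projected gradient with Barzilai-Borwein step and Armijo
    backtracking.  Returns the final iterate and the objective history (one
    entry per accepted iterate, non-increasing by construction)."""
    w = np.maximum(np.asarray(w0, dtype=float), lower)
    f, g = fun_grad(w)
    history = [f]
    step = 1.0 / max(np.linalg.norm(g), 1e-12)
    for _ in range(maxiter):
        w_new = np.maximum(w - step * g, lower)
        delta = w_new - w
        if np.linalg.norm(delta) <= tol * max(1.0, np.linalg.norm(w)):
            break
        f_new, g_new = fun_grad(w_new)
        # Armijo backtracking on the projected step
        bt = 0
        while f_new > f + 1e-4 * np.dot(g, delta) and bt < 30:
            step *= 0.5
            w_new = np.maximum(w - step * g, lower)
            delta = w_new - w
            f_new, g_new = fun_grad(w_new)
            bt += 1
        if f_new > f:  # no descent found
            break
        # Barzilai-Borwein step for the next iterate
        y = g_new - g
        sy = float(np.dot(delta, y))
        if sy > 0:
            step = float(np.dot(delta, delta)) / sy
        w, f, g = w_new, f_new, g_new
        history.append(f)
        if not np.isfinite(f):
            raise FloatingPointError("objective became non-finite")
    return w, history


# --------------------------------------------------------------------------
# Deliverability filters
# --------------------------------------------------------------------------

def filter_layers(
    plan: ArcPlan, weights: np.ndarray, final_count: int
) -> np.ndarray:
    """Boolean keep-mask over plan.layers retaining the ``final_count``
    Bragg layers with the largest total MU (ties to lower energy first).

    Shoot-through layers are structural and exempt from removal, and every
    direction keeps at least its best Bragg layer when it has one.
    """
    table = plan.spot_table()
    n_layers = len(plan.layers)
    layer_mu = np.zeros(n_layers)
    np.add.at(layer_mu, table["layer_index"], np.asarray(weights, dtype=float))
    keep = np.zeros(n_layers, dtype=bool)
    bragg = [i for i, l in enumerate(plan.layers) if not l.is_st]
    for i, l in enumerate(plan.layers):
        if l.is_st:
            keep[i] = True
    if final_count >= len(bragg):
        for i in bragg:
            keep[i] = True
        return keep
    # per-direction floor: the best Bragg layer of each direction survives
    order_key = sorted(bragg, key=lambda i: (-layer_mu[i], plan.layers[i].energy))
    forced = {}
    for i in order_key:
        d = plan.layers[i].direction_index
        if d not in forced:
            forced[d] = i
    chosen = set(forced.values())
    for i in order_key:
        if len(chosen) >= final_count:
            break
        chosen.add(i)
    for i in chosen:
        keep[i] = True
    return keep


def filter_spots(weights: np.ndarray, min_spot_mu: float) -> np.ndarray:
    """Boolean mask of spots meeting the minimum spot meter (MU floor)."""
    return np.asarray(weights, dtype=float) >= min_spot_mu


# --------------------------------------------------------------------------
# Problem / result containers and the two-phase driver
# --------------------------------------------------------------------------

@dataclass
class OptimizationProblem:
    plan: ArcPlan
    matrices: list[InfluenceMatrix]  # nominal first
    objective: Objective
    beam: BeamModel
    layers_final: int = 240
    maxiter: int = 200
    tol: float = 1e-6
    seed: int = 17

    def __post_init__(self) -> None:
        if any(t.robust for t in self.objective.terms) and len(self.matrices) < 2:
            raise ValueError("robust terms require at least one non-nominal scenario")


@dataclass
class OptimizationResult:
    weights: np.ndarray
    history: dict[str, list[float]]
    layer_keep: np.ndarray
    active_spots: np.ndarray
    counts: dict[str, int]
    per_term: dict[str, float]
    objective_value: float

    @property
    def full_history(self) -> list[float]:
        return list(self.history.get("phase1", [])) + list(self.history.get("phase2", []))


def optimize_weights(problem: OptimizationProblem) -> OptimizationResult:
    """Two-phase optimization: all spots, then layer/spot filtering, then
    re-optimization of the survivors above the MU floor.  Deterministic for a
    given problem (uniform initialization at 2x the minimum spot MU)."""
    plan = problem.plan
    beam = problem.beam
    mats = problem.matrices
    obj = problem.objective
    n = plan.spot_count

    def fg_all(w):
        f, g, _ = obj.value_and_grad(w, mats)
        return f, g

    w0 = np.full(n, 2.0 * beam.min_spot_mu)
    w1, hist1 = _projected_gradient(
        fg_all, w0, np.zeros(n), maxiter=problem.maxiter, tol=problem.tol
    )

    keep_layers = filter_layers(plan, w1, problem.layers_final)
    table = plan.spot_table()
    spot_in_kept_layer = keep_layers[table["layer_index"]]
    w1 = np.where(spot_in_kept_layer, w1, 0.0)
    active = spot_in_kept_layer & filter_spots(w1, beam.min_spot_mu)
    counts = {
        "spots_initial": n,
        "layers_initial": len(plan.layers),
        "layers_kept": int(keep_layers.sum()),
        "spots_after_filter": int(active.sum()),
    }
    if not np.any(active):
        raise RuntimeError("all spots were filtered out; check objective scales")

    sub = [
        InfluenceMatrix(
            matrix=m.matrix[:, active].tocsr(),
            rows=m.rows,
            grid_shape=m.grid_shape,
            scenario=m.scenario,
        )
        for m in mats
    ]

    def fg_active(wa):
        f, g, _ = obj.value_and_grad(wa, sub)
        return f, g

    wa0 = np.maximum(w1[active], beam.min_spot_mu)
    lb = np.full(int(active.sum()), beam.min_spot_mu)
    wa, hist2 = _projected_gradient(
        fg_active, wa0, lb, maxiter=problem.maxiter, tol=problem.tol
    )
    w_final = np.zeros(n)
    w_final[active] = wa
    f_final, _, per_term = obj.value_and_grad(wa, sub)
    # layers that lost all spots to the MU floor count as removed
    layer_has_mu = np.zeros(len(plan.layers), dtype=bool)
    np.add.at(layer_has_mu, table["layer_index"][w_final > 0], True)
    counts["layers_final"] = int(layer_has_mu.sum())
    counts["layers_final_bragg"] = int(
        sum(
            1
            for i, l in enumerate(plan.layers)
            if layer_has_mu[i] and not l.is_st
        )
    )
    counts["spots_final"] = int(np.count_nonzero(w_final))
    return OptimizationResult(
        weights=w_final,
        history={"phase1": hist1, "phase2": hist2},
        layer_keep=keep_layers,
        active_spots=active,
        counts=counts,
        per_term=per_term,
        objective_value=f_final,
    )
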