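# Methods

This note documents the models, numerical choices and limitations behind
`arcst`: a desk-scale simulation of upright static proton arcs with
shoot-through (ST) layers, from phantom construction through spot-weight
optimization, plan evaluation, delivery timing and residual-range
verification.

## Geometry and phantom

All computations use the patient frame x = left, y = anterior, z = superior
(cm), isotropic voxels with half-open boxes, and a parallel-beam geometry:
a beam direction is an azimuth in the axial plane (0° entering from
anterior, clockwise from superior) and all spot rays of a direction are
parallel. Parallel rays keep the water-equivalent geometry exact and avoid
committing to an unspecified source-axis distance.

The virtual phantom is an ellipsoid of water (half-axes 10, 8.5, 10 cm)
containing an air cylinder (d = 2 cm, l = 5 cm, axis left–right, centre
(+5.5, +3, 0)), a bone cylinder (d = 3.5 cm, l = 8 cm, axis left–right,
centre (−5, −3, 0)), an OAR ellipsoid (half-axes 2 × 3 × 4 cm at (0, +5, 0))
and one of three centred targets: a 3 cm cube, or 4.5/6 cm cubes with two
full-height cutout cuboids forming an H (cutouts opening toward ±y). The
exact inclusion placements are a package convention (only a qualitative layout is
established for such benchmark phantoms): laterally off-axis so that part of the arc traverses air and
bone, with the OAR abutting the target anteriorly. SPR values are water 1.0,
air 0.001, cortical-bone-like 1.6 — standard clinical magnitudes. Default
voxel pitch is 0.25 cm; all shipped end-to-end runs use 0.5 cm to keep a
full optimization on one CPU in minutes (problem sizes: ≈ 28 500 body
voxels, ≈ 7 000–10 000 spots, ≈ 28 M influence entries).

Perturbations: global/regional SPR scaling (exact on line integrals), rigid
setup shifts (nearest-neighbour resampling, preserving discrete material
classes), and sub-volume displacement (vacated voxels become air). An
*asymmetric* phantom variant adds a 4 cm-radius shoulder-like half-cylinder
protrusion; displacing it emulates an inter-fractional anatomy change
without patient data.

## Beam model

The machine spans 5–230 MeV. The package uses the Bragg–Kleeman law
R = αE^p with α = 0.0022 cm·MeV⁻ᵖ, p = 1.77 and range straggling
σ_R = 0.012·R^0.935 cm — the standard analytic parameterization of
therapeutic proton depth dose. The depth-dose curve is the fluence-derivative
profile ∝ (R − z)^(1/p − 1), bin-averaged exactly through its integrable
end-of-range singularity and convolved with the straggling Gaussian, then
normalized to unit integral over depth. At 230 MeV (R ≈ 33.3 cm) a ≤ 20 cm
body sees only the entrance plateau (max/min < 1.5) — the defining property
of shoot-through spots.

Lateral spread sums in quadrature an in-air entrance sigma
σ_air(E) = 0.40 + 0.90·(1 − (E − 5)/225) cm — 0.40 cm at 230 MeV growing to
1.30 cm at 5 MeV, encoding the penumbra broadening of nozzle energy
selection — and in-patient multiple scattering
σ_MCS = 0.021·R·(wed/R)^1.5 cm (≈ 2.1 % of range at end of range). Neither
quantity is publicly documented for the modelled machine class; both are declared
package constants with plausible magnitudes. 64 energy levels uniform in
range emulate the binary range-shifter plates (≈ 0.5 cm layer spacing).
MU ↔ protons uses the fixed point 0.0683 MU = 5.63·10⁶ protons; a constant
RBE of 1.1 multiplies physical dose. One absolute-dose constant
(8.5·10⁻⁸ Gy·cm³ per proton) sets the MU scale; every reported metric is
relative, so it only affects MU totals and beam-on time.

## Plans and dose

Plans have 20 uniformly spaced directions by default (IMPT comparators use
explicit angle lists). Per direction, energy layers sample the target's WET
interval ± one straggling sigma uniformly in range, snapped to machine
levels and deduplicated; each Bragg layer covers the target voxels whose WET
lies within half the inter-layer range spacing of its range. Spots sit on a
rectangular lattice (0.6 cm pitch ≈ 1.5× the finest spot sigma, anchored at
the beam axis so ST and Bragg layers share the lattice) covering the slab's
beam's-eye-view projection dilated by margin = margin_factor · σ_air(E)
(1.0 uncollimated, 1.25 collimated, the margin that performs best for
collimated plans in this configuration). The ST layer per direction is a 230 MeV layer covering the *full*
target projection with margins. Collimated plans attach per-layer apertures:
the slab projection dilated by the same margin, stored as a signed-distance
field with an error-function transmission edge of width 0.1 cm.

Water-equivalent thickness is computed two ways: an exact voxel-walking ray
tracer (every voxel chord × SPR; used for range verification and as the
reference) and a vectorized midpoint-rule sampler at half-voxel steps (used
to build per-voxel water-equivalent depth for dose kernels). Spot dose at a
voxel is depth-dose(WED) × a normalized lateral Gaussian of σ(E, WED) ×
aperture transmission × RBE, truncated at 3.5 lateral sigma and R + 3σ_R in
depth (< 0.5 % of spot dose). Influence matrices are sparse (voxel, spot)
maps of dose per MU, restricted to the External contour; dose is exactly
linear in the weights. Setup-error scenarios translate the beam geometry
relative to the grid (no resampling artefacts in influence columns;
consequently a shift component along a given beam axis leaves that beam
unchanged — the usual isocenter-shift approximation); density/range errors
scale the SPR globally before WED computation.

## Optimization

The objective set mirrors the study configuration: uniform 60 GyRBE on the
CTV (weight 20), min-DVH 60 GyRBE to 95 % (5), max-DVH 60 GyRBE to 2 % (10),
max-EUD (A = 1) 4 GyRBE on the OAR (3), and two External dose fall-offs —
60→0 GyRBE over 1 cm (0.5) and 60→10 GyRBE over 0.5 cm (1), scaled by a
fall-off weight factor (1–4) for conformity sweeps. DVH terms use the
classic "cheapest-to-fix" construction (sort doses, penalize the excess
voxels just beyond the allowed count, normalized by the ROI size); EUD is
the generalized mean (mean d^A)^(1/A); fall-off terms penalize dose above a
reference that ramps from D_high at the CTV surface to D_low over the
fall-off distance (Euclidean distance transform). Robust terms take the
worst value over 9 scenarios (nominal, six 3 mm axial shifts, ±3.5 % SPR) —
a minimax composite per term. Commercial treatment-planning systems keep their exact functional forms
internal; these are declared equivalents.

The solver is a monotone projected-gradient method (Barzilai–Borwein step,
Armijo backtracking), chosen for guaranteed non-increasing objective
history, trivial bound handling and determinism; initialization is uniform
at 2× the minimum spot MU, so runs are reproducible without randomness.
Phase 1 optimizes all spots (nonnegativity); energy layers are then filtered
to the final budget (480 → 240 requested; deduplication usually leaves
fewer) keeping the largest-MU Bragg layers, with ST layers exempt
(structural) and each direction retaining its best Bragg layer; spots below
0.0683 MU are removed; phase 2 re-optimizes survivors with the MU floor as a
hard lower bound, so naive clipping can only be improved on. Iteration caps
default to 200 per phase (250 in the shipped end-to-end checks), relative
step tolerance 10⁻⁶.

Finally the plan is **normalized to coverage**: all weights are scaled by
one global factor so the nominal CTV D95 equals the prescription (factor
typically within 1 % of unity). Without it, converged doses hover just below
the prescription and the prescription-isodose volume becomes a near-empty,
solver-noise-dominated set, making Paddick CI comparisons meaningless;
coverage normalization is the standard clinical convention for comparing
conformity across plans.

## Evaluation and timing

DVH values use raw voxel samples without interpolation: D_v is the
descending-sorted dose at 0-based index floor(v·N/100) — a reproducible
integer convention under which a single cold voxel among twenty sets D95.
Paddick CI = overlap²/(TV·PIV) at the prescription isodose; HI = D95/D5;
the robustness evaluation takes the worst CTV D95 over 28 scenarios — 14
shift directions (6 axial + 8 body diagonals, all normalized to 3 mm) × 2
SPR scales (±3.5 %), the natural 14 × 2 factorization of the
conventional 28-scenario count. The ST fraction is the MU share of ST spots (MU ∝ protons).

Delivery time per fraction sums positioner rotations (trapezoidal profile,
6°/s, 5°/s²; triangular for steps below v²/a = 7.2°; park-to-start counted
as one mean step, 18° on a full 20-direction arc), 0.2 s energy switching
per layer, serpentine raster travel at 600 mm/s, beam-on time from spot
charge over 55 nC/s, and — for collimated layers — leaf travel at 500 mm/s
measured as the symmetric Hausdorff distance between consecutive aperture
contours (the first layer pays travel from a fully open 20 cm field). Spot
ordering and the park convention are package choices; no public
measurements of these delivery parameters exist to validate against.

## Range verification

Each ST spot ray is traced exactly through the nominal and a perturbed
geometry; residual ranges r = R_max − WET give the per-spot statistic
ΔWET/WET = (r_plan − r_measured)/(R_max − r_plan). Spots missing the body
(r_plan = R_max, vanishing denominator) or stopping inside (r < 0) are
flagged and excluded from summaries. Per-angle box-plot summaries use
quartiles with 1.5·IQR whiskers; spot maps cap the display scale at ±15 %.
The detector is ideal (no resolution or noise term); an exact ray tracer
makes the global-SPR oracle exact: scaling SPR by 1.05 yields
ΔWET/WET = 0.05 for every body-crossing spot to floating-point precision.

## What the synthetic conditions do and do not show

The phantom fixes one fully specified study configuration (geometry,
objective weights and margins, 20 directions, 60 GyRBE/30 fractions,
scenario magnitudes); the dose engine is an analytic pencil beam, not a
Monte Carlo engine. Absolute CI/HI/time values from Monte-Carlo-based
clinical systems are therefore not comparable — the package asserts *trends* (ST layers do
not degrade conformity relative to an uncollimated arc; collimation lowers
the External mean dose; removing apertures shortens delivery) and *exact*
verification arithmetic. Known limitations: no nuclear halo or secondaries,
no heterogeneity-induced lateral distortions beyond WED-dependent sigma, no
patient anatomy (the H&N-class results are out of scope), ideal range
detector, and an ST fraction (~9 % on the small target at 5 mm) below the
24–31 % reported for comparable Monte-Carlo-planned uncollimated arcs — the analytic kernels and coarse grid under-reward the
sharp ST penumbra relative to the Monte Carlo engine.
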