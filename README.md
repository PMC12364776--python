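# arcst — upright proton arcs with shoot-through layers

`arcst` is a desk-scale research toolkit for studying **static proton arc
therapy in upright position with added shoot-through (ST) layers**, aimed at
medical-physics researchers exploring compact delivery systems. Compact
upright systems select the beam energy close to the patient, which broadens
the spot penumbra at low energies. Adding one layer of maximum-energy
(230 MeV) *shoot-through* protons per arc direction exploits the sharp
high-energy penumbra: the optimizer places ST spots at the target edge, the
protons traverse the patient and exit with a measurable residual range — so
the same spots that sharpen the dose gradient also enable near-instantaneous
in-vivo range verification with a fixed detector behind the patient.

The package covers the full chain on a fully specified virtual phantom:

- **phantom** — ellipsoidal water body (20 × 17 × 20 cm) with air and bone
  cylinders, an OAR ellipsoid, and three targets (3 cm cube and two H-shaped
  targets), rasterized to a stopping-power-ratio (SPR) voxel grid, plus
  SPR/setup/anatomy perturbations;
- **beam** — 5–230 MeV machine model: Bragg–Kleeman range–energy law
  `R = αE^p` (α = 0.0022, p = 1.77), range straggling, energy-dependent
  in-air spot size, analytic Bragg curves, MU ↔ proton ↔ charge conversion
  (0.0683 MU ≙ 5.63·10⁶ protons);
- **plans** — arc/IMPT plan skeletons: 20 uniformly spaced directions,
  energy-layer selection from the target's WET interval, rectangular spot
  lattices with margins proportional to the spot size, per-layer apertures
  (layer-by-layer collimation), and one ST layer per direction;
- **dose** — exact voxel-walking WET ray tracing and an analytic pencil-beam
  engine producing sparse influence matrices under perturbation scenarios
  (RBE 1.1);
- **optimize** — two-phase spot-weight optimization of the study objective
  set (uniform 60 GyRBE, min/max DVH, max EUD, dose fall-off), optional
  worst-case robust composite, energy-layer filtering (480 → 240) and
  minimum-MU spot filtering;
- **evaluate** — DVH, Paddick CI, homogeneity index D95/D5, EUD, External
  mean dose, ST proton fraction, and the 28-scenario worst-case CTV D95
  (3 mm setup / 3.5 % SPR);
- **timing** — step-and-shoot delivery time (positioner rotation 6°/s,
  5°/s², scanning 600 mm/s, 55 nC/s, 0.2 s energy switch, 500 mm/s leaves);
- **verification** — per-ST-spot relative WET differences
  `ΔWET/WET = (r_plan − r_measured)/(R_max − r_plan)` with per-angle
  box-plot summaries and spot maps.

## The statistic at the core

For each ST spot the residual range in water behind the patient is
`r = R_max − WET`, where `R_max` is the range of the 230 MeV protons
(≈ 33.3 cm) and WET the water-equivalent thickness along the spot ray.
Comparing the planned prediction `r_plan` with a (simulated) measurement
`r_measured` on a perturbed geometry gives the per-spot relative WET error

```
ΔWET/WET = (r_plan − r_measured) / (R_max − r_plan)
```

A global SPR miscalibration by a factor (1 + s) produces ΔWET/WET = s at
every angle; a setup shift produces errors peaking at the beam directions
perpendicular to the shift; a local anatomy change is visible only from the
few directions whose rays cross it.

## Worked example

```python
from arcst import ArcPlanModel, PlanSettings, scale_spr
import numpy as np

model = ArcPlanModel.from_phantom(target="CTV_small", spacing=0.5,
                                  settings=PlanSettings(shoot_through=True))
results = model.fit(maxiter=250)
print(results.summary())
```

prints (5 mm grid, 20 directions, one ST layer each):

```
Plan summary
========================================================
plan type                   Arc+ST
target                      CTV_small
prescription [GyRBE]        60.0 in 30 fx
directions                  20
energy layers (Bragg)       157
energy layers (incl. ST)    177
spots                       7221
ST fraction [%]             9.0
protons (1e9)               140.34
delivery time [s]           197.8
CI (Paddick)                0.954
HI (D95/D5)                 0.993
External Dmean [GyRBE]      3.36
final objective             33.73
```

Here CI is the Paddick conformity index at the 60 GyRBE prescription isodose
(1 = perfect), HI = D95/D5 inside the target (1 = flat), the ST fraction is
the share of irradiated protons delivered by the shoot-through layers, and
the delivery time is per fraction. Range verification against a 5 % SPR
miscalibration then recovers the error at every angle:

```python
records = results.verify_range(scale_spr(model.grid, 1.05))
medians = [r.delta_wet_rel for r in records if r.valid]
print(np.median(medians))   # 0.05
```

A thin CLI wraps the same chain (`arcst make-phantom / plan / optimize /
evaluate / time / verify-range / report`); example YAML configurations for
the study's plan types (Arc, Arc+ST, Arc+Coll, Arc+ST+Coll, 3-beam,
3-beam+ST) ship under `src/arcst/configs/`.

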