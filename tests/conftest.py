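"""Shared fixtures: coarse phantoms, small synthetic grids and the optimized
plan trio used by the end-to-end trend checks (built once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from arcst import (
    ArcPlanModel,
    BeamModel,
    PhantomSpec,
    PlanSettings,
    RoiMask,
    SprGrid,
    build_phantom,
)


@pytest.fixture(scope="session")
def beam() -> BeamModel:
    return BeamModel()


@pytest.fixture(scope="session")
def phantom_coarse():
    """The virtual phantom at 5 mm spacing with the small cubic target."""
    return build_phantom(spacing=0.5, target_choice="CTV_small")


@pytest.fixture(scope="session")
def phantom_6h():
    return build_phantom(spacing=0.5, target_choice="CTV_6H")


@pytest.fixture(scope="session")
def water_slab():
    """A 20 x 20 x 20 cm uniform water block with a central 4 cm cubic
    target; simple enough for hand-computed WET values."""
    spacing = 0.5
    n = 40
    origin = np.array([-10.0, -10.0, -10.0])
    grid = SprGrid(spacing, origin, np.ones((n, n, n)))
    x, y, z = grid.center_mesh()
    target = RoiMask("cube", (np.abs(x) <= 2) & (np.abs(y) <= 2) & (np.abs(z) <= 2))
    return grid, target


@pytest.fixture(scope="session")
def small_fit():
    """A small but real optimization: 8 directions on the 5 mm phantom with a
    modest iteration budget; used by solver-behaviour and determinism tests."""
    model = ArcPlanModel.from_phantom(
        target="CTV_small",
        spacing=0.5,
        settings=PlanSettings(n_directions=8, layers_initial=64, layers_final=40),
    )
    return model.fit(maxiter=60)


@pytest.fixture(scope="session")
def optimized_plans():
    """Arc+ST, Arc and Arc+Coll optimized on the 5 mm phantom under the
    identical objective configuration; the basis of the plan-quality trend
    checks."""
    out = {}
    for label, kwargs in [
        ("Arc+ST", dict(shoot_through=True, collimated=False)),
        ("Arc", dict(shoot_through=False, collimated=False)),
        ("Arc+Coll", dict(shoot_through=False, collimated=True)),
    ]:
        model = ArcPlanModel.from_phantom(
            target="CTV_small", spacing=0.5, settings=PlanSettings(**kwargs)
        )
        out[label] = model.fit(maxiter=250)
    return out
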