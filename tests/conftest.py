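"""Shared fixtures: a desk-scale anatomy for fast unit tests and the
full-size default phantom (built once per session) for recovery experiments."""

from __future__ import annotations

import numpy as np
import pytest

from phantomforge import (
    GM,
    STRIATUM,
    WM,
    PSFModel,
    apply_psf,
    build_activity_map,
    build_compartments,
    generate_anatomy,
)
from phantomforge.fill_planner import FillPlan, compartment_volumes
from phantomforge.synthetic_anatomy import AnatomyParams

#: Table-style target concentrations (kBq/mL) assigned in recovery experiments
TARGETS = {GM: 45.53, WM: 16.01, STRIATUM: 43.76}


def small_anatomy_params(
    seed: int = 0,
    n_islands: int = 2,
    grid: tuple[int, int, int] = (96, 96, 96),
    voxel: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> AnatomyParams:
    """A compact brain that fits a 96³ mm grid: same topology as the default
    anatomy (rind + core + 4 striatal bodies + deep nuclei), smaller radii."""
    bodies = {
        10: ((10.0, 4.0, 3.0), (3.0, 8.0, 4.0)),
        11: ((-10.0, 4.0, 3.0), (3.0, 8.0, 4.0)),
        12: ((17.0, -3.0, 1.0), (4.0, 9.0, 4.5)),
        13: ((-17.0, -3.0, 1.0), (4.0, 9.0, 4.5)),
    }
    nuclei = [
        (22, (6.0, -11.0, -1.0), 3.5),
        (22, (-6.0, -11.0, -1.0), 3.5),
        (23, (5.0, -6.0, -9.0), 2.0),
        (24, (3.0, -9.0, -7.0), 1.5),
    ]
    return AnatomyParams(
        grid_shape=grid,
        voxel_size_mm=voxel,
        brain_radii_mm=(38.0, 33.0, 35.0),
        gm_rind_thickness_mm=6.0,
        striatum_bodies=bodies,
        deep_nuclei_spec=nuclei,
        n_islands=n_islands,
        seed=seed,
    )


def plan_with_concentrations(model, concentrations: dict[int, float]) -> FillPlan:
    """A fill plan that pins scan-time concentrations directly (doses at Δt=0)."""
    volumes = compartment_volumes(model)
    return FillPlan(
        volumes_mL=volumes,
        concentrations_kBq_per_mL=dict(concentrations),
        doses_MBq={c: concentrations[c] * volumes[c] / 1000.0 for c in concentrations},
        ratios_vs_wm=(
            {c: concentrations[c] / concentrations[WM] for c in concentrations}
            if concentrations.get(WM, 0) > 0
            else {}
        ),
    )


@pytest.fixture(scope="session")
def small_model():
    """Coarse 96³ build at 1 mm (no supersampling): fast unit-test phantom."""
    anatomy = generate_anatomy(small_anatomy_params(seed=11))
    return build_compartments(anatomy, print_voxel_mm=1.0)


@pytest.fixture(scope="session")
def standard_model():
    """The default phantom: 160³ source grid at 0.9375×0.9375×1 mm,
    supersampled to 0.75 mm print resolution."""
    anatomy = generate_anatomy(AnatomyParams(seed=7))
    return build_compartments(anatomy)


@pytest.fixture(scope="session")
def standard_plan(standard_model):
    return plan_with_concentrations(standard_model, TARGETS)


@pytest.fixture(scope="session")
def standard_pet(standard_model, standard_plan):
    """Noiseless simulated PET of the default phantom at 6.36 mm FWHM."""
    act = build_activity_map(standard_model, standard_plan)
    return apply_psf(act, PSFModel(6.36))


@pytest.fixture(scope="session")
def standard_recovery(standard_model, standard_plan, standard_pet):
    from phantomforge import evaluate_recovery

    return evaluate_recovery(
        standard_model, standard_plan, PSFModel(6.36), pet=standard_pet
    )
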