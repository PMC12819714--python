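"""Shared fixtures: meshes, fiber fields and (expensive) coupled runs are
built once per session and reused across test modules."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from cardiomefi.config import load_config
from cardiomefi.driver import SimulationConfig, run_systolic_case
from cardiomefi.ep import calibrated_params
from cardiomefi.fibers import generate_fibers
from cardiomefi.geometry import CASES, build_lv_geometry
from cardiomefi.shapes import make_annulus_mesh, make_box_mesh

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*overflow.*")


@pytest.fixture(scope="session")
def case1_mesh():
    return build_lv_geometry(CASES[1], "coarse")


@pytest.fixture(scope="session")
def case1_fibers(case1_mesh):
    return generate_fibers(case1_mesh)


@pytest.fixture(scope="session")
def ep_defaults():
    """EP parameters with the potential mapping calibrated from the
    simulated single-cell action potential."""
    return calibrated_params()


@pytest.fixture(scope="session")
def annulus():
    return make_annulus_mesh(20.0, 27.0, 8.0, nr=6, ntheta=48, nz=3)


@pytest.fixture(scope="session")
def small_box():
    return make_box_mesh((10.0, 10.0, 10.0), (3, 3, 3), {"z0": "base"})


def _short_coupled(k=None, eta3=None, duration=300.0, seed=0):
    overrides = {"case": {"case_id": 1}}
    active = {}
    if k is not None:
        active["k"] = k
    if eta3 is not None:
        active["eta3"] = eta3
    if active:
        overrides["active"] = active
    params = load_config(overrides=overrides)
    cfg = SimulationConfig(case_id=1, resolution="tiny", duration=duration,
                           dt_mech=2.5, seed=seed, params=params)
    return run_systolic_case(cfg)


@pytest.fixture(scope="session")
def coupled_k_sweep():
    """Coupled tiny-mesh runs at increasing active-stress gain k."""
    ks = (4.0, 12.0, 24.0)
    return {k: _short_coupled(k=k) for k in ks}


@pytest.fixture(scope="session")
def coupled_eta3_sweep():
    """Coupled tiny-mesh runs across the sheet-normal weight sweep."""
    vals = (0.3, 0.55, 0.8)
    return {v: _short_coupled(k=12.0, eta3=v) for v in vals}


@pytest.fixture(scope="session")
def coupled_reference(coupled_k_sweep):
    """One representative coupled trace (k = 12)."""
    return coupled_k_sweep[12.0]
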