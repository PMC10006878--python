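"""Shared fixtures.

Drift-diffusion solutions are the expensive objects in this suite, so they
are computed once per session and shared between the semiconductor unit
tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from isfetsim import (
    BiasPoint,
    DeviceGeometry,
    SemiconductorParams,
    SensorAssembly,
    calibrate,
    composition_from_ph_and_chloride,
    make_mesh,
    solve_dd,
)
from isfetsim.semiconductor import extract_vth_dd


@pytest.fixture(scope="session")
def comp100():
    """Sweat-like bath at pH 6 with 100 mol/m^3 chloride."""
    return composition_from_ph_and_chloride(100.0)


@pytest.fixture(scope="session")
def assembly():
    return SensorAssembly()


@pytest.fixture(scope="session")
def calibrated_assembly():
    """Assembly calibrated to the published sensitivity anchor."""
    return calibrate(SensorAssembly(), S_target=1.2e-7)


# ---------------------------------------------------------------------------
# Drift-diffusion session fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def dd_setup():
    sp_ = SemiconductorParams()
    geom = DeviceGeometry()
    return sp_, geom, make_mesh(geom)


@pytest.fixture(scope="session")
def dd_equilibrium(dd_setup):
    sp_, geom, mesh = dd_setup
    return solve_dd(sp_, geom, BiasPoint(0.0, 0.0), 0.0, mesh=mesh)


@pytest.fixture(scope="session")
def dd_linear(dd_setup, dd_equilibrium):
    """V_GS = 1.0 V, V_DS = 50 mV (triode reference point)."""
    sp_, geom, mesh = dd_setup
    return solve_dd(sp_, geom, BiasPoint(1.0, 0.05), 1.0, mesh=mesh, _warm=dd_equilibrium)


@pytest.fixture(scope="session")
def dd_vds_zero(dd_setup, dd_equilibrium):
    """V_GS = 1.0 V, V_DS = 0: inverted channel but no lateral drive."""
    sp_, geom, mesh = dd_setup
    return solve_dd(sp_, geom, BiasPoint(1.0, 0.0), 1.0, mesh=mesh, _warm=dd_equilibrium)


@pytest.fixture(scope="session")
def dd_vth(dd_setup):
    """Extracted DD threshold voltage at V_DS = 50 mV."""
    sp_, geom, mesh = dd_setup
    vgs = np.arange(0.3, 1.21, 0.1)
    return extract_vth_dd(sp_, geom, vgs, v_ds=0.05, mesh=mesh)


@pytest.fixture(scope="session")
def dd_saturation_sweep(dd_setup, dd_equilibrium, dd_vth):
    """Transfer sweep in saturation over a 0.3 V overdrive span."""
    sp_, geom, mesh = dd_setup
    v_gs = dd_vth + np.arange(0.25, 0.56, 0.05)
    ids = []
    warm = dd_equilibrium
    for vg in v_gs:
        st = solve_dd(sp_, geom, BiasPoint(float(vg), 1.44), float(vg), mesh=mesh, _warm=warm)
        warm = st
        ids.append(st.I_drain)
    return v_gs, np.asarray(ids), warm
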