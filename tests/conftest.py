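"""Shared fixtures: calibrated parameters and cached simulation runs.

The expensive runs (0D control ischemia, the scaled-down 1D sensitivity
suite) are session-scoped so every test reuses the same trajectories.
"""

import numpy as np
import pytest

from cardiak import cable, cell, params as par
from cardiak.protocol import RegionalLayout


@pytest.fixture(scope="session")
def cp():
    return par.CellParams.calibrated()


@pytest.fixture(scope="session")
def y_ss():
    return par.steady_state()


@pytest.fixture(scope="session")
def run0d_control():
    """0D control: 5 min normoxia + 21 min progressive ischemia at 1 Hz."""
    sc = cell.Scenario0D(normoxia_min=5.0, ischemia_min=21.0)
    return cell.run_single_cell(sc)


@pytest.fixture(scope="session")
def run0d_suppressed():
    """Alternans-suppression intervention (ICaL gain window), 13 min."""
    sc = cell.Scenario0D(normoxia_min=5.0, ischemia_min=13.5,
                         ical_gain=2.0, ical_on_min=3.5, ical_off_min=12.0)
    return cell.run_single_cell(sc)


def _regional(dv=1.0, dk=1.0):
    # scaled-down sensitivity profile: coarse grid, short ischemia; the
    # coarse-accuracy stepping profile keeps only wavefronts at the fine dt
    sc = cable.Scenario1D(tissue=par.TissueParams(dx_cm=0.1),
                          layout=RegionalLayout(),
                          normoxia_min=1.0, ischemia_min=4.0,
                          dv_factor=dv, dk_factor=dk,
                          probes_cm=(1.0, 2.5, 3.5),
                          snap_every_s=0.1,
                          dvdt_fine_thresh=2.0)
    return cable.run_cable(sc)


@pytest.fixture(scope="session")
def cable_ctrl():
    return _regional()


@pytest.fixture(scope="session")
def cable_dv04():
    return _regional(dv=0.4)


@pytest.fixture(scope="session")
def cable_dk10():
    return _regional(dk=10.0)


@pytest.fixture(scope="session")
def cable_dk0():
    return _regional(dk=0.0)


@pytest.fixture(scope="session")
def cv_refined(y_ss):
    """CV benchmark at halved space and time discretization."""
    sc = cable.Scenario1D(tissue=par.TissueParams(dx_cm=0.0125, dt_ms=0.01),
                          normoxia_min=3000.0 / 60000.0, ischemia_min=0.0,
                          regional=False, probes_cm=(1.0, 1.5),
                          dt_fine_ms=0.01)
    return cable.run_cable(sc, y0=y_ss)


@pytest.fixture(scope="session")
def cv_normoxic(y_ss):
    """Short normoxic cable run at the reference numerics (for CV)."""
    sc = cable.Scenario1D(normoxia_min=3000.0 / 60000.0, ischemia_min=0.0,
                          regional=False, probes_cm=(1.0, 1.5))
    return cable.run_cable(sc, y0=y_ss)
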