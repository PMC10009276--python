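"""Cell-model properties: bookkeeping, gating bounds, integrator accuracy."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cardiak import _kernel as K
from cardiak import analysis, cell, params as par

NORMOXIC_MET = np.tile(np.array([[10.0, 15.0, 7.2, 7.4, 2.0]]), (4, 1))
GATE_IDX = list(range(9, 35))   # all [0, 1]-bounded gates


def _run(y, ms, cp, amp=None, tau=math.inf, clamp_ko=False, met=NORMOXIC_MET,
         nf=50, nc=4, t_occ=math.inf, alpha=None):
    rec = np.zeros((int(ms) + 1, K.NREC_CH))
    a = cp.alpha_internal if alpha is None else alpha
    stim = 2.0 * cp.stim_threshold if amp is None else amp
    fail = K.run_0d(y, rec, 0.0, 1000.0, stim, 0.5, 10.0, met, 1e9,
                    1.0, 0.0, 0.0, a, 0.0, 1.8e6, t_occ,
                    tau, tau, cp.p, nf, nc, clamp_ko)
    assert fail == -1
    return rec


def test_zero_conductance_cell_is_a_capacitor(cp, y_ss):
    """With every conductance zeroed, dVm/dt = Istm/Cm and d[K+]o/dt is the
    wash-out term alone."""
    p0 = cp.replace()
    for idx in range(13 + 1):       # all conductances/permeabilities
        p0.p[idx] = 0.0
    y = y_ss.copy()
    y[38] = 7.0
    cur = np.zeros(K.NCUR)
    acc = np.zeros(8)
    dt = 0.01
    v0, ko0 = y[0], y[38]
    dvdt = K.step_cell(y, dt, 3.0, 10.0, 15.0, 7.2, 7.4, 2.0, 1.0,
                       cp.alpha_internal, 15000.0, p0.p, cur, acc, True)
    assert dvdt == pytest.approx(3.0)              # Cm = 1
    assert y[0] - v0 == pytest.approx(3.0 * dt)
    expected_dko = (5.4 - ko0) / 15000.0 * dt
    assert y[38] - ko0 == pytest.approx(expected_dko, rel=1e-9)


def test_gating_variables_stay_bounded(cp, y_ss):
    """All gates remain in [0, 1] through normoxia and deep ischemia."""
    y = y_ss.copy()
    met = np.tile(np.array([[3.0, 90.0, 6.5, 6.7, 15.0]]), (4, 1))
    _run(y, 5000, cp, met=met, t_occ=0.0)
    g = y[GATE_IDX]
    assert np.all(g >= -1e-12) and np.all(g <= 1.0 + 1e-12)


def test_ko_bookkeeping_matches_current_integrals(cp, y_ss):
    """Without wash-out, the change in [K+]o equals the prefactor times the
    integral of the summed K+ currents (exact for the solver's own steps)."""
    y = y_ss.copy()
    rec = _run(y, 8000, cp, tau=math.inf)
    cums = rec[-1, K.REC_CUM0:K.REC_CUM0 + 8] - rec[0, K.REC_CUM0:K.REC_CUM0 + 8]
    names = list(K.CUM_NAMES)
    total = sum(cums[i] if n != "INaK" else -2.0 * cums[i]
                for i, n in enumerate(names))
    dko = rec[-1, K.REC_KO] - rec[0, K.REC_KO]
    assert dko == pytest.approx(cp.alpha_internal * total, rel=1e-6, abs=1e-9)


def test_washout_closed_form(cp, y_ss):
    """With all membrane currents disabled, Ko relaxes to the bulk value as
    exp(-t / 15 s)."""
    p0 = cp.replace()
    for idx in range(13 + 1):
        p0.p[idx] = 0.0
    y = y_ss.copy()
    y[38] = 9.0
    rec = np.zeros((10001, K.NREC_CH))
    fail = K.run_0d(y, rec, 0.0, 0.0, 0.0, 0.5, 10.0, NORMOXIC_MET, 1e9,
                    1.0, 0.0, 0.0, cp.alpha_internal, 0.0, 1.8e6, math.inf,
                    15000.0, 15000.0, p0.p, 50, 4, False)
    assert fail == -1
    t = rec[:, K.REC_T]
    expected = 5.4 + (9.0 - 5.4) * np.exp(-t / 15000.0)
    rel = np.abs(rec[:, K.REC_KO] - expected) / expected
    assert rel.max() < 1e-3


def test_rush_larsen_matches_stiff_reference_integration(cp, y_ss):
    """One paced beat integrated by the Rush-Larsen scheme agrees with an
    independent stiff integration (LSODA) of the same right-hand side within
    1 mV RMS and 2 ms APD90."""
    amp = 2.0 * cp.stim_threshold

    def rhs(t, y):
        yy = y.copy()
        cur = np.zeros(K.NCUR)
        acc = np.zeros(8)
        h = 1e-7
        istm = amp if 0.0 <= t < 0.5 else 0.0
        K.step_cell(yy, h, istm, 10.0, 15.0, 7.2, 7.4, 2.0, 1.0,
                    cp.alpha_internal, 15000.0, cp.p, cur, acc, True)
        return (yy - y) / h

    t_eval = np.arange(0.0, 500.0, 1.0)
    sol = solve_ivp(rhs, (0.0, 500.0), y_ss, method="LSODA", rtol=1e-6,
                    atol=1e-8, t_eval=t_eval, max_step=0.5)
    assert sol.success
    v_ref = sol.y[0]

    y = y_ss.copy()
    rec = _run(y, 500, cp, amp=amp, tau=15000.0)
    # the kernel's first stimulus is at t = 10 ms; align by shifting
    v_rl = np.interp(t_eval + 10.0, rec[:, K.REC_T], rec[:, K.REC_V])
    rms = np.sqrt(np.mean((v_rl - v_ref) ** 2))
    assert rms < 1.0

    def apd(t, v):
        pk = v.max()
        base = v[0]
        v90 = pk - 0.9 * (pk - base)
        above = np.where(v > v90)[0]
        return t[above[-1]] - t[above[0]]

    assert abs(apd(t_eval, v_rl) - apd(t_eval, v_ref)) < 2.0


def test_normoxic_biomarkers_in_published_range(cp, y_ss):
    """Steady normoxic AP biomarkers fall in the published human-endocardial
    range: APD90, resting potential, peak overshoot, stable [K+]o near 5.4."""
    y = y_ss.copy()
    rec = _run(y, 3000, cp, tau=15000.0)
    bm = analysis.apd90(rec[:, K.REC_T], rec[:, K.REC_V], 1010.0, 1000.0)
    apd, peak, dvdt, cap = bm
    assert cap
    assert 240.0 < apd < 310.0
    assert 25.0 < peak < 50.0
    assert -92.0 < rec[0, K.REC_V] < -84.0
    assert abs(rec[:, K.REC_KO] - 5.4).max() < 0.1


def test_halving_step_convergence(cp, y_ss):
    """Halving both integrator steps changes APD90 by less than 0.5 ms."""
    def one(nf, nc):
        y = y_ss.copy()
        rec = _run(y, 2000, cp, tau=15000.0, nf=nf, nc=nc)
        return analysis.apd90(rec[:, K.REC_T], rec[:, K.REC_V], 1010.0, 1000.0)[0]

    assert abs(one(50, 4) - one(100, 8)) < 0.5


def test_pump_flux_is_an_influx_throughout(run0d_control):
    """The NaK-pump K+ flux rate stays negative (an influx) at every sampled
    instant of the control ischemia run."""
    run = run0d_control
    cum = run.cum_integral("INaK")
    # windowed average every 10 s
    w = 10000
    avg = np.diff(cum[::w]) / w
    assert np.all(-2.0 * avg < 0.0)


def test_quiescent_ischemic_cell_ko_dips_then_rises():
    """Unpaced ischemic cell: [K+]o transiently dips below the normoxic
    value before rising."""
    sc = cell.Scenario0D(normoxia_min=1.0, ischemia_min=10.0, bpm=0.0)
    run = cell.run_single_cell(sc)
    tocc = int(run.t_occ_ms)
    ko = run.ko
    assert ko[tocc:].min() < 5.2
    assert ko[-1] > ko[tocc:].min() + 0.5      # recovery under way


def test_run_single_cell_is_deterministic():
    sc = cell.Scenario0D(normoxia_min=0.2, ischemia_min=0.3)
    r1 = cell.run_single_cell(sc)
    r2 = cell.run_single_cell(sc)
    assert np.array_equal(r1.rec, r2.rec)


def test_integration_failure_reports_time(cp, y_ss):
    """A poisoned state must abort with the last valid time, not NaNs."""
    y = y_ss.copy()
    y[0] = np.inf
    with pytest.raises(RuntimeError, match="failed at t ="):
        cell.run_single_cell(cell.Scenario0D(normoxia_min=0.05,
                                             ischemia_min=0.0), cp, y0=y)
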