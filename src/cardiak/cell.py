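"""Single-cell ("0D") simulation driver.

A scenario is 5 min of normoxia followed by up to 30 min of progressive
ischemia: the metabolite drivers follow their prescribed time courses, the
wash-out term is switched off at occlusion (no-flow), and the cleft [K+]o
evolves under the membrane potassium currents.  Traces are recorded every
1 ms together with running time-integrals of the seven K+ channel currents
and the NaK pump, so flux rates over any window are exact quadratures of the
solver's own steps.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import _kernel as K
from . import params as par
from .protocol import MetaboliteTimeCourse, PacingProtocol, build_met_array


@dataclasses.dataclass
class Scenario0D:
    """Configuration of a single-cell run."""

    normoxia_min: float = 5.0
    ischemia_min: float = 30.0
    bpm: float = 60.0
    adp_variant: str = "default"
    # alternans-suppression intervention: ICaL gain over a window
    # (minutes relative to occlusion); gain 1 = off
    ical_gain: float = 1.0
    ical_on_min: float = 0.0
    ical_off_min: float = 0.0
    # prescribed extracellular-volume shrinkage reaching `shrink_total`
    # (fraction) 30 min after occlusion; 0 = off
    shrink_total: float = 0.0
    stim_amp: float | None = None    # uA/uF; default 2x diastolic threshold
    pulse_ms: float = 0.5
    clamp_ko: bool = False
    ischemic_washout: bool = False   # keep wash-out on after occlusion
    dt_fine_ms: float = 0.02
    dt_coarse_ms: float = 0.25
    seed: int | None = None          # reserved; the model is deterministic

    @property
    def duration_ms(self) -> float:
        return (self.normoxia_min + self.ischemia_min) * 60000.0

    @property
    def t_occ_ms(self) -> float:
        return self.normoxia_min * 60000.0

    @property
    def bcl_ms(self) -> float:
        return math.inf if self.bpm <= 0 else 60000.0 / self.bpm


@dataclasses.dataclass
class CellRun:
    """Result bundle of a 0D run."""

    scenario: Scenario0D
    cp: par.CellParams
    rec: np.ndarray          # (nframes, NREC_CH), 1-ms cadence
    t_occ_ms: float
    stim_amp: float

    @property
    def t_ms(self) -> np.ndarray:
        return self.rec[:, K.REC_T]

    @property
    def vm(self) -> np.ndarray:
        return self.rec[:, K.REC_V]

    @property
    def ko(self) -> np.ndarray:
        return self.rec[:, K.REC_KO]

    @property
    def nai(self) -> np.ndarray:
        return self.rec[:, K.REC_NAI]

    def cum_integral(self, current: str) -> np.ndarray:
        """Running integral of a K+ current (uA/uF * ms) at 1-ms cadence."""
        k = K.CUM_NAMES.index(current)
        return self.rec[:, K.REC_CUM0 + k]

    def current(self, current: str) -> np.ndarray:
        k = K.CUM_NAMES.index(current)
        return self.rec[:, K.REC_I0 + k]

    def stim_times(self) -> np.ndarray:
        """Stimulus onset times (ms) within the recorded span."""
        sc = self.scenario
        if sc.bpm <= 0:
            return np.array([])
        t_first = 10.0
        n = int((self.t_ms[-1] - t_first) // sc.bcl_ms) + 1
        return t_first + sc.bcl_ms * np.arange(n)

    def macro_ko(self) -> pd.DataFrame:
        """[K+]o sampled at 1-s intervals (the "macro" series)."""
        idx = np.arange(0, len(self.t_ms), 1000)
        return pd.DataFrame({"t_s": self.t_ms[idx] / 1000.0, "ko": self.ko[idx]})

    def to_frame(self, every_ms: int = 1) -> pd.DataFrame:
        """Columnar trace export (used by the CSV writer)."""
        idx = np.arange(0, self.rec.shape[0], every_ms)
        cols = {"t_ms": self.t_ms[idx], "vm": self.vm[idx], "ko": self.ko[idx],
                "nai": self.nai[idx], "cai": self.rec[idx, K.REC_CAI]}
        for name in K.CUM_NAMES:
            cols["i_" + name.lower()] = self.current(name)[idx]
        cols["i_ical"] = self.rec[idx, K.REC_ICAL]
        cols["i_ina"] = self.rec[idx, K.REC_INA]
        cols["i_inal"] = self.rec[idx, K.REC_INAL]
        cols["i_inaca"] = self.rec[idx, K.REC_INACA]
        return pd.DataFrame(cols)


def _resolve_amp(sc: Scenario0D, cp: par.CellParams) -> float:
    if sc.stim_amp is not None:
        return float(sc.stim_amp)
    if not math.isfinite(cp.stim_threshold):
        raise ValueError("no stimulus amplitude given and no calibrated threshold")
    return 2.0 * cp.stim_threshold


def run_single_cell(sc: Scenario0D | None = None,
                    cp: par.CellParams | None = None,
                    y0: np.ndarray | None = None) -> CellRun:
    """Run a 0D scenario and return the recorded traces.

    Deterministic given the configuration; raises RuntimeError with the last
    valid time on numerical failure.
    """
    sc = sc or Scenario0D()
    cp = cp or par.CellParams.calibrated()
    y = (y0 if y0 is not None else par.steady_state()).copy()

    course = MetaboliteTimeCourse(sc.adp_variant)
    met = build_met_array(sc.duration_ms, sc.t_occ_ms, course)
    nframes = int(sc.duration_ms) + 1
    rec = np.zeros((nframes, K.NREC_CH))

    amp = _resolve_amp(sc, cp) if sc.bpm > 0 else 0.0
    bcl = 0.0 if sc.bpm <= 0 else sc.bcl_ms
    tau_pre = cp.tau_wo_s * 1000.0
    tau_post = tau_pre if sc.ischemic_washout else math.inf

    nf = int(round(1.0 / sc.dt_fine_ms))
    nc = int(round(1.0 / sc.dt_coarse_ms))
    fail = K.run_0d(
        y, rec, 0.0, bcl, amp, sc.pulse_ms, 10.0,
        met, 100.0,
        sc.ical_gain,
        sc.t_occ_ms + sc.ical_on_min * 60000.0,
        sc.t_occ_ms + sc.ical_off_min * 60000.0,
        cp.alpha_internal, sc.shrink_total, 30.0 * 60000.0, sc.t_occ_ms,
        tau_pre, tau_post,
        cp.p, nf, nc, sc.clamp_ko,
    )
    if fail >= 0:
        raise RuntimeError(
            f"integration failed at t = {fail} ms (last valid state recorded)")
    return CellRun(scenario=sc, cp=cp, rec=rec, t_occ_ms=sc.t_occ_ms,
                   stim_amp=amp)


def prepace(y: np.ndarray, cp: par.CellParams, n_beats: int = 1000,
            bcl_ms: float = 1000.0, amp: float | None = None,
            dt_fine_ms: float = 0.02, dt_coarse_ms: float = 0.25) -> np.ndarray:
    """Pace the normoxic cell to its limit cycle; returns the final state."""
    y = y.copy()
    amp = _resolve_amp(Scenario0D(stim_amp=amp), cp) if amp is None else amp
    met = np.tile(np.array([[K.ATP_NORM, K.ADP_NORM, K.PHI_NORM,
                             K.PHO_NORM, K.LPC_NORM]]), (4, 1))
    chunk = 10  # beats per kernel call
    rec = np.zeros((int(chunk * bcl_ms) + 1, K.NREC_CH))
    nf = int(round(1.0 / dt_fine_ms))
    nc = int(round(1.0 / dt_coarse_ms))
    done = 0
    while done < n_beats:
        nb = min(chunk, n_beats - done)
        r = rec[: int(nb * bcl_ms) + 1]
        fail = K.run_0d(y, r, 0.0, bcl_ms, amp, 0.5, 10.0, met, 1e9,
                        1.0, 0.0, 0.0,
                        cp.alpha_internal, 0.0, 1.8e6, math.inf,
                        cp.tau_wo_s * 1000.0, cp.tau_wo_s * 1000.0,
                        cp.p, nf, nc, False)
        if fail >= 0:
            raise RuntimeError(f"pre-pacing failed at beat {done}, t = {fail} ms")
        done += nb
    return y
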