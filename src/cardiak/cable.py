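"""1D cable electrophysiology with coupled extracellular K+ transport.

Monodomain-style reaction-diffusion for Vm (operator splitting: per-node
reaction update, explicit diffusion with zero-flux ends), two-step recovery
of the extracellular potential Vo from a 1D Poisson problem, injury current
as a post-processing second difference, and the K+ transport PDE (diffusion
+ electromigration + transmembrane source + wash-out) advanced on the same
grid.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.linalg import solve_banded

from . import _kernel as K
from . import params as par
from .protocol import MetaboliteTimeCourse, RegionalLayout, build_met_array

#: intracellular surface-to-volume ratio used to express the injury current
#: (uA/uF * cm^-2-equivalent) in uA/mm^3
SVI_PER_MM = par.SVI_PER_MM


@dataclasses.dataclass
class Scenario1D:
    """Configuration of a cable run."""

    tissue: par.TissueParams = dataclasses.field(default_factory=par.TissueParams)
    layout: RegionalLayout = dataclasses.field(default_factory=RegionalLayout)
    normoxia_min: float = 1.0
    ischemia_min: float = 8.0
    regional: bool = True          # False: fully normoxic cable
    bpm: float = 60.0
    adp_variant: str = "default"
    stim_amp: float | None = None  # uA/uF at the leftmost node(s)
    n_stim_nodes: int | None = None   # default: ~0.25 mm of stimulated tissue
    pulse_ms: float = 0.5
    dv_factor: float = 1.0
    dk_factor: float = 1.0
    probes_cm: tuple = (1.0, 1.5, 2.0, 2.5, 2.9, 3.3, 3.5)
    snap_every_s: float = 1.0
    transport_substeps: int = 5
    dt_fine_ms: float = 0.02
    #: |dVm/dt| above which the fine electrical step is used; at the default
    #: (0.05 mV/ms) any depolarized node also forces fine stepping, so the
    #: whole AP is resolved at dt_fine.  Larger values confine fine stepping
    #: to upstroke/repolarization fronts (coarse-accuracy profile).
    dvdt_fine_thresh: float = 0.05
    seed: int | None = None        # reserved; the solver is deterministic

    @property
    def duration_ms(self) -> float:
        return (self.normoxia_min + self.ischemia_min) * 60000.0

    @property
    def t_occ_ms(self) -> float:
        return self.normoxia_min * 60000.0 if self.regional else math.inf


@dataclasses.dataclass
class CableRun:
    """Result bundle of a 1D run."""

    scenario: Scenario1D
    cp: par.CellParams
    x_cm: np.ndarray
    t_ms: np.ndarray               # frame times (1 ms)
    probes_idx: np.ndarray
    rec_probe: np.ndarray          # (nframes, nprobe, 5): Vm, Ko, Vo, cumIKx, cumTransport
    snap_t_ms: np.ndarray
    snap_v: np.ndarray             # (nsnap, nnode)
    snap_ko: np.ndarray
    act_times: np.ndarray          # (nbeat, nnode) -20 mV upstroke crossings
    stim_amp: float

    def probe_trace(self, x_cm: float, channel: int) -> np.ndarray:
        q = int(np.argmin(np.abs(self.x_cm[self.probes_idx] - x_cm)))
        return self.rec_probe[:, q, channel]

    def ko_profile(self, t_min: float) -> np.ndarray:
        """Ko spatial profile at the snapshot closest to ``t_min`` (sim time)."""
        k = int(np.argmin(np.abs(self.snap_t_ms - t_min * 60000.0)))
        return self.snap_ko[k]

    def vm_profile(self, t_ms: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.snap_t_ms - t_ms)))
        return self.snap_v[k]

    def conduction_velocity(self, x1_cm: float = 1.0, x2_cm: float = 1.5,
                            beat: int = -1) -> float:
        """CV (cm/s) from activation times at two sites, last full beat by default."""
        i1 = int(np.argmin(np.abs(self.x_cm - x1_cm)))
        i2 = int(np.argmin(np.abs(self.x_cm - x2_cm)))
        beats = np.arange(self.act_times.shape[0])
        ok = [b for b in beats
              if np.isfinite(self.act_times[b, i1])
              and np.isfinite(self.act_times[b, i2])]
        if not ok:
            raise ValueError("no captured beat at both sites to measure CV on")
        b = ok[beat]
        dt_ms = self.act_times[b, i2] - self.act_times[b, i1]
        return (self.x_cm[i2] - self.x_cm[i1]) / dt_ms * 1000.0


def run_cable(sc: Scenario1D | None = None,
              cp: par.CellParams | None = None,
              y0: np.ndarray | None = None) -> CableRun:
    """Run a 1D scenario; all nodes start from the normoxic steady state."""
    sc = sc or Scenario1D()
    cp = cp or par.CellParams.calibrated()
    tp = sc.tissue
    n = tp.n_nodes
    x = tp.x_cm

    ys = (y0 if y0 is not None else par.steady_state()).copy()
    Y = np.tile(ys, (n, 1))

    course = MetaboliteTimeCourse(sc.adp_variant)
    met = build_met_array(sc.duration_ms, min(sc.t_occ_ms, sc.duration_ms * 2),
                          course)
    if sc.regional:
        wstep = sc.layout.step_weight(x)
        wph = sc.layout.ph_weight(x)
        tau_wo_node = np.where(wstep > 0.5, math.inf, cp.tau_wo_s * 1000.0)
    else:
        wstep = np.zeros(n)
        wph = np.zeros(n)
        tau_wo_node = np.full(n, cp.tau_wo_s * 1000.0)

    nframes = int(sc.duration_ms) + 1
    probes_idx = np.array([int(round(p / tp.dx_cm)) for p in sc.probes_cm
                           if 0 <= p <= tp.length_cm], dtype=np.int64)
    rec_probe = np.zeros((nframes, len(probes_idx), 5))
    snap_every = max(1, int(round(sc.snap_every_s * 1000.0)))
    nsnap = nframes // snap_every + 1
    snap_v = np.zeros((nsnap, n))
    snap_ko = np.zeros((nsnap, n))

    if sc.stim_amp is not None:
        amp = float(sc.stim_amp)
    else:
        cal = par.load_calibration()
        amp = 2.0 * cal["stim_threshold_1d_ua_uf"]
    n_stim = sc.n_stim_nodes
    if n_stim is None:
        n_stim = max(1, int(round(0.025 / tp.dx_cm)))
    bcl = 0.0 if sc.bpm <= 0 else 60000.0 / sc.bpm
    nbeat = 0 if bcl == 0.0 else int(sc.duration_ms // bcl) + 1
    act_times = np.full((max(nbeat, 1), n), np.nan)

    nf = int(round(1.0 / sc.dt_fine_ms))
    fail = K.run_1d(
        Y, tp.dx_cm, tp.dv_cm2_ms * sc.dv_factor, tp.lam,
        rec_probe, probes_idx,
        snap_v, snap_ko, snap_every,
        act_times, -20.0,
        0.0, bcl, amp, sc.pulse_ms, 10.0, n_stim,
        met, 100.0,
        wstep, wph,
        cp.alpha_internal, sc.t_occ_ms, tau_wo_node,
        tp.dk_cm2_ms * sc.dk_factor, sc.transport_substeps,
        cp.p, nf, 4, sc.dvdt_fine_thresh,
    )
    if fail >= 0:
        raise RuntimeError(f"cable integration failed at frame {fail} ms")
    t_ms = np.arange(nframes, dtype=float)
    snap_t = t_ms[::snap_every][:nsnap]
    return CableRun(scenario=sc, cp=cp, x_cm=x, t_ms=t_ms,
                    probes_idx=probes_idx, rec_probe=rec_probe,
                    snap_t_ms=snap_t, snap_v=snap_v[: len(snap_t)],
                    snap_ko=snap_ko[: len(snap_t)], act_times=act_times,
                    stim_amp=amp)


# ---- extracellular potential, injury current, electrograms -------------------

def extracellular_potential(vm: np.ndarray, lam: float, dx_cm: float,
                            gauge: str = "zero-mean") -> np.ndarray:
    """Solve d2Vo/dx2 = -1/(1+lam) d2Vm/dx2 with zero-flux ends.

    The double-Neumann problem fixes Vo only up to a constant; ``gauge``
    selects "zero-mean" (default) or "zero-left".  With zero-flux Vm ends
    the solution coincides with the closed form -Vm/(1+lam) + const.
    """
    vm = np.asarray(vm, float)
    n = vm.size
    if gauge not in ("zero-mean", "zero-left"):
        raise ValueError("gauge must be 'zero-mean' or 'zero-left'")
    rhs = -second_difference(vm) / (1.0 + lam)
    # discrete Neumann Laplacian (ghost-node reflection), singular: pin the
    # nullspace by replacing the last equation with the gauge condition
    ab = np.zeros((3, n))
    ab[0, 1:] = 1.0
    ab[1, :] = -2.0
    ab[2, :-1] = 1.0
    ab[1, 0] = -1.0
    ab[1, n - 1] = -1.0
    b = rhs.copy()
    ab[1, n - 1] = 1.0
    ab[0, n - 1] = 0.0
    ab[2, n - 2] = 0.0
    b[n - 1] = 0.0
    vo = solve_banded((1, 1), ab, b)
    if gauge == "zero-mean":
        vo -= vo.mean()
    else:
        vo -= vo[0]
    return vo


def second_difference(vm: np.ndarray) -> np.ndarray:
    """Zero-flux second-difference stencil (ghost-node reflection at ends)."""
    vm = np.asarray(vm, float)
    out = np.empty_like(vm)
    out[1:-1] = vm[:-2] - 2.0 * vm[1:-1] + vm[2:]
    out[0] = vm[1] - vm[0]
    out[-1] = vm[-2] - vm[-1]
    return out


def injury_current(vm: np.ndarray, dv_cm2_ms: float, dx_cm: float,
                   per_volume: bool = False) -> np.ndarray:
    """Intracellular injury current profile, DV * d2Vm/dx2.

    In solver units the result is uA/uF (times Cm = 1 uF/cm2, i.e. uA/cm2 of
    membrane).  With ``per_volume=True`` it is converted to uA/mm3 of tissue
    through the intracellular surface-to-volume ratio (Svi = 363.6 mm^-1):
    1 uA/cm2 * Svi = 363.6 uA/(100 mm2 * mm) = 3.636 uA/mm3.
    """
    out = dv_cm2_ms / dx_cm**2 * second_difference(vm)
    if per_volume:
        out = out * SVI_PER_MM / 100.0
    return out


def electrogram_at(run: CableRun, x_cm: float,
                   baseline_ms: float = 50.0) -> np.ndarray:
    """Vo(t) at a recording site with per-beat diastolic baseline alignment.

    The baseline of each beat is the mean Vo over the ``baseline_ms`` window
    before its stimulus, subtracted beat-wise (ST-segment convention).
    """
    sites = run.x_cm[run.probes_idx]
    q = int(np.argmin(np.abs(sites - x_cm)))
    if abs(sites[q] - x_cm) > run.scenario.tissue.dx_cm:
        import warnings
        warnings.warn(f"site {x_cm} cm off probe grid; using {sites[q]:.3f} cm")
    vo = run.rec_probe[:, q, 2].copy()
    bcl = 0.0 if run.scenario.bpm <= 0 else 60000.0 / run.scenario.bpm
    if bcl > 0:
        t_first = 10.0
        nb = int((run.t_ms[-1] - t_first) / bcl)
        for b in range(nb + 1):
            ts = t_first + b * bcl
            w0 = max(0, int(ts - baseline_ms))
            w1 = max(w0 + 1, int(ts))
            seg0 = int(ts)
            seg1 = min(len(vo), int(ts + bcl))
            vo[seg0:seg1] -= vo[w0:w1].mean()
    return vo
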