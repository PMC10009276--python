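"""Model parameters, physical constants and the versioned calibration set.

Two bookkeeping conventions coexist deliberately:

* the baseline cell model keeps its own published geometry for the
  intracellular concentration balances (see ``_kernel``);
* the extracellular cleft potassium balance uses a single conversion
  prefactor ``alpha`` = Ac/(F*vo) that turns a membrane current density
  (uA/uF) into a rate of change of [K+]o.  The tabulated cell surface
  (0.0152 mm^2) and cleft volume (13.3 um^3) are dimensionally inconsistent
  anchors, so ``alpha`` is treated as one calibrated constant, fixed by
  requiring the normoxic unidirectional K+ efflux rate at steady 1 Hz pacing
  to equal 34.5 (umol/L)/s.  Both the raw anchors and the derived prefactor
  are stored here.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import math

import numpy as np

from . import _kernel as K

# raw tabulated anchors, kept for reference
AC_MM2 = 0.0152          # cell capacitive surface, mm^2
VO_UM3 = 13.3            # extracellular cleft volume, um^3
SVI_PER_MM = 363.6       # intracellular surface-to-volume ratio, mm^-1
SVE_PER_MM = 127.3       # extracellular surface-to-volume ratio, mm^-1
CM_UF_CM2 = 1.0

_CAL_KEYS = {
    "gna_ms_uf": K.P_GNA,
    "gkatp_ms_uf": K.P_GKATP,
    "kmnak0_mm": K.P_KMNAK0,
    "kadp_um": K.P_KADP,
    "qadp": K.P_QADP,
    "hnak": K.P_HNAK,
    "kmnakmax_mm": K.P_KMNAKMAX,
    "kmratio_ca": K.P_KMRATIO_CA,
    "katp_km_scale": K.P_KATP_KM,
    "katp_h_scale": K.P_KATP_H,
    "s_ical": K.P_SICAL,
    "s_ina": K.P_SINA,
    "s_inal": K.P_SINAL,
    "s_inaca": K.P_SINACA,
    "s_inak": K.P_SINAK,
    "s_lpc_na_per_um": K.P_SLPCNA,
    "g_lpc_nal_per_um": K.P_GLPCNAL,
}


def load_calibration() -> dict:
    ref = importlib.resources.files("cardiak.data").joinpath("calibration.json")
    with ref.open() as fh:
        return json.load(fh)


@dataclasses.dataclass
class CellParams:
    """Cell-level parameters: kernel vector + cleft-K+ bookkeeping.

    ``alpha_um_s`` is the calibrated Ac/(F*vo) prefactor in (umol/L)/s per
    uA/uF; ``tau_wo_s`` the wash-out time constant (s, may be inf);
    ``kb_mm`` the bulk potassium concentration.
    """

    p: np.ndarray
    alpha_um_s: float
    kb_mm: float = 5.4
    tau_wo_s: float = 15.0
    stim_threshold: float = float("nan")  # uA/uF, 0.5-ms diastolic pulse

    @property
    def alpha_internal(self) -> float:
        """Prefactor in (mmol/L)/ms per uA/uF (kernel units)."""
        return self.alpha_um_s * 1.0e-6

    @classmethod
    def calibrated(cls) -> "CellParams":
        cal = load_calibration()
        p = K.default_params()
        for key, idx in _CAL_KEYS.items():
            if key in cal:
                p[idx] = cal[key]
        return cls(p=p, alpha_um_s=cal["alpha_um_s_per_ua_uf"],
                   stim_threshold=cal.get("stim_threshold_ua_uf", float("nan")))

    def replace(self, **kw) -> "CellParams":
        out = dataclasses.replace(self, p=self.p.copy())
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclasses.dataclass(frozen=True)
class TissueParams:
    """Cable and transport parameters (Table-style defaults)."""

    length_cm: float = 4.0
    dx_cm: float = 0.025            # 0.25 mm
    dv_cm2_ms: float = 0.0026       # effective conductivity-diffusion coefficient
    lam: float = 3.647              # extracellular/intracellular conductivity ratio
    dk_cm2_ms: float = 1.5e-8       # K+ diffusion coefficient (cm^2/ms)
    dt_ms: float = 0.02

    def __post_init__(self):
        n = self.length_cm / self.dx_cm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cable length must be an integer number of dx")
        if self.dt_ms * self.dv_cm2_ms / self.dx_cm**2 > 0.5:
            raise ValueError("explicit stability bound violated: reduce dt or DV, "
                             "or increase dx")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length_cm / self.dx_cm)) + 1

    @property
    def x_cm(self) -> np.ndarray:
        return np.linspace(0.0, self.length_cm, self.n_nodes)


def default_state() -> np.ndarray:
    """Unpaced baseline initial condition (pre-pacing)."""
    y = np.zeros(K.NSTATE)
    y[0] = -87.0
    y[1] = 7.0
    y[2] = 7.0
    y[3] = 145.0
    y[4] = 145.0
    y[5] = 1.0e-4
    y[6] = 1.0e-4
    y[7] = 1.2
    y[8] = 1.2
    y[10] = 1.0
    y[11] = 1.0
    y[13] = 1.0
    y[14] = 1.0
    y[16] = 1.0
    y[17] = 1.0
    y[19] = 1.0
    y[20] = 1.0
    for idx in (22, 23, 24, 25, 26, 28, 29):
        y[idx] = 1.0
    y[34] = 1.0
    y[38] = 5.4
    return y


def steady_state() -> np.ndarray:
    """Normoxic 1 Hz steady state (pre-paced, stored with the calibration)."""
    ref = importlib.resources.files("cardiak.data").joinpath("steady_state.json")
    with ref.open() as fh:
        data = json.load(fh)
    y = np.asarray(data["state"], dtype=float)
    if y.shape != (K.NSTATE,):
        raise ValueError("stored steady state has wrong length")
    return y


def ek_nernst(ko: float, ki: float) -> float:
    """Potassium Nernst potential (mV)."""
    return (1.0 / K.FRT) * math.log(ko / ki)
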