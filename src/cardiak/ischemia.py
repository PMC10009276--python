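"""Ischemia interventions at the cell membrane: K(ATP) current, pump
scaling, acidosis scaling, LPC scaling.

All factors are multiplicative on their target currents and equal 1 at the
normoxic anchors ([ATP]i 10 mmol/L, [ADP]i 15 umol/L, pHi 7.2, pHo 7.4,
[LPC]i 2 umol/L).  The functional forms are parametric saturating/Hill
curves; the parameter values are calibrated against the printed single-cell
outcomes and versioned in ``cardiak/data/calibration.json``.
"""

from __future__ import annotations

import numpy as np

from . import _kernel as K
from . import params as par

PH_RANGE = (5.5, 7.6)


def _params(cp: par.CellParams | None) -> np.ndarray:
    return (cp or par.CellParams.calibrated()).p


def ikatp_current(vm: float, ko: float, atp: float, adp: float,
                  cp: par.CellParams | None = None,
                  ki: float = 145.0) -> float:
    """ATP-sensitive K+ current density (uA/uF), outward positive.

    Zero exactly at the K+ Nernst potential; magnitude grows as [ATP]i falls
    or [ADP]i rises.  ``ki`` sets the Nernst potential when used standalone.
    """
    if ko <= 0.0 or atp <= 0.0:
        raise ValueError("Ko and ATPi must be positive")
    return float(K.ikatp_current(vm, ko, atp, adp, _params(cp), ki))


def f_katp_open(atp: float, adp: float,
                cp: par.CellParams | None = None) -> float:
    """Fraction of open K(ATP) channels at the given metabolic state."""
    if atp <= 0.0:
        raise ValueError("ATPi must be positive")
    p = _params(cp)
    return float(K.f_atp(atp, adp, p[K.P_KATP_KM], p[K.P_KATP_H]))


def pump_scaling(atp: float, adp: float,
                 cp: par.CellParams | None = None) -> tuple:
    """(fNaK, fpCa, fup): ATP/ADP scaling of the NaK pump, the sarcolemmal
    Ca pump and SERCA; each in (0, 1], ~1 at the normoxic anchor and
    non-increasing as [ATP]i falls."""
    if atp <= 0.0:
        raise ValueError("ATPi must be positive")
    return tuple(float(v) for v in K.pump_factors(atp, adp, _params(cp)))


def acidosis_scaling(phi: float, pho: float,
                     cp: par.CellParams | None = None) -> dict:
    """Multiplicative acidosis factors for {ICaL, INa, INaL, INaCa, INaK}.

    All 1 at (pHi, pHo) = (7.2, 7.4); non-increasing as pH falls; floored at
    the configured minimum.  Out-of-physiological-range pH raises.
    """
    for v, name in ((phi, "pHi"), (pho, "pHo")):
        if not PH_RANGE[0] <= v <= PH_RANGE[1]:
            raise ValueError(f"{name}={v} outside physiological range {PH_RANGE}")
    fical, fina, final, fncx, fnak = K.acidosis_factors(phi, pho, _params(cp))
    return {"ICaL": float(fical), "INa": float(fina), "INaL": float(final),
            "INaCa": float(fncx), "INaK": float(fnak)}


def lpc_scaling(lpc: float, cp: par.CellParams | None = None) -> dict:
    """Lysophosphatidylcholine factors for {INa, INaL}.

    1 at the normoxic 2 umol/L; INa is progressively inhibited and the late
    sodium current enhanced as LPC accumulates.
    """
    if lpc < 0.0:
        raise ValueError("LPCi must be non-negative")
    fina, final = K.lpc_factors(lpc, _params(cp))
    return {"INa": float(fina), "INaL": float(final)}
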