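"""Ischemia protocol: metabolite time courses, spatial profiles, pacing.

The five ischemic drivers ([ATP]i, [ADP]i, pHi, pHo, [LPC]i) are prescribed,
not mechanistically modelled.  Their time courses are tabulated control
points (CSV files under ``cardiak/data``) interpolated with a monotone
piecewise-cubic rule; LPC is exactly linear.  In tissue, ATP/ADP/LPC change
stepwise at the metabolic border (x = 2 cm) while pH ramps linearly across a
transition zone of configurable width.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from ._kernel import ADP_NORM, ATP_NORM, LPC_NORM, PHI_NORM, PHO_NORM

ISCHEMIA_SPAN_MIN = 30.0


@dataclasses.dataclass(frozen=True)
class MetabolicState:
    """The five ischemic drivers at one point in space-time."""

    atp: float   # mmol/L
    adp: float   # umol/L
    phi: float   # pH units
    pho: float   # pH units
    lpc: float   # umol/L

    def as_array(self) -> np.ndarray:
        return np.array([self.atp, self.adp, self.phi, self.pho, self.lpc])


NORMOXIC = MetabolicState(ATP_NORM, ADP_NORM, PHI_NORM, PHO_NORM, LPC_NORM)


def _load_table(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("cardiak.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")


class MetaboliteTimeCourse:
    """Interpolated time courses of the five drivers on [0, 30] min.

    Values at t <= 0 are the normoxic anchors; beyond 30 min the curves are
    clamped at their 30-min values.  ``adp_variant="alt"`` selects the
    alternative, slower ADP profile used in the sensitivity runs.
    """

    def __init__(self, adp_variant: str = "default"):
        adp_file = {"default": "adp.csv", "alt": "adp_alt.csv"}[adp_variant]
        self.adp_variant = adp_variant
        self._interp = {}
        for key, fname in (("atp", "atp.csv"), ("adp", adp_file), ("phi", "ph.csv")):
            tab = _load_table(fname)
            self._interp[key] = PchipInterpolator(tab["t_min"], tab["value"])
        lpc = _load_table("lpc.csv")
        self._lpc0 = float(lpc["value"].iloc[0])
        self._lpc1 = float(lpc["value"].iloc[-1])

    def __call__(self, t_min: float) -> MetabolicState:
        return self.at(t_min)

    def at(self, t_min: float) -> MetabolicState:
        """MetabolicState at ``t_min`` minutes since occlusion."""
        if t_min <= 0.0:
            return NORMOXIC
        t = min(float(t_min), ISCHEMIA_SPAN_MIN)
        atp = float(self._interp["atp"](t))
        adp = float(self._interp["adp"](t))
        phi = float(self._interp["phi"](t))
        pho = PHO_NORM + (phi - PHI_NORM)
        lpc = self._lpc0 + (self._lpc1 - self._lpc0) * t / ISCHEMIA_SPAN_MIN
        return MetabolicState(atp, adp, phi, pho, lpc)

    def sample(self, t_min: np.ndarray) -> np.ndarray:
        """(n, 5) array of driver values at the given minute marks."""
        return np.array([self.at(t).as_array() for t in np.asarray(t_min, float)])


def metabolites_at(t_min: float,
                   course: "MetaboliteTimeCourse | None" = None) -> MetabolicState:
    """Driver values ``t_min`` minutes after occlusion (0D time course)."""
    return (course or MetaboliteTimeCourse()).at(t_min)


@dataclasses.dataclass(frozen=True)
class RegionalLayout:
    """Geometry of the regionally ischemic strand.

    The first ``border_cm`` of the cable stay normoxic; the remainder is the
    altered (ischemic) segment.  pH ramps linearly over ``tz_cm`` starting at
    the metabolic border; ATP/ADP/LPC change stepwise at the border.
    """

    length_cm: float = 4.0
    border_cm: float = 2.0
    tz_cm: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.border_cm < self.length_cm:
            raise ValueError("metabolic border must lie inside the cable")
        if self.tz_cm < 0.0 or self.border_cm + self.tz_cm > self.length_cm:
            raise ValueError("pH transition zone must fit inside the altered segment")

    def step_weight(self, x_cm: np.ndarray) -> np.ndarray:
        """0 in the normoxic segment, 1 in the altered segment (ATP/ADP/LPC)."""
        x = np.asarray(x_cm, float)
        self._check(x)
        return (x >= self.border_cm).astype(float)

    def ph_weight(self, x_cm: np.ndarray) -> np.ndarray:
        """0 -> 1 linear ramp across the pH transition zone."""
        x = np.asarray(x_cm, float)
        self._check(x)
        if self.tz_cm == 0.0:
            return (x >= self.border_cm).astype(float)
        w = (x - self.border_cm) / self.tz_cm
        return np.clip(w, 0.0, 1.0) * (x >= self.border_cm)

    def _check(self, x):
        if np.any(x < 0.0) or np.any(x > self.length_cm + 1e-12):
            raise ValueError("position outside the cable")


def metabolites_at_x(x_cm: float, t_min: float,
                     course: MetaboliteTimeCourse | None = None,
                     layout: RegionalLayout | None = None) -> MetabolicState:
    """Driver values at position ``x_cm`` and time ``t_min`` since occlusion."""
    course = course or MetaboliteTimeCourse()
    layout = layout or RegionalLayout()
    ws = float(layout.step_weight(np.array([x_cm]))[0])
    wp = float(layout.ph_weight(np.array([x_cm]))[0])
    isc = course.at(t_min)
    if t_min <= 0.0:
        return NORMOXIC
    atp = ATP_NORM if ws < 0.5 else isc.atp
    adp = ADP_NORM if ws < 0.5 else isc.adp
    lpc = LPC_NORM if ws < 0.5 else isc.lpc
    phi = PHI_NORM + wp * (isc.phi - PHI_NORM)
    pho = PHO_NORM + wp * (isc.pho - PHO_NORM)
    return MetabolicState(atp, adp, phi, pho, lpc)


@dataclasses.dataclass(frozen=True)
class PacingProtocol:
    """Train of rectangular stimulus pulses.

    ``amplitude_factor`` multiplies the normoxic diastolic threshold (the
    protocol amplitude is resolved once the threshold is known).
    """

    bpm: float = 60.0
    pulse_ms: float = 0.5
    amplitude_factor: float = 2.0
    duration_min: float = 35.0
    t_first_ms: float = 10.0

    @property
    def bcl_ms(self) -> float:
        """Basic cycle length in ms (inf when unpaced)."""
        if self.bpm <= 0.0:
            return float("inf")
        return 60000.0 / self.bpm


def stimulus_at(t_ms: float, protocol: PacingProtocol, threshold: float) -> float:
    """Stimulus current density (uA/uF, depolarizing positive) at ``t_ms``."""
    if protocol.bpm <= 0.0 or t_ms < protocol.t_first_ms:
        return 0.0
    ph = (t_ms - protocol.t_first_ms) % protocol.bcl_ms
    if ph < protocol.pulse_ms:
        return protocol.amplitude_factor * threshold
    return 0.0


def build_met_array(duration_ms: float, t_occ_ms: float,
                    course: MetaboliteTimeCourse | None = None,
                    met_dt_ms: float = 100.0) -> np.ndarray:
    """Sampled (n, 5) driver table on a uniform grid for the compiled runners.

    Rows before the occlusion time hold the normoxic anchors.
    """
    course = course or MetaboliteTimeCourse()
    n = int(np.ceil(duration_ms / met_dt_ms)) + 2
    out = np.empty((n, 5))
    for i in range(n):
        t = i * met_dt_ms
        out[i] = course.at((t - t_occ_ms) / 60000.0).as_array()
    return out


def find_diastolic_threshold(run_beat, lo: float = 1.0, hi: float = 200.0,
                             rtol: float = 0.01) -> float:
    """Bisect the minimum 0.5-ms pulse amplitude that elicits an AP.

    ``run_beat(amp) -> bool`` must simulate one stimulated beat from the
    normoxic steady state and report capture.  Raises if [lo, hi] does not
    bracket the threshold.
    """
    if run_beat(lo):
        raise ValueError("lower bound already captures; no bracket")
    if not run_beat(hi):
        raise ValueError("upper bound does not capture; no bracket")
    while (hi - lo) / hi > rtol:
        mid = 0.5 * (lo + hi)
        if run_beat(mid):
            hi = mid
        else:
            lo = mid
    return hi
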