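"""Derived quantities: K+ flux rates, beat metrics, alternans, border zone.

Sign convention: a positive potassium flux rate is an efflux (raises cleft
[K+]o), a negative one an influx.  The NaK pump contributes -2*INaK (two K+
imported per cycle); all other K+ currents contribute with their own sign.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import _kernel as K
from .cell import CellRun

#: currents entering the cleft K+ balance, in report order
KFLUX_CURRENTS = ("IKr", "IKs", "Ito", "IK1", "IKatp", "IKb", "ICaK", "INaK")


@dataclasses.dataclass
class FluxRateReport:
    """Per-current K+ flux rates over one averaging window ((umol/L)/s)."""

    t_start_ms: float
    window_ms: float
    rates: dict          # current name -> signed flux rate
    efflux: float        # sum of positive rates
    influx: float        # sum of negative rates
    net: float           # efflux + influx

    def check_additivity(self, tol: float = 1e-9) -> bool:
        return abs(self.net - sum(self.rates.values())) < tol * max(
            1.0, abs(self.net))


def k_flux_rate(t_ms: np.ndarray, i_trace: np.ndarray, t_start_ms: float,
                bcl_ms: float, alpha_um_s: float, n_beats: int = 4,
                pump: bool = False) -> float:
    """Flux rate of one current over [t, t + n_beats*BCL], (umol/L)/s.

    Trapezoidal quadrature of the current trace scaled by the cleft
    prefactor; ``pump=True`` applies the -2x stoichiometry of INaK.
    """
    t_end = t_start_ms + n_beats * bcl_ms
    if t_start_ms < t_ms[0] - 1e-9 or t_end > t_ms[-1] + 1e-9:
        raise ValueError("trace does not cover the averaging window")
    m = (t_ms >= t_start_ms - 1e-9) & (t_ms <= t_end + 1e-9)
    integ = np.trapezoid(i_trace[m], t_ms[m])
    rate = alpha_um_s * integ / (n_beats * bcl_ms)
    return -2.0 * rate if pump else rate


def flux_report(run: CellRun, t_start_ms: float, n_beats: int = 4,
                bcl_ms: float | None = None) -> FluxRateReport:
    """Flux-rate decomposition from a 0D run's exact current integrals."""
    bcl = bcl_ms if bcl_ms is not None else run.scenario.bcl_ms
    window = n_beats * bcl
    i0 = int(round(t_start_ms))
    i1 = int(round(t_start_ms + window))
    if i0 < 0 or i1 >= run.rec.shape[0]:
        raise ValueError("run does not cover the averaging window")
    dt = run.t_ms[i1] - run.t_ms[i0]
    rates = {}
    for name in KFLUX_CURRENTS:
        cum = run.cum_integral(name)
        avg = (cum[i1] - cum[i0]) / dt
        if name == "INaK":
            avg = -2.0 * avg
        rates[name] = avg * run.cp.alpha_um_s
    efflux = sum(v for v in rates.values() if v > 0)
    influx = sum(v for v in rates.values() if v < 0)
    return FluxRateReport(t_start_ms=t_start_ms, window_ms=window, rates=rates,
                          efflux=efflux, influx=influx, net=efflux + influx)


def decompose_fluxes(run: CellRun,
                     sample_min: tuple = (0.0, 2.5, 5.0, 10.0, 20.0),
                     centered: bool = True) -> list[FluxRateReport]:
    """Flux-rate reports at minute marks after occlusion (4-beat windows)."""
    out = []
    bcl = run.scenario.bcl_ms
    for m in sample_min:
        t_c = run.t_occ_ms + m * 60000.0
        t0 = t_c - 2.0 * bcl if centered else t_c
        out.append(flux_report(run, t0))
    return out


# ---- beat-resolved metrics ----------------------------------------------------

@dataclasses.dataclass
class BeatMetrics:
    """Per-beat AP and cleft-K+ metrics of a paced trace."""

    t_stim_ms: np.ndarray
    captured: np.ndarray      # bool
    apd90_ms: np.ndarray      # NaN for non-captured beats
    peak_vm: np.ndarray
    dvdt_max: np.ndarray
    dmkl: np.ndarray          # diastolic minimum [K+]o per cycle

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_stim_ms": self.t_stim_ms, "captured": self.captured,
            "apd90_ms": self.apd90_ms, "peak_vm": self.peak_vm,
            "dvdt_max": self.dvdt_max, "dmkl": self.dmkl})


def apd90(t_ms: np.ndarray, vm: np.ndarray, t_stim_ms: float, bcl_ms: float,
          diastole_ms: float = 100.0,
          capture_vm: float = -20.0, capture_win_ms: float = 50.0):
    """(apd90, peak, dvdt_max, captured) for the beat stimulated at t_stim.

    APD90 runs from the time of maximum upstroke velocity to 90%
    repolarization relative to the beat's own amplitude (peak minus the
    pre-stimulus diastolic potential).  Non-captured beats (peak Vm below
    ``capture_vm`` within ``capture_win_ms``) return NaN APD.
    """
    i0 = int(np.searchsorted(t_ms, t_stim_ms))
    i1 = int(np.searchsorted(t_ms, min(t_stim_ms + bcl_ms, t_ms[-1])))
    if i1 - i0 < 5:
        raise ValueError("beat window not covered by trace")
    ib = int(np.searchsorted(t_ms, t_stim_ms - diastole_ms))
    v_dia = vm[max(0, ib):i0].mean() if i0 > ib else vm[i0]
    seg = vm[i0:i1]
    ts = t_ms[i0:i1]
    peak = float(seg.max())
    dv = np.diff(seg) / np.diff(ts)
    dvdt_max = float(dv.max()) if len(dv) else np.nan
    iw = int(np.searchsorted(ts, t_stim_ms + capture_win_ms))
    captured = bool(seg[:max(iw, 1)].max() > capture_vm)
    if not captured:
        return np.nan, peak, dvdt_max, False
    iup = int(np.argmax(dv))
    v90 = peak - 0.9 * (peak - v_dia)
    below = np.where(seg[iup:] < v90)[0]
    rep = below[below > np.argmax(seg[iup:])]
    if len(rep) == 0:
        return np.nan, peak, dvdt_max, True
    j = iup + rep[0]
    # linear interpolation of the crossing
    if j > 0 and seg[j - 1] > v90 >= seg[j]:
        frac = (seg[j - 1] - v90) / (seg[j - 1] - seg[j])
        t90 = ts[j - 1] + frac * (ts[j] - ts[j - 1])
    else:
        t90 = ts[j]
    return float(t90 - ts[iup]), peak, dvdt_max, True


def beat_metrics(run: CellRun, diastole_ms: float = 100.0) -> BeatMetrics:
    """Per-beat metrics over a whole 0D run."""
    stim = run.stim_times()
    bcl = run.scenario.bcl_ms
    n = len(stim)
    apd = np.full(n, np.nan)
    cap = np.zeros(n, bool)
    pk = np.full(n, np.nan)
    dvm = np.full(n, np.nan)
    dmk = np.full(n, np.nan)
    t = run.t_ms
    vm = run.vm
    ko = run.ko
    for b, ts in enumerate(stim):
        if ts + bcl > t[-1]:
            break
        apd[b], pk[b], dvm[b], cap[b] = apd90(t, vm, ts, bcl, diastole_ms)
        i0 = int(np.searchsorted(t, ts + bcl - diastole_ms))
        i1 = int(np.searchsorted(t, ts + bcl))
        if i1 > i0:
            dmk[b] = ko[i0:i1].min()
    return BeatMetrics(t_stim_ms=stim, captured=cap, apd90_ms=apd,
                       peak_vm=pk, dvdt_max=dvm, dmkl=dmk)


def dmkl(ko: np.ndarray, t_ms: np.ndarray, stim_times: np.ndarray,
         bcl_ms: float, diastole_ms: float = 100.0) -> np.ndarray:
    """Diastolic minimum [K+]o per beat (minimum over the last
    ``diastole_ms`` of each cycle)."""
    out = np.full(len(stim_times), np.nan)
    for b, ts in enumerate(stim_times):
        i0 = int(np.searchsorted(t_ms, ts + bcl_ms - diastole_ms))
        i1 = int(np.searchsorted(t_ms, ts + bcl_ms))
        if i1 > i0 and i1 <= len(ko):
            out[b] = ko[i0:i1].min()
    return out


@dataclasses.dataclass
class AlternansEpisode:
    onset_beat: int
    offset_beat: int
    pattern: str      # "2:2" or "complex"

    @property
    def n_beats(self) -> int:
        return self.offset_beat - self.onset_beat + 1


def detect_alternans(apd_series: np.ndarray, threshold_ms: float = 5.0,
                     min_beats: int = 8) -> list[AlternansEpisode]:
    """Alternans episodes from a per-beat APD90 series.

    A beat pair alternates when |dAPD90| exceeds ``threshold_ms``; runs of at
    least ``min_beats`` consecutive alternating beats form an episode.
    Non-captured beats (NaN APD) break episodes.  A 2:2 label requires the
    sign of dAPD90 to flip at every step; anything else is "complex".
    """
    apd = np.asarray(apd_series, float)
    d = np.diff(apd)
    alt = np.abs(d) > threshold_ms
    alt &= np.isfinite(d)
    episodes = []
    i = 0
    while i < len(alt):
        if not alt[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(alt) and alt[j + 1]:
            j += 1
        nb = j - i + 2
        if nb >= min_beats:
            signs = np.sign(d[i:j + 1])
            is22 = bool(np.all(signs[1:] * signs[:-1] < 0))
            episodes.append(AlternansEpisode(onset_beat=i, offset_beat=j + 1,
                                             pattern="2:2" if is22 else "complex"))
        i = j + 1
    return episodes


# ---- border-zone metrics ------------------------------------------------------

@dataclasses.dataclass
class BZReport:
    """Spatial metrics of a regional-ischemia [K+]o profile."""

    peak_x_cm: float          # NaN when the profile is flat
    peak_ko: float
    ciz_ko: float             # plateau level in the central ischemic zone
    width_cm: float           # metabolic border -> profile peak
    width_span_cm: float      # alternative: 10%-90% of the CIZ-normoxic span
    invasion_cm: float        # Ko elevation reach into the normoxic segment


def bz_metrics(x_cm: np.ndarray, ko: np.ndarray, border_cm: float = 2.0,
               k_normoxic: float = 5.4, elev_thresh: float = 0.1) -> BZReport:
    """Border-zone metrics of one [K+]o spatial profile.

    The primary width is the distance from the metabolic border to the
    profile peak (parabolically interpolated); the alternative span width
    measures where the profile crosses 10% and 90% of the CIZ-normoxic
    difference.  Invasion depth is how far the elevation (above normoxic +
    ``elev_thresh``) reaches into the normoxic segment.
    """
    x = np.asarray(x_cm, float)
    k = np.asarray(ko, float)
    if k.max() - k.min() < elev_thresh:
        return BZReport(np.nan, float(k.max()), float(k[-1]), 0.0, 0.0, 0.0)
    ip = int(np.argmax(k))
    if 0 < ip < len(k) - 1:
        y0, y1, y2 = k[ip - 1], k[ip], k[ip + 1]
        denom = y0 - 2.0 * y1 + y2
        off = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        xp = x[ip] + off * (x[1] - x[0])
    else:
        xp = x[ip]
    ciz = float(k[int(0.9 * len(k)):].mean())
    lo = k_normoxic + 0.1 * (ciz - k_normoxic)
    hi = k_normoxic + 0.9 * (ciz - k_normoxic)
    x_lo = _first_crossing(x, k, lo)
    x_hi = _first_crossing(x, k, hi)
    span = max(0.0, x_hi - x_lo) if np.isfinite(x_lo) and np.isfinite(x_hi) else np.nan
    elev = np.where(k > k_normoxic + elev_thresh)[0]
    if len(elev) and x[elev[0]] < border_cm:
        invasion = border_cm - x[elev[0]]
    else:
        invasion = 0.0
    return BZReport(peak_x_cm=float(xp), peak_ko=float(k[ip]), ciz_ko=ciz,
                    width_cm=max(0.0, float(xp - border_cm)),
                    width_span_cm=float(span), invasion_cm=float(invasion))


def _first_crossing(x, k, level):
    above = np.where(k >= level)[0]
    if len(above) == 0:
        return np.nan
    i = above[0]
    if i == 0:
        return x[0]
    f = (level - k[i - 1]) / (k[i] - k[i - 1])
    return x[i - 1] + f * (x[i] - x[i - 1])
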