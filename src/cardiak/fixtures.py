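"""Deterministic synthetic fixtures with known analytic answers.

Used by the test suite and available from the CLI; none of these derive
from simulation output.
"""

from __future__ import annotations

import numpy as np


def square_ap(apd_ms: float = 200.0, bcl_ms: float = 1000.0,
              n_beats: int = 4, v_rest: float = -85.0, v_peak: float = 15.0,
              t_stim_ms: float = 10.0, dt_ms: float = 1.0):
    """Square (trapezoidal with 1-sample edges) AP train.

    Returns (t, vm, stim_times); the 90% level is crossed exactly
    ``apd_ms`` after the upstroke.
    """
    n = int(n_beats * bcl_ms / dt_ms) + 1
    t = np.arange(n) * dt_ms
    vm = np.full(n, v_rest)
    stim = t_stim_ms + bcl_ms * np.arange(n_beats)
    for ts in stim:
        on = (t >= ts) & (t < ts + apd_ms)
        vm[on] = v_peak
    return t, vm, stim


def constant_current(i_ua_uf: float = 0.5, duration_ms: float = 4000.0,
                     dt_ms: float = 1.0):
    """Constant current-density trace: (t, i)."""
    t = np.arange(int(duration_ms / dt_ms) + 1) * dt_ms
    return t, np.full(len(t), i_ua_uf)


def quadratic_vm_profile(n_nodes: int = 161, dx_cm: float = 0.025,
                         a: float = 10.0, v0: float = -80.0):
    """Prescribed Vm(x) = v0 + a*x^2: (x, vm).

    The interior second difference of this profile is exactly 2*a*dx^2, so
    the injury current is constant at interior nodes.
    """
    x = np.arange(n_nodes) * dx_cm
    return x, v0 + a * x**2


def zero_flux_vm_profile(n_nodes: int = 161, length_cm: float = 4.0,
                         amp_mv: float = 40.0, v0: float = -60.0):
    """Smooth Vm(x) with zero discrete flux at both ends (cosine mode)."""
    x = np.linspace(0.0, length_cm, n_nodes)
    return x, v0 + amp_mv * np.cos(np.pi * x / length_cm)


def alternating_apd_series(n_beats: int = 30, base_ms: float = 200.0,
                           delta_ms: float = 10.0):
    """APD90 series alternating base +/- delta (perfect 2:2 pattern)."""
    s = np.full(n_beats, base_ms)
    s[1::2] += delta_ms
    s[0::2] -= delta_ms
    return s


def make_fixture(kind: str, **kw):
    """Dispatch by fixture kind (see the individual constructors)."""
    table = {
        "square-ap": square_ap,
        "constant-current": constant_current,
        "quadratic-vm": quadratic_vm_profile,
        "zero-flux-vm": zero_flux_vm_profile,
        "alternating-apd": alternating_apd_series,
    }
    if kind not in table:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {sorted(table)}")
    return table[kind](**kw)
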