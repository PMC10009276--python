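"""Extracellular K+ transport on the cable grid.

The PDE combines Fickian diffusion, electromigration along the
extracellular-potential gradient (Nernst-Planck drift, the F/RT term), the
transmembrane source alpha * sum(IKx), and wash-out toward the bulk blood
concentration; no-flux conditions hold at both cable ends.  The coupled
solver in ``cable`` advances the same discretization inline; this module
exposes the operator for standalone use and testing.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._kernel import FRT


@dataclasses.dataclass(frozen=True)
class TransportParams:
    """Parameters of the K+ transport PDE."""

    dk_cm2_ms: float = 1.5e-8
    kb_mm: float = 5.4
    tau_wo_normoxic_s: float = 15.0
    dx_cm: float = 0.025

    def tau_profile(self, altered: np.ndarray) -> np.ndarray:
        """Per-node wash-out constant (ms): finite in the normoxic segment,
        infinite where ``altered`` is true (no-flow ischemia)."""
        tau = np.full(len(altered), self.tau_wo_normoxic_s * 1000.0)
        tau[np.asarray(altered, bool)] = math.inf
        return tau


def k_flux_interfaces(ko: np.ndarray, vo: np.ndarray, dk: float,
                      dx: float) -> np.ndarray:
    """Total K+ flux (diffusion + electromigration) at cell interfaces.

    Returns n+1 interface fluxes; the two boundary fluxes are zero."""
    ko = np.asarray(ko, float)
    vo = np.asarray(vo, float)
    flux = np.zeros(len(ko) + 1)
    grad = np.diff(ko) / dx
    kom = 0.5 * (ko[1:] + ko[:-1])
    em = FRT * kom * np.diff(vo) / dx
    flux[1:-1] = -dk * (grad + em)
    return flux


def transport_rate(ko: np.ndarray, vo: np.ndarray, dk: float,
                   dx: float) -> np.ndarray:
    """d[K+]o/dt contribution of the transport term (divergence of flux)."""
    flux = k_flux_interfaces(ko, vo, dk, dx)
    return -np.diff(flux) / dx


def step_k_transport(ko: np.ndarray, vo: np.ndarray, sum_ikx: np.ndarray,
                     dt_ms: float, tp: TransportParams,
                     alpha_internal: float,
                     tau_wo_ms: np.ndarray | None = None) -> np.ndarray:
    """One explicit step of the full transport equation.

    ``alpha_internal`` converts current density to (mmol/L)/ms; ``tau_wo_ms``
    is the per-node wash-out constant (defaults to no wash-out).  Raises on a
    negative concentration, which signals a dt/dx misconfiguration.
    """
    ko = np.asarray(ko, float)
    if dt_ms * tp.dk_cm2_ms / tp.dx_cm**2 > 0.5:
        raise ValueError("explicit stability bound violated for DK")
    dko = transport_rate(ko, vo, tp.dk_cm2_ms, tp.dx_cm)
    dko = dko + alpha_internal * np.asarray(sum_ikx, float)
    if tau_wo_ms is not None:
        w = np.isfinite(tau_wo_ms)
        dko = dko + np.where(w, (tp.kb_mm - ko) / np.where(w, tau_wo_ms, 1.0), 0.0)
    out = ko + dt_ms * dko
    if np.any(out <= 0.0):
        raise RuntimeError("negative [K+]o after transport step "
                           "(check dt/dx configuration)")
    return out


def diffusion_flux_rate(run, x_cm: float, t_start_ms: float,
                        window_ms: float = 4000.0) -> float:
    """Time-averaged transport-term contribution to d[K+]o/dt at a site.

    Evaluated from the cable run's accumulated transport integrals at the
    probe nearest ``x_cm``; reported in (umol/L)/s.
    """
    sites = run.x_cm[run.probes_idx]
    q = int(np.argmin(np.abs(sites - x_cm)))
    cum = run.rec_probe[:, q, 4]           # mmol/L accumulated
    i0 = int(round(t_start_ms))
    i1 = int(round(t_start_ms + window_ms))
    if i1 >= len(cum):
        raise ValueError("window beyond run span")
    return (cum[i1] - cum[i0]) / (window_ms / 1000.0) * 1000.0
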