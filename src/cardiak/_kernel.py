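"""Compiled numerical core: ischemia-modified human ventricular cell model and
the 0D / 1D cable integrators.

The baseline electrophysiology is the O'Hara-Rudy (2011) endocardial human
ventricular model.  Two departures from the published baseline:

* the fast sodium current uses the ten Tusscher-Panfilov (2006) m3hj
  formulation (with a calibrated maximum conductance) to obtain realistic
  upstroke velocity and conduction velocity in tissue;
* an ATP-sensitive potassium current (Ferrero et al. 1996 functional form,
  human-adapted conductance) and multiplicative ischemia scaling factors for
  pumps and pH/LPC-sensitive currents are added, together with a dynamic
  extracellular cleft potassium concentration.

State vector layout (length NSTATE):
  0  Vm (mV)
  1  Nai   2 Nass   3 Ki   4 Kss   5 Cai   6 Cass   7 Cansr  8 Cajsr (mmol/L)
  9  m    10 h    11 j                       (fast Na gates, TT06)
  12 mL   13 hL   14 hLp                     (late Na gates)
  15 a    16 iF   17 iS   18 ap  19 iFp  20 iSp   (Ito gates)
  21 d    22 ff   23 fs   24 fcaf 25 fcas 26 jca 27 nca 28 ffp 29 fcafp (ICaL)
  30 xrf  31 xrs  32 xs1  33 xs2  34 xk1
  35 Jrelnp  36 Jrelp  37 CaMKt
  38 Ko (mmol/L, extracellular cleft potassium; dynamic)

Currents record layout (length NCUR), densities in uA/uF:
  0 INa  1 INaL  2 Ito  3 ICaL  4 ICaNa  5 ICaK  6 IKr  7 IKs  8 IK1
  9 IKatp  10 IKb  11 INaK  12 INaCa  13 IpCa  14 ICab  15 INab
  16 Istm  17 sumIKx (= IKr+IKs+Ito+IK1+IKatp+IKb+ICaK-2*INaK)

All voltages mV, time ms, currents uA/uF (Cm = 1 uF/cm2).
"""

import math

import numpy as np
from numba import njit

NSTATE = 39
NCUR = 18

# physical constants (mV-ms-mmol units as in the baseline model)
RGAS = 8314.0
TEMP = 310.0
FARADAY = 96485.0
FRT = FARADAY / (RGAS * TEMP)  # 1/mV

# cell geometry of the baseline model (cm, uL)
_L = 0.01
_RAD = 0.0011
VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

# ---- parameter vector indices -------------------------------------------------
P_GNA = 0       # mS/uF, TT06-style INa
P_GNAL = 1
P_GTO = 2
P_PCA = 3
P_GKR = 4
P_GKS = 5
P_GK1 = 6
P_GNCX = 7
P_PNAK = 8
P_GKB = 9
P_PNAB = 10
P_PCAB = 11
P_GPCA = 12
P_GKATP = 13    # mS/uF, maximum fully-activated conductance at Ko = 5.4
P_KMNAK0 = 14   # mmol/L, pump ATP half-activation at zero ADP
P_KADP = 15     # umol/L, ADP half-saturation of the Km growth
P_QADP = 16     # Hill exponent of the ADP dependence of Km
P_HNAK = 17     # Hill exponent of pump ATP dependence
P_KMNAKMAX = 18  # mmol/L, saturating increment of pump Km at high ADP
P_KMRATIO_CA = 19  # Km ratio of the Ca pumps (IpCa, SERCA) vs the NaK pump
P_SICAL = 20    # acidosis slopes, fraction per pH unit
P_SINA = 21
P_SINAL = 22
P_SINACA = 23
P_SINAK = 24
P_FLOOR = 25    # lower bound of every scaling factor
P_SLPCNA = 26   # INa reduction per umol/L LPC above normoxic
P_GLPCNAL = 27  # INaL enhancement per umol/L LPC above normoxic
P_NAO = 28
P_CAO = 29
P_KB = 30       # bulk (blood) potassium, mmol/L
P_KATP_KM = 31  # scale of the K(ATP) ATP half-saturation (human adaptation)
P_KATP_H = 32   # scale of the K(ATP) Hill exponent (human adaptation)
NPARAM = 33

PHI_NORM = 7.2
PHO_NORM = 7.4
LPC_NORM = 2.0
ATP_NORM = 10.0
ADP_NORM = 15.0


def default_params() -> np.ndarray:
    """Baseline + calibrated parameter vector (endocardial cell)."""
    p = np.zeros(NPARAM)
    p[P_GNA] = 11.0        # calibrated against CV = 70 cm/s (see calibration data)
    p[P_GNAL] = 0.0075
    p[P_GTO] = 0.02
    p[P_PCA] = 0.0001
    p[P_GKR] = 0.046
    p[P_GKS] = 0.0034
    p[P_GK1] = 0.1908
    p[P_GNCX] = 0.0008
    p[P_PNAK] = 30.0
    p[P_GKB] = 0.003
    p[P_PNAB] = 3.75e-10
    p[P_PCAB] = 2.5e-8
    p[P_GPCA] = 0.0005
    p[P_GKATP] = 0.3
    p[P_KMNAK0] = 0.3
    p[P_KADP] = 25.0
    p[P_QADP] = 6.0
    p[P_HNAK] = 2.0
    p[P_KMNAKMAX] = 10.6
    p[P_KMRATIO_CA] = 0.6
    p[P_SICAL] = 0.30
    p[P_SINA] = 0.25
    p[P_SINAL] = 0.25
    p[P_SINACA] = 0.40
    p[P_SINAK] = 0.20
    p[P_FLOOR] = 0.05
    p[P_SLPCNA] = 0.015
    p[P_GLPCNAL] = 0.08
    p[P_NAO] = 140.0
    p[P_CAO] = 1.8
    p[P_KB] = 5.4
    p[P_KATP_KM] = 17.0
    p[P_KATP_H] = 3.2
    return p


# ---- ischemia scaling factors -------------------------------------------------

@njit(cache=True)
def f_atp(atp, adp, km_scale, h_scale):
    """Fraction of open K(ATP) channels.

    Hill function of [ATP]i whose half-saturation Km(ADP) = 35.8 +
    17.9*ADP^0.256 (uM) and exponent H(ADP) = 1.3 + 0.74*exp(-0.09*ADP);
    ``km_scale``/``h_scale`` are the human-adaptation factors applied to Km
    and H.  atp in mmol/L, adp in umol/L."""
    atp_um = 1000.0 * atp
    km = km_scale * (35.8 + 17.9 * adp ** 0.256)
    hh = h_scale * (1.3 + 0.74 * math.exp(-0.09 * adp))
    return 1.0 / (1.0 + (atp_um / km) ** hh)


@njit(cache=True)
def pump_factors(atp, adp, p):
    """(fNaK, fpCa, fup) ATP/ADP-dependent pump scaling factors in (0, 1].

    Each factor is a Hill function of the ATP concentration whose
    half-activation Km rises with free ADP (competitive inhibition) along a
    saturating Hill curve: Km = Km0 + Kmax / (1 + (KADP/ADP)^q).
    """
    km = p[P_KMNAK0] + p[P_KMNAKMAX] / (1.0 + (p[P_KADP] / adp) ** p[P_QADP])
    h = p[P_HNAK]
    fnak = 1.0 / (1.0 + (km / atp) ** h)
    kmca = km * p[P_KMRATIO_CA]
    fpca = 1.0 / (1.0 + (kmca / atp) ** h)
    fup = 1.0 / (1.0 + (kmca / atp) ** h)
    return fnak, fpca, fup


@njit(cache=True)
def acidosis_factors(phi, pho, p):
    """(fICaL, fINa, fINaL, fINaCa, fINaK) multiplicative acidosis factors."""
    di = PHI_NORM - phi
    if di < 0.0:
        di = 0.0
    do = PHO_NORM - pho
    if do < 0.0:
        do = 0.0
    fl = p[P_FLOOR]
    fical = max(fl, 1.0 - p[P_SICAL] * do)
    fina = max(fl, 1.0 - p[P_SINA] * do)
    final = max(fl, 1.0 - p[P_SINAL] * do)
    fncx = max(fl, 1.0 - p[P_SINACA] * di)
    fnak = max(fl, 1.0 - p[P_SINAK] * di)
    return fical, fina, final, fncx, fnak


@njit(cache=True)
def lpc_factors(lpc, p):
    """(fINa, fINaL) lysophosphatidylcholine factors; both 1 at 2 umol/L."""
    dl = lpc - LPC_NORM
    if dl < 0.0:
        dl = 0.0
    fina = max(p[P_FLOOR], 1.0 - p[P_SLPCNA] * dl)
    final = 1.0 + p[P_GLPCNAL] * dl
    return fina, final


@njit(cache=True)
def ikatp_current(v, ko, atp, adp, p, ki=145.0):
    """ATP-sensitive potassium current density (uA/uF), outward positive."""
    ek = (1.0 / FRT) * math.log(ko / ki)
    fo = f_atp(atp, adp, p[P_KATP_KM], p[P_KATP_H])
    return p[P_GKATP] * (ko / 5.4) ** 0.24 * fo * (v - ek)


# ---- single cell step ---------------------------------------------------------

@njit(cache=True, fastmath=True)
def step_cell(y, dt, istm, atp, adp, phi, pho, lpc, icalg,
              alpha, tau_wo, p, cur, acc, update_ko):
    """One Rush-Larsen / Euler step of the full cell model.

    Currents are evaluated at the pre-step state and written to ``cur``;
    ``acc`` accumulates the time integrals of the seven K+ channel currents
    and INaK (uA/uF * ms).  ``alpha`` converts current density to d[K+]o/dt
    ((mmol/L)/ms per uA/uF); ``tau_wo`` is the wash-out constant (ms, may be
    inf).  ``update_ko``: if False the 0D Ko equation is skipped entirely
    (used when Ko is clamped).  Returns dVm/dt at the pre-step state.
    """
    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    ko = y[38]

    nao = p[P_NAO]
    cao = p[P_CAO]

    # ischemia factors
    fnak_p, fpca_p, fup_p = pump_factors(atp, adp, p)
    fical_a, fina_a, final_a, fncx_a, fnak_a = acidosis_factors(phi, pho, p)
    fina_l, final_l = lpc_factors(lpc, p)
    fkatp = f_atp(atp, adp, p[P_KATP_KM], p[P_KATP_H])

    ena = (1.0 / FRT) * math.log(nao / nai)
    ek = (1.0 / FRT) * math.log(ko / ki)
    eks = (1.0 / FRT) * math.log((ko + 0.01833 * nao) / (ki + 0.01833 * nai))

    vfrt = v * FRT
    vffrt = v * FARADAY * FRT

    # CaMK
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKt = y[37]
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt

    # ---------------- INa (TT06 formulation) ----------------
    m = y[9]
    h = y[10]
    jg = y[11]
    ina = p[P_GNA] * m * m * m * h * jg * (v - ena) * fina_a * fina_l

    minf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    taum = am * bm
    hinf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    tauh = 1.0 / (ah + bh)
    jinf = hinf
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    tauj = 1.0 / (aj + bj)

    # ---------------- INaL ----------------
    mL = y[12]
    hL = y[13]
    hLp = y[14]
    fINaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    inal = (p[P_GNAL] * (v - ena) * mL * ((1.0 - fINaLp) * hL + fINaLp * hLp)
            * final_a * final_l)

    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tmL = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955))
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL

    # ---------------- Ito ----------------
    a = y[15]
    iF = y[16]
    iS = y[17]
    ap = y[18]
    iFp = y[19]
    iSp = y[20]
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_g = AiF * iF + AiS * iS
    ip = AiF * iFp + AiS * iSp
    fItop = 1.0 / (1.0 + KmCaMK / CaMKa)
    ito = p[P_GTO] * (v - ek) * ((1.0 - fItop) * a * i_g + fItop * ap * ip)

    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS

    # ---------------- ICaL / ICaNa / ICaK ----------------
    d = y[21]
    ff = y[22]
    fs = y[23]
    fcaf = y[24]
    fcas = y[25]
    jca = y[26]
    nca = y[27]
    ffp = y[28]
    fcafp = y[29]

    Aff = 0.6
    Afs = 0.4
    f = Aff * ff + Afs * fs
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * fcaf + Afcas * fcas
    fp = Aff * ffp + Afs * fs
    fcap = Afcaf * fcafp + Afcas * fcas

    vx = v
    if -1.0e-4 < vx < 1.0e-4:
        vx = 1.0e-4
    vfrtx = vx * FRT
    vffrtx = vx * FARADAY * FRT
    ev1 = math.exp(vfrtx)
    ev2 = ev1 * ev1
    PhiCaL = 4.0 * vffrtx * (cass * ev2 - 0.341 * cao) / (ev2 - 1.0)
    PhiCaNa = vffrtx * (0.75 * nass * ev1 - 0.75 * nao) / (ev1 - 1.0)
    PhiCaK = vffrtx * (0.75 * kss * ev1 - 0.75 * ko) / (ev1 - 1.0)

    PCa = p[P_PCA]
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    fICaLp = 1.0 / (1.0 + KmCaMK / CaMKa)

    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
    ical = (((1.0 - fICaLp) * PCa * gate_np + fICaLp * PCap * gate_p)
            * PhiCaL * fical_a * icalg)
    icana = (((1.0 - fICaLp) * PCaNa * gate_np + fICaLp * PCaNap * gate_p)
             * PhiCaNa * fical_a * icalg)
    icak = (((1.0 - fICaLp) * PCaK * gate_np + fICaLp * PCaKp * gate_p)
            * PhiCaK * fical_a * icalg)

    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (3.5e-5 * math.exp(-(v + 5.0) / 4.0)
                          + 3.5e-5 * math.exp((v + 5.0) / 6.0))
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0))
    tjca = 75.0
    tffp = 2.5 * tff
    tfcafp = 2.5 * tfcaf
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)

    # ---------------- IKr ----------------
    xrf = y[30]
    xrs = y[31]
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = 1.0 / ((1.0 + math.exp((v + 55.0) / 75.0)) * (1.0 + math.exp((v - 10.0) / 30.0)))
    ikr = p[P_GKR] * math.sqrt(ko / 5.4) * xr * rkr * (v - ek)

    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))

    # ---------------- IKs ----------------
    xs1 = y[32]
    xs2 = y[33]
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    iks = p[P_GKS] * KsCa * xs1 * xs2 * (v - eks)
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))

    # ---------------- IK1 ----------------
    xk1 = y[34]
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59) / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    ik1 = p[P_GK1] * math.sqrt(ko) * rk1 * xk1 * (v - ek)

    # ---------------- IK(ATP) ----------------
    ikatp = p[P_GKATP] * (ko / 5.4) ** 0.24 * fkatp * (v - ek)

    # ---------------- INaCa (i and ss) ----------------
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    gncx = p[P_GNCX] * fncx_a
    KmCaAct = 150.0e-6

    # i compartment
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p_ = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p_ + k3pp
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    E1 = x1 / s
    E2 = x2 / s
    E3 = x3 / s
    E4 = x4 / s
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    inaca_i = 0.8 * gncx * allo * (JncxNa + 2.0 * JncxCa)

    # ss compartment
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k6 = h6 * cass * kcaon
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    E1 = x1 / s
    E2 = x2 / s
    E3 = x3 / s
    E4 = x4 / s
    allo_ss = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    inaca_ss = 0.2 * gncx * allo_ss * (JncxNa + 2.0 * JncxCa)
    inaca = inaca_i + inaca_ss

    # ---------------- INaK ----------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * math.exp(delta * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    Hp = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    Pph = eP / (1.0 + Hp / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3) / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0)
    a3 = (k3p * (ko / Kko) ** 2) / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0)
    b3 = (k3m * Pph * Hp) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    s = x1 + x2 + x3 + x4
    E1 = x1 / s
    E2 = x2 / s
    E3 = x3 / s
    E4 = x4 / s
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    inak = p[P_PNAK] * (JnakNa + JnakK) * fnak_p * fnak_a

    # ---------------- minor currents ----------------
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    ikb = p[P_GKB] * xkb * (v - ek)
    inab = p[P_PNAB] * vffrtx * (nai * ev1 - nao) / (ev1 - 1.0)
    icab = p[P_PCAB] * 4.0 * vffrtx * (cai * ev2 - 0.341 * cao) / (ev2 - 1.0)
    ipca = p[P_GPCA] * cai / (0.0005 + cai) * fpca_p

    # ---------------- fluxes ----------------
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ical) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ical) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    fJrelp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jrel = (1.0 - fJrelp) * y[35] + fJrelp * y[36]

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    fJupp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = ((1.0 - fJupp) * Jupnp + fJupp * Jupp) * fup_p - Jleak
    Jtr = (cansr - cajsr) / 100.0

    sum_ikx = ikr + iks + ito + ik1 + ikatp + ikb + icak - 2.0 * inak

    cur[0] = ina
    cur[1] = inal
    cur[2] = ito
    cur[3] = ical
    cur[4] = icana
    cur[5] = icak
    cur[6] = ikr
    cur[7] = iks
    cur[8] = ik1
    cur[9] = ikatp
    cur[10] = ikb
    cur[11] = inak
    cur[12] = inaca
    cur[13] = ipca
    cur[14] = icab
    cur[15] = inab
    cur[16] = istm
    cur[17] = sum_ikx

    acc[0] += ikr * dt
    acc[1] += iks * dt
    acc[2] += ito * dt
    acc[3] += ik1 * dt
    acc[4] += ikatp * dt
    acc[5] += ikb * dt
    acc[6] += icak * dt
    acc[7] += inak * dt

    iion = (ina + inal + ito + ical + icana + icak + ikr + iks + ik1 + ikatp
            + ikb + inak + inaca + ipca + icab + inab)
    dvdt = -iion + istm

    # ---------------- Euler updates (concentrations, CaMKt, V, Ko) ----------
    # stimulus charge is booked as a Na+ influx: the K+ cycle then closes
    # through the NaK pump and the channel K+ efflux balances the pump K+
    # influx exactly at the paced normoxic limit cycle (zero net cleft flux)
    dnai = (-(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab - istm)
            * ACAP / (FARADAY * VMYO) + JdiffNa * VSS / VMYO)
    dnass = -(icana + 3.0 * inaca_ss) * ACAP / (FARADAY * VSS) - JdiffNa
    dki = (-(ito + ikr + iks + ik1 + ikatp + ikb - 2.0 * inak)
           * ACAP / (FARADAY * VMYO) + JdiffK * VSS / VMYO)
    dkss = -icak * ACAP / (FARADAY * VSS) - JdiffK

    Bcai = 1.0 / (1.0 + 0.05 * 0.00238 / (0.00238 + cai) ** 2
                  + 0.07 * 0.0005 / (0.0005 + cai) ** 2)
    dcai = Bcai * (-(ipca + icab - 2.0 * inaca_i) * ACAP / (2.0 * FARADAY * VMYO)
                   - Jup * VNSR / VMYO + Jdiff * VSS / VMYO)
    Bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + cass) ** 2
                   + 1.124 * 0.0087 / (0.0087 + cass) ** 2)
    dcass = Bcass * (-(ical - 2.0 * inaca_ss) * ACAP / (2.0 * FARADAY * VSS)
                     + Jrel * VJSR / VSS - Jdiff)
    dcansr = Jup - Jtr * VJSR / VNSR
    Bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)
    dcajsr = Bcajsr * (Jtr - Jrel)

    y[0] = v + dt * dvdt
    y[1] = nai + dt * dnai
    y[2] = nass + dt * dnass
    y[3] = ki + dt * dki
    y[4] = kss + dt * dkss
    y[5] = cai + dt * dcai
    y[6] = cass + dt * dcass
    y[7] = cansr + dt * dcansr
    y[8] = cajsr + dt * dcajsr
    y[37] = CaMKt + dt * (aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt)

    if update_ko:
        dko = alpha * sum_ikx
        if math.isfinite(tau_wo):
            dko += (p[P_KB] - ko) / tau_wo
        y[38] = ko + dt * dko

    # ---------------- Rush-Larsen gate updates ----------------
    y[9] = minf + (m - minf) * math.exp(-dt / taum)
    y[10] = hinf + (h - hinf) * math.exp(-dt / tauh)
    y[11] = jinf + (jg - jinf) * math.exp(-dt / tauj)
    y[12] = mLss + (mL - mLss) * math.exp(-dt / tmL)
    y[13] = hLss + (hL - hLss) * math.exp(-dt / thL)
    y[14] = hLssp + (hLp - hLssp) * math.exp(-dt / thLp)
    y[15] = ass + (a - ass) * math.exp(-dt / ta)
    y[16] = iss + (iF - iss) * math.exp(-dt / tiF)
    y[17] = iss + (iS - iss) * math.exp(-dt / tiS)
    y[18] = assp + (ap - assp) * math.exp(-dt / ta)
    y[19] = iss + (iFp - iss) * math.exp(-dt / tiFp)
    y[20] = iss + (iSp - iss) * math.exp(-dt / tiSp)
    y[21] = dss + (d - dss) * math.exp(-dt / td)
    y[22] = fss + (ff - fss) * math.exp(-dt / tff)
    y[23] = fss + (fs - fss) * math.exp(-dt / tfs)
    y[24] = fss + (fcaf - fss) * math.exp(-dt / tfcaf)
    y[25] = fss + (fcas - fss) * math.exp(-dt / tfcas)
    y[26] = fss + (jca - fss) * math.exp(-dt / tjca)
    nca_inf = anca * k2n / km2n
    y[27] = nca_inf + (nca - nca_inf) * math.exp(-dt * km2n)
    y[28] = fss + (ffp - fss) * math.exp(-dt / tffp)
    y[29] = fss + (fcafp - fss) * math.exp(-dt / tfcafp)
    y[30] = xrss + (xrf - xrss) * math.exp(-dt / txrf)
    y[31] = xrss + (xrs - xrss) * math.exp(-dt / txrs)
    y[32] = xs1ss + (xs1 - xs1ss) * math.exp(-dt / txs1)
    y[33] = xs2ss + (xs2 - xs2ss) * math.exp(-dt / txs2)
    y[34] = xk1ss + (xk1 - xk1ss) * math.exp(-dt / txk1)
    y[35] = Jrel_inf + (y[35] - Jrel_inf) * math.exp(-dt / tau_rel)
    y[36] = Jrel_infp + (y[36] - Jrel_infp) * math.exp(-dt / tau_relp)

    return dvdt


# ---- recording layout for the 0D runner --------------------------------------
REC_T = 0
REC_V = 1
REC_KO = 2
REC_NAI = 3
REC_CAI = 4
REC_CUM0 = 5           # 5..12  cumulative integrals IKr,IKs,Ito,IK1,IKatp,IKb,ICaK,INaK
REC_I0 = 13            # 13..20 instantaneous same order
REC_ICAL = 21
REC_INA = 22
REC_INAL = 23
REC_INACA = 24
REC_DVDTMAX = 25
NREC_CH = 26
CUM_NAMES = ("IKr", "IKs", "Ito", "IK1", "IKatp", "IKb", "ICaK", "INaK")


@njit(cache=True)
def _stim_at(t, bcl, t_first, width, amp):
    if amp <= 0.0 or bcl <= 0.0 or t < t_first:
        return 0.0
    ph = (t - t_first) % bcl
    if ph < width:
        return amp
    return 0.0


@njit(cache=True)
def run_0d(y, rec, t0, bcl, stim_amp, stim_w, t_first,
           met, met_dt,
           icalg_gain, icalg_on, icalg_off,
           alpha0, shrink_total, shrink_full_ms, t_occ,
           tau_pre, tau_post,
           p, nf, nc, clamp_ko):
    """Integrate the single cell for rec.shape[0]-1 ms, recording every 1 ms.

    ``met``: (n, 5) metabolite samples [ATP, ADP, pHi, pHo, LPC] on a uniform
    ``met_dt``-ms grid starting at t0.  ``tau_pre/tau_post``: wash-out time
    constant (ms) before/after the occlusion time ``t_occ``.  ``nf``/``nc``:
    substeps per ms in fine/coarse mode.  Returns the frame index of a
    numerical failure, or -1 on success.
    """
    cur = np.zeros(NCUR)
    acc = np.zeros(8)
    nframes = rec.shape[0]
    nmet = met.shape[0]
    dvdt = 0.0
    t = t0
    for i in range(nframes):
        v0 = y[0]
        if not (-300.0 < v0 < 300.0) or not (y[38] > 0.0):
            return i
        rec[i, REC_T] = t
        rec[i, REC_V] = v0
        rec[i, REC_KO] = y[38]
        rec[i, REC_NAI] = y[1]
        rec[i, REC_CAI] = y[5]
        for k in range(8):
            rec[i, REC_CUM0 + k] = acc[k]
        if i == nframes - 1:
            break

        mrow = int((t - t0) / met_dt)
        if mrow >= nmet:
            mrow = nmet - 1
        atp = met[mrow, 0]
        adp = met[mrow, 1]
        phi = met[mrow, 2]
        pho = met[mrow, 3]
        lpc = met[mrow, 4]

        if t < t_occ:
            tau_wo = tau_pre
            alpha = alpha0
        else:
            tau_wo = tau_post
            fr = (t - t_occ) / shrink_full_ms
            if fr > 1.0:
                fr = 1.0
            alpha = alpha0 / (1.0 - shrink_total * fr)
        icalg = 1.0
        if icalg_on <= t < icalg_off:
            icalg = icalg_gain

        stim_frame = False
        if stim_amp > 0.0 and bcl > 0.0:
            if t + 1.0 >= t_first:
                ph = (t - t_first) % bcl
                if ph > bcl - 2.0 or ph < stim_w + 2.0:
                    stim_frame = True
        fine = stim_frame or abs(dvdt) > 0.05 or v0 > -40.0
        nsub = nf if fine else nc
        dt = 1.0 / nsub
        dvmax = 0.0
        for k in range(nsub):
            tt = t + k * dt
            istm = _stim_at(tt, bcl, t_first, stim_w, stim_amp)
            dvdt = step_cell(y, dt, istm, atp, adp, phi, pho, lpc, icalg,
                             alpha, tau_wo, p, cur, acc, not clamp_ko)
            if dvdt > dvmax:
                dvmax = dvdt
        rec[i, REC_ICAL] = cur[3]
        rec[i, REC_INA] = cur[0]
        rec[i, REC_INAL] = cur[1]
        rec[i, REC_INACA] = cur[12]
        rec[i, REC_DVDTMAX] = dvmax
        # order of instantaneous channels must match CUM_NAMES
        rec[i, REC_I0 + 0] = cur[6]   # IKr
        rec[i, REC_I0 + 1] = cur[7]   # IKs
        rec[i, REC_I0 + 2] = cur[2]   # Ito
        rec[i, REC_I0 + 3] = cur[8]   # IK1
        rec[i, REC_I0 + 4] = cur[9]   # IKatp
        rec[i, REC_I0 + 5] = cur[10]  # IKb
        rec[i, REC_I0 + 6] = cur[5]   # ICaK
        rec[i, REC_I0 + 7] = cur[11]  # INaK
        t += 1.0
    return -1


# ---- 1D cable runner ----------------------------------------------------------

@njit(cache=True)
def run_1d(Y, dx, dv_coef, lam,
           rec_probe, probe_idx,
           snap_v, snap_ko, snap_every,
           act_times, act_thresh,
           t0, bcl, stim_amp, stim_w, t_first, n_stim,
           met, met_dt,
           wstep, wph,
           alpha0, t_occ, tau_wo_node,
           dk_coef, n_tr_sub,
           p, nf, nc_max, dvdt_fine):
    """Operator-split cable integration.

    Y: (nnode, NSTATE).  dv_coef: DV (cm^2/ms); lam: conductivity ratio.
    rec_probe: (nframes, nprobe, 5) with channels [Vm, Ko, Vo, cum sumIKx,
    cum transport-term integral].  snap_v/snap_ko: (nsnap, nnode) profile
    snapshots every ``snap_every`` frames.  act_times: (nbeat, nnode)
    activation times (NaN until the upstroke crosses ``act_thresh``).
    wstep/wph: per-node weights of the stepwise (ATP/ADP/LPC) and ramped (pH)
    metabolite profiles.  tau_wo_node: per-node wash-out constant (ms, inf in
    the altered segment).  Returns -1 on success or the failing frame.
    """
    nnode = Y.shape[0]
    nframes = rec_probe.shape[0]
    nprobe = probe_idx.shape[0]
    nmet = met.shape[0]
    cur = np.zeros(NCUR)
    acc = np.zeros(8)

    cum_ikx = np.zeros(nnode)
    cum_tr = np.zeros(nnode)
    dvdt_n = np.zeros(nnode)
    vtmp = np.zeros(nnode)
    ko_flux = np.zeros(nnode + 1)
    vo = np.zeros(nnode)

    inv_dx2 = 1.0 / (dx * dx)
    # diffusive stability bound for the coarse sub-step
    nc = nc_max
    while nc < nf and (1.0 / nc) * dv_coef * inv_dx2 > 0.4:
        nc *= 2
    beat_ctr = -1
    last_pulse = -1

    t = t0
    isnap = 0
    tr_ctr = 0
    tr_dt = 0.0
    for i in range(nframes):
        vmax = -1.0e30
        admax = 0.0
        for n in range(nnode):
            if Y[n, 0] > vmax:
                vmax = Y[n, 0]
            if abs(dvdt_n[n]) > admax:
                admax = abs(dvdt_n[n])
            if not (-300.0 < Y[n, 0] < 300.0) or not (Y[n, 38] > 0.0):
                return i
        # record probes
        vmean = 0.0
        for n in range(nnode):
            vmean += Y[n, 0]
        vmean /= nnode
        for q in range(nprobe):
            n = probe_idx[q]
            rec_probe[i, q, 0] = Y[n, 0]
            rec_probe[i, q, 1] = Y[n, 38]
            rec_probe[i, q, 2] = -(Y[n, 0] - vmean) / (1.0 + lam)
            rec_probe[i, q, 3] = cum_ikx[n]
            rec_probe[i, q, 4] = cum_tr[n]
        if snap_every > 0 and i % snap_every == 0 and isnap < snap_v.shape[0]:
            for n in range(nnode):
                snap_v[isnap, n] = Y[n, 0]
                snap_ko[isnap, n] = Y[n, 38]
            isnap += 1
        if i == nframes - 1:
            break

        mrow = int((t - t0) / met_dt)
        if mrow >= nmet:
            mrow = nmet - 1
        atp_f = met[mrow, 0]
        adp_f = met[mrow, 1]
        phi_f = met[mrow, 2]
        pho_f = met[mrow, 3]
        lpc_f = met[mrow, 4]

        stim_frame = False
        if stim_amp > 0.0 and bcl > 0.0 and t + 1.0 >= t_first:
            ph = (t - t_first) % bcl
            if ph > bcl - 2.0 or ph < stim_w + 2.0:
                stim_frame = True
        fine = stim_frame or admax > dvdt_fine
        if dvdt_fine <= 0.05 and vmax > -40.0:
            fine = True
        nsub = nf if fine else nc
        dt = 1.0 / nsub

        for k in range(nsub):
            tt = t + k * dt
            istm0 = _stim_at(tt, bcl, t_first, stim_w, stim_amp)
            if istm0 > 0.0:
                pulse_id = int((tt - t_first) / bcl)
                if pulse_id != last_pulse:
                    last_pulse = pulse_id
                    beat_ctr += 1
            # reaction step per node
            for n in range(nnode):
                if wstep[n] > 0.5 and tt >= t_occ:
                    atp = atp_f
                    adp = adp_f
                    lpc = lpc_f
                else:
                    atp = ATP_NORM
                    adp = ADP_NORM
                    lpc = LPC_NORM
                if tt >= t_occ:
                    phi = PHI_NORM + wph[n] * (phi_f - PHI_NORM)
                    pho = PHO_NORM + wph[n] * (pho_f - PHO_NORM)
                else:
                    phi = PHI_NORM
                    pho = PHO_NORM
                istm = istm0 if n < n_stim else 0.0
                vprev = Y[n, 0]
                dvdt_n[n] = step_cell(Y[n], dt, istm, atp, adp, phi, pho, lpc,
                                      1.0, alpha0, tau_wo_node[n], p, cur, acc,
                                      True)
                cum_ikx[n] += cur[17] * dt
                vnew = Y[n, 0]
                if beat_ctr >= 0 and beat_ctr < act_times.shape[0]:
                    if vprev < act_thresh and vnew >= act_thresh:
                        if math.isnan(act_times[beat_ctr, n]):
                            act_times[beat_ctr, n] = tt + dt * (act_thresh - vprev) / (vnew - vprev)
            # diffusion step (explicit, zero-flux ends)
            # conservative flux-form stencil: zero flux through the ends,
            # so the spatial mean of Vm is invariant under pure diffusion
            c = dt * dv_coef * inv_dx2
            for n in range(nnode):
                if n == 0:
                    lap = Y[1, 0] - Y[0, 0]
                elif n == nnode - 1:
                    lap = Y[nnode - 2, 0] - Y[nnode - 1, 0]
                else:
                    lap = Y[n - 1, 0] - 2.0 * Y[n, 0] + Y[n + 1, 0]
                vtmp[n] = Y[n, 0] + c * lap
            for n in range(nnode):
                vprev = Y[n, 0]
                vnew = vtmp[n]
                if beat_ctr >= 0 and beat_ctr < act_times.shape[0]:
                    if vprev < act_thresh and vnew >= act_thresh:
                        if math.isnan(act_times[beat_ctr, n]):
                            act_times[beat_ctr, n] = tt + dt
                Y[n, 0] = vnew
            # transport step (diffusion + electromigration of Ko)
            tr_dt += dt
            tr_ctr += 1
            if dk_coef > 0.0 and (tr_ctr >= n_tr_sub or k == nsub - 1):
                vmean = 0.0
                for n in range(nnode):
                    vmean += Y[n, 0]
                vmean /= nnode
                for n in range(nnode):
                    vo[n] = -(Y[n, 0] - vmean) / (1.0 + lam)
                ko_flux[0] = 0.0
                ko_flux[nnode] = 0.0
                for n in range(1, nnode):
                    grad = (Y[n, 38] - Y[n - 1, 38]) / dx
                    kom = 0.5 * (Y[n, 38] + Y[n - 1, 38])
                    em = FRT * kom * (vo[n] - vo[n - 1]) / dx
                    ko_flux[n] = -dk_coef * (grad + em)
                for n in range(nnode):
                    div = -(ko_flux[n + 1] - ko_flux[n]) / dx
                    Y[n, 38] += tr_dt * div
                    cum_tr[n] += tr_dt * div
                tr_ctr = 0
                tr_dt = 0.0
            elif dk_coef <= 0.0:
                tr_ctr = 0
                tr_dt = 0.0
        t += 1.0
    return -1
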