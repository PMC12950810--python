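"""Human ventricular myocyte model (O'Hara-Rudy dynamic formulation).

Re-implementation of the published undiseased human ventricular
action-potential model (41 state variables: membrane voltage, Na+/K+/
Ca2+ concentrations in cytosol/subspace/SR, Hodgkin-Huxley gates with
CaMK-phosphorylated duplicates, ryanodine-release fluxes and active
CaMK fraction), configured here for the midmyocardial ("M") cell type.

Three configuration hooks modify the published formulation:

* ``pca_scale`` multiplies the L-type Ca2+ permeability P_Ca (0.8 in
  this study's baseline, matching measured midmyocardial APD_90);
* ``gkr_scale`` multiplies the rapid delayed-rectifier conductance
  G_Kr (0.31 emulates the ~69% current loss of the variant channels);
* ``iso`` switches on a beta-adrenergic (1 uM isoproterenol) effect
  set modelled as two channel populations per PKA target - a
  phosphorylated fraction carrying the full PKA effect and an
  unaffected remainder.  Phosphorylated I_CaL has increased
  permeability and hyperpolarizing shifts of the activation and
  inactivation curves; phosphorylated I_Ks conductance and Na+/K+
  pump turnover are increased; phospholamban phosphorylation raises
  the SERCA Ca2+ affinity and troponin-I phosphorylation lowers the
  myofilament Ca2+ affinity.  The steady-state gating curves of the
  mixture are the fraction-weighted averages of the two populations.

Integration is fixed-step hybrid Rush-Larsen: gating variables are
updated with their exact local exponential relaxation, all other
states with forward Euler.  The integrator is compiled with numba.

Units follow the published model: ms, mV, mM; currents in uA/uF.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["STATE_NAMES", "initial_state", "pack_params", "run_segment",
           "compute_currents", "CELLTYPE_ENDO", "CELLTYPE_EPI", "CELLTYPE_M"]

CELLTYPE_ENDO, CELLTYPE_EPI, CELLTYPE_M = 0, 1, 2

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
)

# parameter-vector layout for the compiled integrator
P_KO, P_GKR, P_PCA, P_ISO, P_DSHIFT, P_FSHIFT, P_ISO_ICAL, P_ISO_GKS, \
    P_ISO_INAK, P_ISO_KMUP, P_ISO_KMTRPN, P_STIM_AMP, P_STIM_DUR, \
    P_CELLTYPE, P_F_ICAL, P_F_IKS, P_F_INAK, P_F_PLB, P_F_TNI = range(19)


def initial_state() -> np.ndarray:
    """Published resting initial conditions (pre-pacing)."""
    y = np.zeros(41)
    y[0] = -87.0          # v
    y[1] = 7.0            # nai
    y[2] = 7.0            # nass
    y[3] = 145.0          # ki
    y[4] = 145.0          # kss
    y[5] = 1.0e-4         # cai
    y[6] = 1.0e-4         # cass
    y[7] = 1.2            # cansr
    y[8] = 1.2            # cajsr
    ones = [10, 11, 12, 13, 14, 16, 17, 19, 20, 22, 23,
            25, 26, 27, 28, 29, 31, 32, 37]
    for i in ones:
        y[i] = 1.0
    return y


def pack_params(ko=5.4, gkr_scale=1.0, pca_scale=1.0, iso=False,
                d_shift=-3.0, f_shift=-2.8, iso_ical=2.5, iso_gks=3.2,
                iso_inak=1.3, iso_kmup=0.54, iso_kmtrpn=1.6,
                stim_amplitude=-80.0, stim_duration=0.5,
                celltype=CELLTYPE_M, f_ical=0.45, f_iks=0.55,
                f_inak=0.30, f_plb=0.85, f_tni=0.67) -> np.ndarray:
    p = np.zeros(19)
    p[P_KO] = ko
    p[P_GKR] = gkr_scale
    p[P_PCA] = pca_scale
    p[P_ISO] = 1.0 if iso else 0.0
    p[P_DSHIFT] = d_shift
    p[P_FSHIFT] = f_shift
    p[P_ISO_ICAL] = iso_ical
    p[P_ISO_GKS] = iso_gks
    p[P_ISO_INAK] = iso_inak
    p[P_ISO_KMUP] = iso_kmup
    p[P_ISO_KMTRPN] = iso_kmtrpn
    p[P_STIM_AMP] = stim_amplitude
    p[P_STIM_DUR] = stim_duration
    p[P_CELLTYPE] = celltype
    p[P_F_ICAL] = f_ical
    p[P_F_IKS] = f_iks
    p[P_F_INAK] = f_inak
    p[P_F_PLB] = f_plb
    p[P_F_TNI] = f_tni
    return p


@njit(cache=True)
def _derivs(y, p, ist, out):
    """Time derivatives / gate targets of the full model.

    Fills ``out`` with: out[0:41] = dy/dt for the Euler-updated states
    (gate entries hold the steady-state value instead), out[41:82] =
    relaxation time constant for gate entries (0 marks Euler states),
    out[82:90] = selected currents (IKr, ICaL, INaCa, IKs, IK1, INaK,
    INaL, Ito) for inspection.
    """
    # --- constants -------------------------------------------------------
    nao = 140.0
    cao = 1.8
    ko = p[P_KO]
    R = 8314.0
    T = 310.0
    F = 96485.0
    epi = p[P_CELLTYPE] == 1.0
    mcell = p[P_CELLTYPE] == 2.0
    iso = p[P_ISO] == 1.0

    L = 0.01
    rad = 0.0011
    vcell = 1000.0 * 3.14 * rad * rad * L
    ageo = 2.0 * 3.14 * rad * rad + 2.0 * 3.14 * rad * L
    acap = 2.0 * ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    m = y[9]
    hf = y[10]
    hs = y[11]
    jg = y[12]
    hsp = y[13]
    jp = y[14]
    mL = y[15]
    hL = y[16]
    hLp = y[17]
    a = y[18]
    iF = y[19]
    iS = y[20]
    ap = y[21]
    iFp = y[22]
    iSp = y[23]
    d = y[24]
    ff = y[25]
    fs = y[26]
    fcaf = y[27]
    fcas = y[28]
    jca = y[29]
    nca = y[30]
    ffp = y[31]
    fcafp = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    xk1 = y[37]
    Jrelnp = y[38]
    Jrelp = y[39]
    CaMKt = y[40]

    # --- CaMK ------------------------------------------------------------
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dCaMKt = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt
    fp_frac = 1.0 / (1.0 + KmCaMK / CaMKa)   # CaMK-phosphorylated fraction

    # --- reversal potentials --------------------------------------------
    ENa = (R * T / F) * math.log(nao / nai)
    EK = (R * T / F) * math.log(ko / ki)
    PKNa = 0.01833
    EKs = (R * T / F) * math.log((ko + PKNa * nao) / (ki + PKNa * nai))

    vsafe = v if abs(v) > 1e-8 else 1e-8
    vfrt = vsafe * F / (R * T)
    vffrt = vsafe * F * F / (R * T)

    # --- INa -------------------------------------------------------------
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    tjp = 1.46 * tj
    hp = Ahf * hf + Ahs * hsp
    GNa = 75.0
    INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fp_frac) * h * jg
                                      + fp_frac * hp * jp)

    # --- INaL ------------------------------------------------------------
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tmL = tm
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    GNaL = 0.0075
    if epi:
        GNaL *= 0.6
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fp_frac) * hL + fp_frac * hLp)

    # --- Ito -------------------------------------------------------------
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if epi:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_to_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ip_gate = AiF * iFp + AiS * iSp
    Gto = 0.02
    if epi or mcell:
        Gto *= 4.0
    Ito = Gto * (v - EK) * ((1.0 - fp_frac) * a * i_to_gate
                            + fp_frac * ap * ip_gate)

    # --- ICaL / ICaNa / ICaK --------------------------------------------
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    if iso:
        # fraction-weighted mixture of PKA-phosphorylated (shifted)
        # and non-phosphorylated gating curves
        fi = p[P_F_ICAL]
        dss_p = 1.0 / (1.0 + math.exp(-(v - p[P_DSHIFT] + 3.940) / 4.230))
        fss_p = 1.0 / (1.0 + math.exp((v - p[P_FSHIFT] + 19.58) / 3.696))
        dss = (1.0 - fi) * dss + fi * dss_p
        fss = (1.0 - fi) * fss + fi * fss_p
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                           + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    tffp = 2.5 * tff
    fpg = Aff * ffp + Afs * fs
    tfcafp = 2.5 * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)

    e2v = math.exp(2.0 * vfrt)
    e1v = math.exp(vfrt)
    PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * cao) / (e2v - 1.0)
    PhiCaNa = vffrt * (0.75 * nass * e1v - 0.75 * nao) / (e1v - 1.0)
    PhiCaK = vffrt * (0.75 * kss * e1v - 0.75 * ko) / (e1v - 1.0)
    PCa = 0.0001 * p[P_PCA]
    if iso:
        PCa *= 1.0 + p[P_F_ICAL] * (p[P_ISO_ICAL] - 1.0)
    if epi:
        PCa *= 1.2
    elif mcell:
        PCa *= 2.5
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    ICaL = ((1.0 - fp_frac) * PCa * PhiCaL * d
            * (f * (1.0 - nca) + jca * fca * nca)
            + fp_frac * PCap * PhiCaL * d
            * (fpg * (1.0 - nca) + jca * fcap * nca))
    ICaNa = ((1.0 - fp_frac) * PCaNa * PhiCaNa * d
             * (f * (1.0 - nca) + jca * fca * nca)
             + fp_frac * PCaNap * PhiCaNa * d
             * (fpg * (1.0 - nca) + jca * fcap * nca))
    ICaK = ((1.0 - fp_frac) * PCaK * PhiCaK * d
            * (f * (1.0 - nca) + jca * fca * nca)
            + fp_frac * PCaKp * PhiCaK * d
            * (fpg * (1.0 - nca) + jca * fcap * nca))

    # --- IKr -------------------------------------------------------------
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))
           * 1.0 / (1.0 + math.exp((v - 10.0) / 30.0)))
    GKr = 0.046 * p[P_GKR]
    if epi:
        GKr *= 1.3
    elif mcell:
        GKr *= 0.8
    IKr = GKr * math.sqrt(ko / 5.4) * xr * rkr * (v - EK)

    # --- IKs -------------------------------------------------------------
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034
    if epi:
        GKs *= 1.4
    if iso:
        GKs *= 1.0 + p[P_F_IKS] * (p[P_ISO_GKS] - 1.0)
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # --- IK1 -------------------------------------------------------------
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59)
                                  / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                    + math.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    GK1 = 0.1908
    if epi:
        GK1 *= 1.2
    elif mcell:
        GK1 *= 1.3
    IK1 = GK1 * math.sqrt(ko) * rk1 * xk1 * (v - EK)

    # --- INaCa (myoplasmic 80% / subspace 20%) ---------------------------
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
    zca = 2.0
    zna = 1.0
    Gncx = 0.0008
    if epi:
        Gncx *= 1.1
    elif mcell:
        Gncx *= 1.4
    KmCaAct = 150.0e-6

    # myoplasmic component
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
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace component
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k1 = h12 * cao * kcaon
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo_ss = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo_ss * (zna * JncxNa + zca * JncxCa)

    # --- INaK ------------------------------------------------------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p2 = 1899.0
    k3m = 79300.0
    k4p2 = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta_ = -0.1550
    Knai = Knai0 * math.exp(delta_ * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta_) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    Pfrac = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3
          / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0))
    a3 = (k3p2 * (ko / Kko) ** 2
          / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0))
    b3 = k3m * Pfrac * H / (1.0 + MgATP / Kmgatp)
    a4 = k4p2 * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    if epi:
        Pnak *= 0.9
    elif mcell:
        Pnak *= 0.7
    if iso:
        Pnak *= 1.0 + p[P_F_INAK] * (p[P_ISO_INAK] - 1.0)
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # --- background / minor currents ------------------------------------
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    if epi:
        GKb *= 0.6
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * vffrt * (nai * e1v - nao) / (e1v - 1.0)
    PCab = 2.5e-8
    ICab = PCab * 4.0 * vffrt * (cai * e2v - 0.341 * cao) / (e2v - 1.0)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # --- diffusion fluxes ------------------------------------------------
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # --- SR release (RyR) ------------------------------------------------
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if mcell:
        Jrel_inf *= 1.7
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    if mcell:
        Jrel_infp *= 1.7
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    Jrel = (1.0 - fp_frac) * Jrelnp + fp_frac * Jrelp

    # --- SERCA uptake / leak / translocation -----------------------------
    kmup = 0.00092
    if iso:
        kmup *= 1.0 - p[P_F_PLB] * (1.0 - p[P_ISO_KMUP])
    Jupnp = 0.004375 * cai / (cai + kmup)
    Jupp = 2.75 * 0.004375 * cai / (cai + kmup - 0.00017)
    if epi:
        Jupnp *= 1.3
        Jupp *= 1.3
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fp_frac) * Jupnp + fp_frac * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # --- buffers ---------------------------------------------------------
    cmdnmax = 0.05
    if epi:
        cmdnmax *= 1.3
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    if iso:
        kmtrpn *= 1.0 + p[P_F_TNI] * (p[P_ISO_KMTRPN] - 1.0)
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    # --- membrane voltage ------------------------------------------------
    Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + ist)
    out[0] = -Itot

    # --- concentrations --------------------------------------------------
    out[1] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * acap
              / (F * vmyo) + JdiffNa * vss / vmyo)
    out[2] = -(ICaNa + 3.0 * INaCa_ss) * acap / (F * vss) - JdiffNa
    out[3] = (-(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK) * acap
              / (F * vmyo) + JdiffK * vss / vmyo)
    out[4] = -ICaK * acap / (F * vss) - JdiffK
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    out[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * acap / (2.0 * F * vmyo)
                     - Jup * vnsr / vmyo + Jdiff * vss / vmyo)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    out[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * acap / (2.0 * F * vss)
                      + Jrel * vjsr / vss - Jdiff)
    out[7] = Jup - Jtr * vjsr / vnsr
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    out[8] = Bcajsr * (Jtr - Jrel)

    # --- gates: steady state in out[i], tau in out[41+i] -----------------
    out[9] = mss
    out[41 + 9] = tm
    out[10] = hss
    out[41 + 10] = thf
    out[11] = hss
    out[41 + 11] = ths
    out[12] = jss
    out[41 + 12] = tj
    out[13] = hssp
    out[41 + 13] = thsp
    out[14] = jss
    out[41 + 14] = tjp
    out[15] = mLss
    out[41 + 15] = tmL
    out[16] = hLss
    out[41 + 16] = thL
    out[17] = hLssp
    out[41 + 17] = thLp
    out[18] = ass
    out[41 + 18] = ta
    out[19] = iss
    out[41 + 19] = tiF
    out[20] = iss
    out[41 + 20] = tiS
    out[21] = assp
    out[41 + 21] = ta
    out[22] = iss
    out[41 + 22] = tiFp
    out[23] = iss
    out[41 + 23] = tiSp
    out[24] = dss
    out[41 + 24] = td
    out[25] = fss
    out[41 + 25] = tff
    out[26] = fss
    out[41 + 26] = tfs
    out[27] = fcass
    out[41 + 27] = tfcaf
    out[28] = fcass
    out[41 + 28] = tfcas
    out[29] = fcass
    out[41 + 29] = tjca
    out[30] = anca * k2n / km2n
    out[41 + 30] = 1.0 / km2n
    out[31] = fss
    out[41 + 31] = tffp
    out[32] = fcass
    out[41 + 32] = tfcafp
    out[33] = xrss
    out[41 + 33] = txrf
    out[34] = xrss
    out[41 + 34] = txrs
    out[35] = xs1ss
    out[41 + 35] = txs1
    out[36] = xs2ss
    out[41 + 36] = txs2
    out[37] = xk1ss
    out[41 + 37] = txk1
    out[38] = Jrel_inf
    out[41 + 38] = tau_rel
    out[39] = Jrel_infp
    out[41 + 39] = tau_relp
    out[40] = dCaMKt
    out[41 + 40] = 0.0    # Euler-updated

    # --- inspection currents --------------------------------------------
    out[82] = IKr
    out[83] = ICaL
    out[84] = INaCa_i + INaCa_ss
    out[85] = IKs
    out[86] = IK1
    out[87] = INaK
    out[88] = INaL
    out[89] = Ito


#: indices updated by forward Euler (everything else is Rush-Larsen)
_EULER = (0, 1, 2, 3, 4, 5, 6, 7, 8, 40)


@njit(cache=True)
def run_segment(y, dur_ms, dt, p, stimulate, rec, rec_stride):
    """Integrate for ``dur_ms``; a stimulus of the configured amplitude
    is applied in the first ``stim_duration`` ms when ``stimulate``.

    ``rec``: (n, 2) output array receiving (v, cai) every ``rec_stride``
    steps (pass a (0, 2) array to skip recording).  Returns the number
    of recorded samples.  ``y`` is updated in place.
    """
    n = int(round(dur_ms / dt))
    out = np.empty(90)
    nrec = 0
    record = rec.shape[0] > 0
    for istep in range(n):
        if record and istep % rec_stride == 0 and nrec < rec.shape[0]:
            rec[nrec, 0] = y[0]
            rec[nrec, 1] = y[5]
            nrec += 1
        t = istep * dt
        ist = p[P_STIM_AMP] if (stimulate and t < p[P_STIM_DUR]) else 0.0
        _derivs(y, p, ist, out)
        # Euler states
        y[0] += dt * out[0]
        y[1] += dt * out[1]
        y[2] += dt * out[2]
        y[3] += dt * out[3]
        y[4] += dt * out[4]
        y[5] += dt * out[5]
        y[6] += dt * out[6]
        y[7] += dt * out[7]
        y[8] += dt * out[8]
        y[40] += dt * out[40]
        # Rush-Larsen gate states
        for k in range(9, 40):
            ss = out[k]
            tau = out[41 + k]
            y[k] = ss - (ss - y[k]) * math.exp(-dt / tau)
    return nrec


def compute_currents(y: np.ndarray, p: np.ndarray) -> dict:
    """Selected instantaneous currents (uA/uF) at a model state."""
    out = np.empty(90)
    _derivs(y, p, 0.0, out)
    names = ("IKr", "ICaL", "INaCa", "IKs", "IK1", "INaK", "INaL", "Ito")
    return {n: float(out[82 + i]) for i, n in enumerate(names)}
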