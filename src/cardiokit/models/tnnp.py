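"""Human ventricular myocyte model (ten Tusscher-Noble-Noble-Panfilov, 2004),
epicardial / midmyocardial / endocardial variants.

The fast sodium current uses the conductance (Hodgkin-Huxley) form
``I_Na = g_Na m^3 h j (V - E_Na)`` and is carried by two independently gated
allele populations so that heterozygous channelopathies can be expressed as
``0.5 I_Na,WT + 0.5 I_Na,mut``.  Gate-function voltage shifts and the
I_CaL / I_Ks scalings enter through the intervention coefficient vector (see
:mod:`cardiokit.engine`).
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .loader import load_model_file

_DEF = load_model_file("tnnp2004.yaml")
_P = _DEF["params"]

R = _P["R"]; T = _P["T"]; F = _P["F"]
RTONF = R * T / F
CM = _P["Cm"]; V_C = _P["V_c"]; V_SR = _P["V_sr"]
KO = _P["K_o"]; NAO = _P["Na_o"]; CAO = _P["Ca_o"]
GNA = _P["g_Na"]; GK1 = _P["g_K1"]; GKR = _P["g_Kr"]; PKNA = _P["p_KNa"]
GCAL = _P["g_CaL"]; KNACA = _P["k_NaCa"]; GAMMA = _P["gamma"]
KMCA = _P["K_mCa"]; KMNAI = _P["K_mNai"]; KSAT = _P["k_sat"]; ANACA = _P["alpha_naca"]
PNAK = _P["P_NaK"]; KMK = _P["K_mK"]; KMNA = _P["K_mNa"]
GPK = _P["g_pK"]; GPCA = _P["g_pCa"]; KPCA = _P["K_pCa"]
GBNA = _P["g_bNa"]; GBCA = _P["g_bCa"]
VMAXUP = _P["V_maxup"]; KUP = _P["K_up"]
AREL = _P["a_rel"]; BREL = _P["b_rel"]; CREL = _P["c_rel"]; VLEAK = _P["V_leak"]
BUFC = _P["Buf_c"]; KBUFC = _P["K_bufc"]; BUFSR = _P["Buf_sr"]; KBUFSR = _P["K_bufsr"]
CAPC = CM / (V_C * F)

STATE_LABELS = tuple(_DEF["initial_state"].keys())
INITIAL_STATE = np.array(list(_DEF["initial_state"].values()), dtype=float)
SUBTYPES = _DEF["subtypes"]
DT = _DEF["step_size_ms"]

# state indices
iV = 0
iMA, iHA, iJA, iMB, iHB, iJB = 1, 2, 3, 4, 5, 6
iD, iF, iFCA, iR, iS, iXS, iXR1, iXR2, iG = 7, 8, 9, 10, 11, 12, 13, 14, 15
iCAI, iCASR, iNAI, iKI = 16, 17, 18, 19

GATE_IDX = (iMA, iHA, iJA, iMB, iHB, iJB, iD, iF, iFCA, iR, iS, iXS, iXR1, iXR2, iG)
CURRENT_LABELS = ("I_Na", "I_CaL", "I_Ks")


# -- closed-form sodium gate functions (shared by the kernel and the
#    voltage-clamp protocols; vectorized over V) -----------------------------

def m_inf(V):
    return 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2


def tau_m(V, s_kin=0.0):
    Vk = V + s_kin
    am = 1.0 / (1.0 + np.exp((-60.0 - Vk) / 5.0))
    bm = 0.1 / (1.0 + np.exp((Vk + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((Vk - 50.0) / 200.0))
    return am * bm


def h_inf(V):
    return 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2


def _ah(V):
    return np.where(V >= -40.0, 0.0, 0.057 * np.exp(-(V + 80.0) / 6.8))


def _bh(V):
    return np.where(
        V >= -40.0,
        0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
        2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
    )


def tau_h(V, s_kin=0.0):
    """Kinetics shift applies to beta_h only."""
    return 1.0 / (_ah(V) + _bh(V + s_kin))


def j_inf(V):
    return h_inf(V)


def _aj(V):
    neg = (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V)) \
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23)))
    return np.where(V >= -40.0, 0.0, neg)


def _bj(V):
    pos = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    neg = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    return np.where(V >= -40.0, pos, neg)


def tau_j(V):
    return 1.0 / (_aj(V) + _bj(V))


def e_na(Na_i=None):
    nai = INITIAL_STATE[iNAI] if Na_i is None else Na_i
    return RTONF * np.log(NAO / nai)


def i_na(V, m, h, j, Na_i=None):
    """Conductance-form sodium current, uA/uF."""
    return GNA * m ** 3 * h * j * (V - e_na(Na_i))


@njit(cache=True)
def kernel(S, istim, icoef, pvec, dS, yinf, ytau, cur):
    V = S[0]
    Cai = S[iCAI]; CaSR = S[iCASR]; Nai = S[iNAI]; Ki = S[iKI]
    g_to = pvec[0]; g_Ks = pvec[1]
    scale_cal = icoef[9]; scale_ks = icoef[10]; mixA = icoef[8]

    ENa = RTONF * np.log(NAO / Nai)
    EK = RTONF * np.log(KO / Ki)
    EKs = RTONF * np.log((KO + PKNA * NAO) / (Ki + PKNA * Nai))
    ECa = 0.5 * RTONF * np.log(CAO / Cai)

    # --- fast sodium current, two allele populations -----------------------
    INa = 0.0
    for al in range(2):
        off = 3 * al
        s_minf = icoef[0 + 4 * al]; s_mkin = icoef[1 + 4 * al]
        s_hinf = icoef[2 + 4 * al]; s_hkin = icoef[3 + 4 * al]
        m = S[iMA + off]; h = S[iHA + off]; j = S[iJA + off]
        Vm = V + s_minf
        minf = 1.0 / (1.0 + np.exp((-56.86 - Vm) / 9.03)) ** 2
        Vk = V + s_mkin
        am = 1.0 / (1.0 + np.exp((-60.0 - Vk) / 5.0))
        bm = 0.1 / (1.0 + np.exp((Vk + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((Vk - 50.0) / 200.0))
        taum = am * bm
        Vh = V + s_hinf
        hinf = 1.0 / (1.0 + np.exp((Vh + 71.55) / 7.43)) ** 2
        # kinetics shift acts on beta_h only; alpha_h keeps its native argument
        ah = 0.0 if V >= -40.0 else 0.057 * np.exp(-(V + 80.0) / 6.8)
        Vhk = V + s_hkin
        if Vhk >= -40.0:
            bh = 0.77 / (0.13 * (1.0 + np.exp(-(Vhk + 10.66) / 11.1)))
        else:
            bh = 2.7 * np.exp(0.079 * Vhk) + 3.1e5 * np.exp(0.3485 * Vhk)
        tauh = 1.0 / (ah + bh)
        jinf = hinf
        if V >= -40.0:
            aj = 0.0
            bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
        else:
            aj = (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V)) \
                * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23)))
            bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
        tauj = 1.0 / (aj + bj)
        yinf[iMA + off] = minf; ytau[iMA + off] = taum
        yinf[iHA + off] = hinf; ytau[iHA + off] = tauh
        yinf[iJA + off] = jinf; ytau[iJA + off] = tauj
        w = mixA if al == 0 else 1.0 - mixA
        INa += w * GNA * m ** 3 * h * j * (V - ENa)

    # --- L-type calcium current -------------------------------------------
    d = S[iD]; f = S[iF]; fCa = S[iFCA]
    vf = V * F / (R * T)
    if abs(V) < 1e-6:
        ICaL = scale_cal * GCAL * d * f * fCa * 2.0 * F * (Cai - 0.341 * CAO)
    else:
        e2 = np.exp(2.0 * vf)
        ICaL = scale_cal * GCAL * d * f * fCa * 4.0 * V * F * F / (R * T) \
            * (Cai * e2 - 0.341 * CAO) / (e2 - 1.0)
    dinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    yinf[iD] = dinf; ytau[iD] = ad * bd + gd
    finf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tauf = 1125.0 * np.exp(-(V + 27.0) ** 2 / 240.0) + 80.0 \
        + 165.0 / (1.0 + np.exp((25.0 - V) / 10.0))
    yinf[iF] = finf; ytau[iF] = tauf
    afca = 1.0 / (1.0 + (Cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + np.exp((Cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + np.exp((Cai - 0.00075) / 0.0008))
    fcainf = (afca + bfca + gfca + 0.23) / 1.46
    if fcainf > fCa and V > -60.0:
        fcainf = fCa                      # gate may only close above -60 mV
    yinf[iFCA] = fcainf; ytau[iFCA] = 2.0

    # --- potassium currents ------------------------------------------------
    Ito = g_to * S[iR] * S[iS] * (V - EK)
    rinf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    taur = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    yinf[iR] = rinf; ytau[iR] = taur
    if pvec[2] > 0.5:                     # endocardial s gate
        sinf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        taus = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:
        sinf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        taus = 85.0 * np.exp(-(V + 45.0) ** 2 / 320.0) \
            + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0
    yinf[iS] = sinf; ytau[iS] = taus

    IKs = scale_ks * g_Ks * S[iXS] * S[iXS] * (V - EKs)
    xsinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 60.0) / 20.0))
    yinf[iXS] = xsinf; ytau[iXS] = axs * bxs

    IKr = GKR * np.sqrt(KO / 5.4) * S[iXR1] * S[iXR2] * (V - EK)
    xr1inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    yinf[iXR1] = xr1inf; ytau[iXR1] = axr1 * bxr1
    xr2inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    yinf[iXR2] = xr2inf; ytau[iXR2] = axr2 * bxr2

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - EK - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (V - EK + 100.0)) + np.exp(0.1 * (V - EK - 10.0))) \
        / (1.0 + np.exp(-0.5 * (V - EK)))
    IK1 = GK1 * np.sqrt(KO / 5.4) * ak1 / (ak1 + bk1) * (V - EK)

    # --- pumps, exchangers, background -------------------------------------
    INaCa = KNACA * (np.exp(GAMMA * vf) * Nai ** 3 * CAO
                     - np.exp((GAMMA - 1.0) * vf) * NAO ** 3 * Cai * ANACA) \
        / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO)
           * (1.0 + KSAT * np.exp((GAMMA - 1.0) * vf)))
    INaK = PNAK * KO * Nai / ((KO + KMK) * (Nai + KMNA)
                              * (1.0 + 0.1245 * np.exp(-0.1 * vf) + 0.0353 * np.exp(-vf)))
    IpCa = GPCA * Cai / (KPCA + Cai)
    IpK = GPK * (V - EK) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = GBNA * (V - ENa)
    IbCa = GBCA * (V - ECa)

    # --- calcium handling --------------------------------------------------
    Ileak = VLEAK * (CaSR - Cai)
    Iup = VMAXUP / (1.0 + (KUP / Cai) ** 2)
    Irel = (AREL * CaSR * CaSR / (BREL * BREL + CaSR * CaSR) + CREL) * d * S[iG]
    ginf = 1.0 / (1.0 + (Cai / 0.00035) ** 6) if Cai < 0.00035 \
        else 1.0 / (1.0 + (Cai / 0.00035) ** 16)
    if ginf > S[iG] and V > -60.0:
        ginf = S[iG]
    yinf[iG] = ginf; ytau[iG] = 2.0

    bufc = 1.0 / (1.0 + BUFC * KBUFC / (Cai + KBUFC) ** 2)
    bufsr = 1.0 / (1.0 + BUFSR * KBUFSR / (CaSR + KBUFSR) ** 2)
    dS[iCAI] = bufc * (-(ICaL + IbCa + IpCa - 2.0 * INaCa) * CAPC / 2.0
                       + Ileak - Iup + Irel)
    dS[iCASR] = bufsr * (V_C / V_SR) * (Iup - Irel - Ileak)
    dS[iNAI] = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * CAPC
    dS[iKI] = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK - istim) * CAPC

    Iion = IK1 + Ito + IKr + IKs + ICaL + INaK + INa + IbNa + INaCa + IbCa + IpK + IpCa
    dS[0] = -Iion
    cur[0] = INa
    cur[1] = ICaL
    cur[2] = IKs


def pvec_for(subtype: str) -> np.ndarray:
    sub = SUBTYPES[subtype]
    return np.array([sub["g_to"], sub["g_Ks"], 1.0 if subtype == "endo" else 0.0])
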