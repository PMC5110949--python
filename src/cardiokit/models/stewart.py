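"""Human Purkinje fibre cell model (Stewart et al., 2009).

Same I_Na formulation as the ventricular model (conductance form, m^3 h j)
with a much larger maximal conductance, plus a funny current I_f, a sustained
outward current I_sus and a weak inward rectifier; the unstimulated cell is
self-oscillatory.  The calcium subsystem is the 2006 ten Tusscher
dyadic-subspace formulation.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .loader import load_model_file
from . import tnnp  # sodium gate functions are shared (same closed forms)

_DEF = load_model_file("stewart2009.yaml")
_P = _DEF["params"]

R = _P["R"]; T = _P["T"]; F = _P["F"]
RTONF = R * T / F
CM = _P["Cm"]; V_C = _P["V_c"]; V_SR = _P["V_sr"]; V_SS = _P["V_ss"]
KO = _P["K_o"]; NAO = _P["Na_o"]; CAO = _P["Ca_o"]
GNA = _P["g_Na"]; GK1 = _P["g_K1"]; GKR = _P["g_Kr"]; GKS = _P["g_Ks"]
PKNA = _P["p_KNa"]; GTO = _P["g_to"]; GSUS = _P["g_sus"]
GFNA = _P["g_f_Na"]; GFK = _P["g_f_K"]; GCAL = _P["g_CaL"]
KNACA = _P["k_NaCa"]; GAMMA = _P["gamma"]; KMCA = _P["K_mCa"]
KMNAI = _P["K_mNai"]; KSAT = _P["k_sat"]; ANACA = _P["alpha_naca"]
PNAK = _P["P_NaK"]; KMK = _P["K_mK"]; KMNA = _P["K_mNa"]
GPK = _P["g_pK"]; GPCA = _P["g_pCa"]; KPCA = _P["K_pCa"]
GBNA = _P["g_bNa"]; GBCA = _P["g_bCa"]
VMAXUP = _P["V_maxup"]; KUP = _P["K_up"]; VREL = _P["V_rel"]
VLEAK = _P["V_leak"]; VXFER = _P["V_xfer"]
K1P = _P["k1_prime"]; K2P = _P["k2_prime"]; K3 = _P["k3"]; K4 = _P["k4"]
EC = _P["EC"]; MAXSR = _P["max_sr"]; MINSR = _P["min_sr"]
BUFC = _P["Buf_c"]; KBUFC = _P["K_bufc"]
BUFSR = _P["Buf_sr"]; KBUFSR = _P["K_bufsr"]
BUFSS = _P["Buf_ss"]; KBUFSS = _P["K_bufss"]
CAPC = CM / (V_C * F)

STATE_LABELS = tuple(_DEF["initial_state"].keys())
INITIAL_STATE = np.array(list(_DEF["initial_state"].values()), dtype=float)
DT = _DEF["step_size_ms"]

iV = 0
iMA, iHA, iJA, iMB, iHB, iJB = 1, 2, 3, 4, 5, 6
iD, iF, iF2, iFCASS, iR, iS, iXS, iXR1, iXR2, iY = 7, 8, 9, 10, 11, 12, 13, 14, 15, 16
iCAI, iCASS, iCASR, iRPR, iNAI, iKI = 17, 18, 19, 20, 21, 22

GATE_IDX = (iMA, iHA, iJA, iMB, iHB, iJB, iD, iF, iF2, iFCASS,
            iR, iS, iXS, iXR1, iXR2, iY)
CURRENT_LABELS = ("I_Na", "I_CaL", "I_Ks")

# the sodium gate closed forms are those of the ventricular model
m_inf = tnnp.m_inf
tau_m = tnnp.tau_m
h_inf = tnnp.h_inf
tau_h = tnnp.tau_h
j_inf = tnnp.j_inf
tau_j = tnnp.tau_j


def e_na(Na_i=None):
    nai = INITIAL_STATE[iNAI] if Na_i is None else Na_i
    return RTONF * np.log(NAO / nai)


def i_na(V, m, h, j, Na_i=None):
    return GNA * m ** 3 * h * j * (V - e_na(Na_i))


@njit(cache=True)
def kernel(S, istim, icoef, pvec, dS, yinf, ytau, cur):
    V = S[0]
    Cai = S[iCAI]; Cass = S[iCASS]; CaSR = S[iCASR]
    Nai = S[iNAI]; Ki = S[iKI]
    scale_cal = icoef[9]; scale_ks = icoef[10]; mixA = icoef[8]

    ENa = RTONF * np.log(NAO / Nai)
    EK = RTONF * np.log(KO / Ki)
    EKs = RTONF * np.log((KO + PKNA * NAO) / (Ki + PKNA * Nai))
    ECa = 0.5 * RTONF * np.log(CAO / Cai)
    vf = V * F / (R * T)

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

    # --- L-type calcium current (dyadic subspace driving) ------------------
    d = S[iD]; f = S[iF]; f2 = S[iF2]; fCass = S[iFCASS]
    z = 2.0 * (V - 15.0) * F / (R * T)
    if abs(V - 15.0) < 1e-6:
        ICaL = scale_cal * GCAL * d * f * f2 * fCass * 2.0 * F * (0.25 * Cass - CAO)
    else:
        ez = np.exp(z)
        ICaL = scale_cal * GCAL * d * f * f2 * fCass * 4.0 * (V - 15.0) * F * F / (R * T) \
            * (0.25 * Cass * ez - CAO) / (ez - 1.0)
    dinf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    yinf[iD] = dinf; ytau[iD] = ad * bd + gd
    finf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tauf = 1102.5 * np.exp(-(V + 27.0) ** 2 / 225.0) \
        + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0)) \
        + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0
    yinf[iF] = finf; ytau[iF] = tauf
    f2inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tauf2 = 562.0 * np.exp(-(V + 27.0) ** 2 / 240.0) \
        + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0)) \
        + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0))
    yinf[iF2] = f2inf; ytau[iF2] = tauf2
    fcassinf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0
    yinf[iFCASS] = fcassinf; ytau[iFCASS] = taufcass

    # --- potassium / funny / sustained currents ----------------------------
    Ito = GTO * S[iR] * S[iS] * (V - EK)
    rinf = 1.0 / (1.0 + np.exp((20.0 - V) / 13.0))
    taur = 10.45 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 7.3
    yinf[iR] = rinf; ytau[iR] = taur
    sinf = 1.0 / (1.0 + np.exp((V + 27.0) / 13.0))
    taus = 85.0 * np.exp(-(V + 25.0) ** 2 / 320.0) \
        + 5.0 / (1.0 + np.exp((V - 40.0) / 5.0)) + 42.0
    yinf[iS] = sinf; ytau[iS] = taus

    Isus = GSUS * (V - EK) / (1.0 + np.exp((5.0 - V) / 17.0))

    y = S[iY]
    IfNa = GFNA * y * (V - ENa)
    IfK = GFK * y * (V - EK)
    yinfv = 1.0 / (1.0 + np.exp((V + 80.6) / 6.8))
    ay = np.exp(-2.9 - 0.04 * V)
    by = np.exp(3.6 + 0.11 * V)
    yinf[iY] = yinfv; ytau[iY] = 4000.0 / (ay + by)

    IKs = scale_ks * GKS * S[iXS] * S[iXS] * (V - EKs)
    xsinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    yinf[iXS] = xsinf; ytau[iXS] = axs * bxs + 80.0

    IKr = GKR * np.sqrt(KO / 5.4) * S[iXR1] * S[iXR2] * (V - EK)
    xr1inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    yinf[iXR1] = xr1inf; ytau[iXR1] = axr1 * bxr1
    xr2inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    yinf[iXR2] = xr2inf; ytau[iXR2] = axr2 * bxr2

    xk1inf = 1.0 / (1.0 + np.exp(0.1 * (V + 75.44)))
    IK1 = GK1 * xk1inf * (V - 8.0 - EK)

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

    # --- calcium handling (CICR through the dyadic subspace) ---------------
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / CaSR) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    dS[iRPR] = -k2 * Cass * S[iRPR] + K4 * (1.0 - S[iRPR])
    O = k1 * Cass * Cass * S[iRPR] / (K3 + k1 * Cass * Cass)
    Irel = VREL * O * (CaSR - Cass)
    Ileak = VLEAK * (CaSR - Cai)
    Iup = VMAXUP / (1.0 + (KUP / Cai) ** 2)
    Ixfer = VXFER * (Cass - Cai)

    bufc = 1.0 / (1.0 + BUFC * KBUFC / (Cai + KBUFC) ** 2)
    bufsr = 1.0 / (1.0 + BUFSR * KBUFSR / (CaSR + KBUFSR) ** 2)
    bufss = 1.0 / (1.0 + BUFSS * KBUFSS / (Cass + KBUFSS) ** 2)
    dS[iCAI] = bufc * (-(IbCa + IpCa - 2.0 * INaCa) * CAPC / 2.0
                       - (Iup - Ileak) * (V_SR / V_C) + Ixfer)
    dS[iCASR] = bufsr * (Iup - Irel - Ileak)
    dS[iCASS] = bufss * (-ICaL * CM / (2.0 * V_SS * F)
                         + Irel * (V_SR / V_SS) - Ixfer * (V_C / V_SS))
    dS[iNAI] = -(INa + IbNa + IfNa + 3.0 * INaK + 3.0 * INaCa) * CAPC
    dS[iKI] = -(IK1 + Ito + Isus + IfK + IKr + IKs - 2.0 * INaK + IpK - istim) * CAPC

    Iion = IK1 + Ito + Isus + IKr + IKs + ICaL + INaK + INa + IbNa \
        + INaCa + IbCa + IpK + IpCa + IfNa + IfK
    dS[0] = -Iion
    cur[0] = INa
    cur[1] = ICaL
    cur[2] = IKs
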