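"""Human atrial myocyte model (Maleckar et al. 2009, Nygren 1998 lineage).

I_Na uses the Goldman-Hodgkin-Katz permeability form

    I_Na = P_Na m^3 (0.9 h1 + 0.1 h2) [Na+]_c V F^2/(R T)
           (e^{(V-E_Na)F/RT} - 1) / (e^{V F/RT} - 1)

with the removable singularity at V = 0 evaluated by its analytic limit.
Activation kinetics are parameterized by the published "m factor"
(tau_m = 4.2e-5 exp(-m_factor^2) + 2.4e-5 s, m_factor = (V+25.57)/28.8) and
inactivation kinetics by the "h factor" (tau_h1 = 0.03 h_factor + 0.0003 s,
h_factor = 1/(1+exp((V+35.1)/3.2))); mutation effects enter as voltage shifts
of these factors and of the steady-state curves.  Two allele populations of
(m, h1, h2) are integrated for heterozygous mixing.

The model carries restricted extracellular cleft concentrations, diadic-space
calcium and an SR with phenomenological release gating (F1/F2).
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .loader import load_model_file

_DEF = load_model_file("maleckar2009.yaml")
_P = _DEF["params"]

R = _P["R"]; T = _P["T"]; F = _P["F"]
RTONF = R * T / F
FORT = 1.0 / RTONF
CM = _P["Cm"]
VOLI = _P["Vol_i"]; VOLC = _P["Vol_c"]; VOLD = _P["Vol_d"]
VOLREL = _P["Vol_rel"]; VOLUP = _P["Vol_up"]
NAB = _P["Na_b"]; KB = _P["K_b"]; CAB = _P["Ca_b"]
TAUNA = _P["tau_Na"]; TAUK = _P["tau_K"]; TAUCA = _P["tau_Ca"]
PNA = _P["P_Na"]
GCAL = _P["g_CaL"]; ECAAPP = _P["E_Ca_app"]; KCA = _P["k_Ca"]
GT = _P["g_t"]; GKUR = _P["g_kur"]; GKS = _P["g_Ks"]; GKR = _P["g_Kr"]; GK1 = _P["g_K1"]
GBNA = _P["g_B_Na"]; GBCA = _P["g_B_Ca"]
INAKMAX = _P["i_NaK_max"]; KNAKK = _P["K_NaK_K"]; KNAKNA = _P["k_NaK_Na"]
ICAPMAX = _P["i_CaP_max"]; KCAP = _P["k_CaP"]
KNACA = _P["k_NaCa"]; GAMMA = _P["gamma_na"]; DNACA = _P["d_NaCa"]
PHINAEN = _P["phi_Na_en"]
IUPMAX = _P["I_up_max"]; KCYCA = _P["k_cyca"]; KSRCA = _P["k_srca"]; KXCS = _P["k_xcs"]
TAUTR = _P["tau_tr"]; ALPHAREL = _P["alpha_rel"]
RRECOV = _P["r_recov"]; KRELI = _P["k_rel_i"]; KRELD = _P["k_rel_d"]
MGI = _P["Mg_i"]

STATE_LABELS = tuple(_DEF["initial_state"].keys())
INITIAL_STATE = np.array(list(_DEF["initial_state"].values()), dtype=float)
DT = _DEF["step_size_ms"]

iV = 0
iMA, iH1A, iH2A, iMB, iH1B, iH2B = 1, 2, 3, 4, 5, 6
iDL, iFL1, iFL2, iRt, iSt, iAUR, iIUR, iN, iPA = 7, 8, 9, 10, 11, 12, 13, 14, 15
iNAC, iKC, iCAC, iNAI, iKI, iCAI, iCAD = 16, 17, 18, 19, 20, 21, 22
iOC, iOTC, iOTMGC, iOTMGMG, iOCALSE = 23, 24, 25, 26, 27
iCAREL, iCAUP, iF1, iF2 = 28, 29, 30, 31

# O_C, O_TC and O_Calse are linear in their ligand at fixed concentration and
# are advanced with the same exponential update as the HH gates.
GATE_IDX = (iMA, iH1A, iH2A, iMB, iH1B, iH2B, iDL, iFL1, iFL2,
            iRt, iSt, iAUR, iIUR, iN, iPA, iOC, iOTC, iOCALSE)
CURRENT_LABELS = ("I_Na", "I_CaL", "I_Ks")


def m_inf(V):
    return 1.0 / (1.0 + np.exp((V + 27.12) / -8.21))


def tau_m(V, s_kin=0.0):
    """ms; the kinetics shift acts on the m factor's voltage argument."""
    mf = (V + s_kin + 25.57) / 28.8
    return (4.2e-5 * np.exp(-mf * mf) + 2.4e-5) * 1000.0


def h_inf(V):
    return 1.0 / (1.0 + np.exp((V + 63.6) / 5.3))


def _h_factor(V):
    return 1.0 / (1.0 + np.exp((V + 35.1) / 3.2))


def tau_h1(V, s_kin=0.0):
    return (0.03 * _h_factor(V + s_kin) + 0.0003) * 1000.0


def tau_h2(V, s_kin=0.0):
    return (0.12 * _h_factor(V + s_kin) + 0.003) * 1000.0


def e_na(Na_c=None, Na_i=None):
    nac = INITIAL_STATE[iNAC] if Na_c is None else Na_c
    nai = INITIAL_STATE[iNAI] if Na_i is None else Na_i
    return RTONF * np.log(nac / nai)


def i_na(V, m, h1, h2, Na_c=None, Na_i=None):
    """GHK-form sodium current in uA/uF at the given gate values."""
    from ..sodium import ina_ghk, INaParams
    nac = INITIAL_STATE[iNAC] if Na_c is None else Na_c
    nai = INITIAL_STATE[iNAI] if Na_i is None else Na_i
    p = INaParams(P_Na=PNA, Na_c=nac, E_Na=RTONF * np.log(nac / nai),
                  F=F, R=R, T=T, Cm=CM)
    return ina_ghk(V, m, h1, h2, p)


@njit(cache=True)
def kernel(S, istim, icoef, pvec, dS, yinf, ytau, cur):
    V = S[0]
    Nac = S[iNAC]; Kc = S[iKC]; Cac = S[iCAC]
    Nai = S[iNAI]; Ki = S[iKI]; Cai = S[iCAI]; Cad = S[iCAD]
    Carel = S[iCAREL]; Caup = S[iCAUP]
    scale_cal = icoef[9]; scale_ks = icoef[10]; mixA = icoef[8]

    ENa = RTONF * np.log(Nac / Nai)
    EK = RTONF * np.log(Kc / Ki)
    ECa = 0.5 * RTONF * np.log(Cac / Cai)

    # --- I_Na (GHK form), two allele populations ---------------------------
    iNa = 0.0  # pA
    vf = V * FORT
    for al in range(2):
        off = 3 * al
        s_minf = icoef[0 + 4 * al]; s_mkin = icoef[1 + 4 * al]
        s_hinf = icoef[2 + 4 * al]; s_hkin = icoef[3 + 4 * al]
        m = S[iMA + off]; h1 = S[iH1A + off]; h2 = S[iH2A + off]
        Vm = V + s_minf
        minf = 1.0 / (1.0 + np.exp((Vm + 27.12) / -8.21))
        mfac = (V + s_mkin + 25.57) / 28.8
        taum = (4.2e-5 * np.exp(-mfac * mfac) + 2.4e-5) * 1000.0
        Vh = V + s_hinf
        hinf = 1.0 / (1.0 + np.exp((Vh + 63.6) / 5.3))
        hfac = 1.0 / (1.0 + np.exp((V + s_hkin + 35.1) / 3.2))
        tauh1 = (0.03 * hfac + 0.0003) * 1000.0
        tauh2 = (0.12 * hfac + 0.003) * 1000.0
        yinf[iMA + off] = minf; ytau[iMA + off] = taum
        yinf[iH1A + off] = hinf; ytau[iH1A + off] = tauh1
        yinf[iH2A + off] = hinf; ytau[iH2A + off] = tauh2
        hh = 0.9 * h1 + 0.1 * h2
        if abs(V) < 1e-6:
            # limit of V/(e^{VF/RT}-1) as V -> 0 is RT/F
            ghk = PNA * m ** 3 * hh * Nac * F * (np.exp((V - ENa) * FORT) - 1.0)
        else:
            ghk = PNA * m ** 3 * hh * Nac * V * F * FORT \
                * (np.exp((V - ENa) * FORT) - 1.0) / (np.exp(vf) - 1.0)
        w = mixA if al == 0 else 1.0 - mixA
        iNa += w * ghk

    # --- I_CaL -------------------------------------------------------------
    ds_ = S[iDL]; fl1 = S[iFL1]; fl2 = S[iFL2]
    fca = Cad / (Cad + KCA)
    iCaL = scale_cal * GCAL * ds_ * (fca * fl1 + (1.0 - fca) * fl2) * (V - ECAAPP)
    yinf[iDL] = 1.0 / (1.0 + np.exp((V + 9.0) / -5.8))
    ytau[iDL] = (0.0027 * np.exp(-((V + 35.0) / 30.0) ** 2) + 0.002) * 1000.0
    flinf = 1.0 / (1.0 + np.exp((V + 27.4) / 7.1))
    yinf[iFL1] = flinf
    ytau[iFL1] = (0.161 * np.exp(-((V + 40.0) / 14.4) ** 2) + 0.01) * 1000.0
    yinf[iFL2] = flinf
    ytau[iFL2] = (1.3323 * np.exp(-((V + 40.0) / 14.2) ** 2) + 0.0626) * 1000.0

    # --- potassium currents ------------------------------------------------
    it = GT * S[iRt] * S[iSt] * (V - EK)
    yinf[iRt] = 1.0 / (1.0 + np.exp((1.0 - V) / 11.0))
    ytau[iRt] = (0.0035 * np.exp(-(V / 30.0) ** 2) + 0.0015) * 1000.0
    yinf[iSt] = 1.0 / (1.0 + np.exp((V + 40.5) / 11.5))
    ytau[iSt] = (0.025635 * np.exp(-((V + 52.45) / 15.8827) ** 2) + 0.01414) * 1000.0

    ikur = GKUR * S[iAUR] * S[iIUR] * (V - EK)
    yinf[iAUR] = 1.0 / (1.0 + np.exp(-(V + 6.0) / 8.6))
    ytau[iAUR] = (0.009 / (1.0 + np.exp((V + 5.0) / 12.0)) + 0.0005) * 1000.0
    yinf[iIUR] = 1.0 / (1.0 + np.exp((V + 7.5) / 10.0))
    ytau[iIUR] = (0.59 / (1.0 + np.exp((V + 60.0) / 10.0)) + 3.05) * 1000.0

    iks = scale_ks * GKS * S[iN] * (V - EK)
    yinf[iN] = 1.0 / (1.0 + np.exp((V - 19.9) / -12.7))
    ytau[iN] = (0.7 + 0.4 * np.exp(-((V - 20.0) / 20.0) ** 2)) * 1000.0

    pip = 1.0 / (1.0 + np.exp((V + 55.0) / 24.0))
    ikr = GKR * S[iPA] * pip * (V - EK)
    yinf[iPA] = 1.0 / (1.0 + np.exp((V + 15.0) / -6.0))
    ytau[iPA] = (0.03118 + 0.21718 * np.exp(-((V + 20.1376) / 22.1996) ** 2)) * 1000.0

    ik1 = GK1 * Kc ** 0.4457 * (V - EK) \
        / (1.0 + np.exp(1.5 * (V - EK + 3.6) * FORT))

    # --- pumps, exchangers, background -------------------------------------
    ibna = GBNA * (V - ENa)
    ibca = GBCA * (V - ECa)
    nai15 = Nai ** 1.5
    inak = INAKMAX * Kc / (Kc + KNAKK) * nai15 / (nai15 + KNAKNA ** 1.5) \
        * (V + 150.0) / (V + 200.0)
    icap = ICAPMAX * Cai / (Cai + KCAP)
    inaca = KNACA * (Nai ** 3 * Cac * np.exp(GAMMA * vf)
                     - Nac ** 3 * Cai * np.exp((GAMMA - 1.0) * vf)) \
        / (1.0 + DNACA * (Nac ** 3 * Cai + Nai ** 3 * Cac))

    # --- diadic space and SR calcium ---------------------------------------
    idi = (Cad - Cai) * 2.0 * F * VOLD / TAUTR  # tau_di = tau_tr = 10 ms
    iup = IUPMAX * (Cai / KCYCA - KXCS * KXCS * Caup / KSRCA) \
        / ((Cai + KCYCA) / KCYCA + KXCS * (Caup + KSRCA) / KSRCA)
    itr = (Caup - Carel) * 2.0 * F * VOLREL / TAUTR
    F2_ = S[iF2]
    irel = ALPHAREL * (F2_ / (F2_ + 0.25)) ** 2 * (Carel - Cai)

    cai4 = (Cai / (Cai + KRELI)) ** 4
    ract = 203.8 * (cai4 + (Cad / (Cad + KRELD)) ** 4)
    rinact = 33.96 + 339.6 * cai4
    dS[iF1] = (RRECOV * (1.0 - S[iF1] - F2_) - ract * S[iF1]) / 1000.0
    dS[iF2] = (ract * S[iF1] - rinact * F2_) / 1000.0

    # cytosolic buffers (per-second rates)
    dOC = 200000.0 * Cai * (1.0 - S[iOC]) - 476.0 * S[iOC]
    kOC = 200000.0 * Cai + 476.0
    yinf[iOC] = 200000.0 * Cai / kOC; ytau[iOC] = 1000.0 / kOC
    dOTC = 78400.0 * Cai * (1.0 - S[iOTC]) - 392.0 * S[iOTC]
    kOTC = 78400.0 * Cai + 392.0
    yinf[iOTC] = 78400.0 * Cai / kOTC; ytau[iOTC] = 1000.0 / kOTC
    free_tmg = 1.0 - S[iOTMGC] - S[iOTMGMG]
    dOTMgC = 200000.0 * Cai * free_tmg - 6.6 * S[iOTMGC]
    dOTMgMg = 2000.0 * MGI * free_tmg - 666.0 * S[iOTMGMG]
    dS[iOTMGC] = dOTMgC / 1000.0
    dS[iOTMGMG] = dOTMgMg / 1000.0
    dOCalse = 480.0 * Carel * (1.0 - S[iOCALSE]) - 400.0 * S[iOCALSE]
    kOCalse = 480.0 * Carel + 400.0
    yinf[iOCALSE] = 480.0 * Carel / kOCalse; ytau[iOCALSE] = 1000.0 / kOCalse

    # --- concentration dynamics (per-second fluxes, /1000 for ms) ----------
    istim_pa = istim * CM
    dS[iNAC] = ((NAB - Nac) / TAUNA
                + (iNa + ibna + 3.0 * inak + 3.0 * inaca + PHINAEN) / (VOLC * F)) / 1000.0
    dS[iKC] = ((KB - Kc) / TAUK
               + (it + ikur + ik1 + iks + ikr - 2.0 * inak) / (VOLC * F)) / 1000.0
    dS[iCAC] = ((CAB - Cac) / TAUCA
                + (iCaL + ibca + icap - 2.0 * inaca) / (2.0 * VOLC * F)) / 1000.0
    dS[iNAI] = -(iNa + ibna + 3.0 * inak + 3.0 * inaca + PHINAEN) / (VOLI * F) / 1000.0
    dS[iKI] = -(it + ikur + ik1 + iks + ikr - 2.0 * inak - istim_pa) / (VOLI * F) / 1000.0
    dS[iCAI] = (-(ibca + icap + iup - idi - irel - 2.0 * inaca) / (2.0 * VOLI * F)
                - (0.045 * dOC + 0.08 * dOTC + 0.16 * dOTMgC)) / 1000.0
    dS[iCAD] = -(iCaL + idi) / (2.0 * VOLD * F) / 1000.0
    dS[iCAREL] = ((itr - irel) / (2.0 * VOLREL * F) - 31.0 * dOCalse) / 1000.0
    dS[iCAUP] = (iup - itr) / (2.0 * VOLUP * F) / 1000.0

    itot = iNa + iCaL + it + ikur + ik1 + iks + ikr + ibna + ibca + inak + icap + inaca
    dS[0] = -itot / CM
    cur[0] = iNa / CM
    cur[1] = iCaL / CM
    cur[2] = iks / CM
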