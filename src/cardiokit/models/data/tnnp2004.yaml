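# Human ventricular myocyte model (ten Tusscher-Noble-Noble-Panfilov 2004).
# Units: mV, ms, mM, uA/uF.  Subtype-dependent conductances (g_to, g_Ks) are
# under `subtypes`.  The equation registry lives in cardiokit.models.tnnp.
params:
  R: 8314.472          # mJ/(mol K)
  T: 310.0             # K
  F: 96485.3415        # C/mol
  Cm: 0.185            # uF
  V_c: 0.016404        # uL, cytoplasmic volume
  V_sr: 0.001094       # uL, sarcoplasmic reticulum volume
  K_o: 5.4             # mM
  Na_o: 140.0          # mM
  Ca_o: 2.0            # mM
  g_Na: 14.838         # nS/pF
  g_K1: 5.405          # nS/pF
  g_Kr: 0.096          # nS/pF
  p_KNa: 0.03
  g_CaL: 1.75e-4       # cm^3 uF^-1 s^-1
  k_NaCa: 1000.0       # pA/pF
  gamma: 0.35
  K_mCa: 1.38          # mM
  K_mNai: 87.5         # mM
  k_sat: 0.1
  alpha_naca: 2.5
  P_NaK: 1.362         # pA/pF
  K_mK: 1.0            # mM
  K_mNa: 40.0          # mM
  g_pK: 0.0146         # nS/pF
  g_pCa: 0.825         # nS/pF
  K_pCa: 0.0005        # mM
  g_bNa: 0.00029       # nS/pF
  g_bCa: 0.000592      # nS/pF
  V_maxup: 0.000425    # mM/ms
  K_up: 0.00025        # mM
  a_rel: 0.016464      # mM/ms
  b_rel: 0.25          # mM
  c_rel: 0.008232      # mM/ms
  V_leak: 8.0e-5       # 1/ms
  Buf_c: 0.15          # mM
  K_bufc: 0.001        # mM
  Buf_sr: 10.0         # mM
  K_bufsr: 0.3         # mM
subtypes:
  epi:  {g_to: 0.294, g_Ks: 0.245}
  mid:  {g_to: 0.294, g_Ks: 0.062}
  endo: {g_to: 0.073, g_Ks: 0.245}
# Published resting state.  Sodium gates appear twice (alleles A and B).
initial_state:
  V: -86.2
  m_a: 0.0
  h_a: 0.75
  j_a: 0.75
  m_b: 0.0
  h_b: 0.75
  j_b: 0.75
  d: 0.0
  f: 1.0
  fCa: 1.0
  r: 0.0
  s: 1.0
  xs: 0.0
  xr1: 0.0
  xr2: 1.0
  g: 1.0
  Ca_i: 0.0002     # mM
  Ca_SR: 0.2       # mM
  Na_i: 11.6       # mM
  K_i: 138.3       # mM
step_size_ms: 0.001
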