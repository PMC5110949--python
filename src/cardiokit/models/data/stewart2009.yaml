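# Human Purkinje fibre cell model (Stewart-Aslanidi-Noble-Noble-Boyett-Zhang
# 2009).  Extends the 2006 ten Tusscher ventricular formulation with a
# hyperpolarization-activated funny current, a sustained outward current and
# a weakened inward rectifier; the model is self-oscillatory.
# Units: mV, ms, mM, uA/uF.
params:
  R: 8314.472
  T: 310.0
  F: 96485.3415
  Cm: 0.185            # uF
  V_c: 0.016404        # uL
  V_sr: 0.001094       # uL
  V_ss: 5.468e-5       # uL
  K_o: 5.4
  Na_o: 140.0
  Ca_o: 2.0
  g_Na: 130.5744       # nS/pF
  g_K1: 0.065          # nS/pF
  g_Kr: 0.0918         # nS/pF
  g_Ks: 0.2352         # nS/pF
  p_KNa: 0.03
  g_to: 0.08184        # nS/pF
  g_sus: 0.0227        # nS/pF
  g_f_Na: 0.0145654    # nS/pF
  g_f_K: 0.0234346     # nS/pF
  g_CaL: 3.98e-5       # cm^3 uF^-1 s^-1
  k_NaCa: 1000.0
  gamma: 0.35
  K_mCa: 1.38
  K_mNai: 87.5
  k_sat: 0.1
  alpha_naca: 2.5
  P_NaK: 2.724
  K_mK: 1.0
  K_mNa: 40.0
  g_pK: 0.0146
  g_pCa: 0.1238
  K_pCa: 0.0005
  g_bNa: 0.00029
  g_bCa: 0.000592
  V_maxup: 0.006375    # mM/ms
  K_up: 0.00025
  V_rel: 0.102         # mM/ms
  V_leak: 0.00036      # 1/ms
  V_xfer: 0.0038       # 1/ms
  k1_prime: 0.15
  k2_prime: 0.045
  k3: 0.06
  k4: 0.005
  EC: 1.5
  max_sr: 2.5
  min_sr: 1.0
  Buf_c: 0.2
  K_bufc: 0.001
  Buf_sr: 10.0
  K_bufsr: 0.3
  Buf_ss: 0.4
  K_bufss: 0.00025
initial_state:
  V: -69.1370441635924
  m_a: 0.0417391656294997
  h_a: 0.190678733735145
  j_a: 0.238219836154029
  m_b: 0.0417391656294997
  h_b: 0.190678733735145
  j_b: 0.238219836154029
  d: 0.000287906256206415
  f: 0.989328560287987
  f2: 0.995474890442185
  fCass: 0.999955429598213
  r: 0.00103618091196912
  s: 0.963861017995785
  xs: 0.00953708522974789
  xr1: 0.00550281999719088
  xr2: 0.313213286437995
  y: 0.0457562667986602
  Ca_i: 0.000101878186157052
  Ca_ss: 0.000446818714055411
  Ca_SR: 3.10836886659417
  R_prime: 0.991580051907845
  Na_i: 8.80420286531673
  K_i: 136.781894160227
step_size_ms: 0.01
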