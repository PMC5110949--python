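# Human atrial myocyte model (Maleckar-Greenstein-Trayanova-Giles 2009,
# Nygren 1998 lineage).  The fast sodium current uses the
# Goldman-Hodgkin-Katz permeability form with one activation gate (m) and two
# inactivation gates (h1 fast, h2 slow).  The original publication uses
# seconds; time constants and rates are converted to ms at load (the kernel
# works in ms throughout).  Membrane currents are in pA and are normalized by
# the 50 pF cell capacitance to uA/uF inside the kernel.
params:
  R: 8314.0            # mJ/(mol K)
  T: 306.15            # K (33 C)
  F: 96487.0           # C/mol
  Cm: 50.0             # pF
  Vol_i: 0.005884      # nL, cytosol
  Vol_c: 0.000800224   # nL, extracellular cleft
  Vol_d: 0.00011768    # nL, diadic space
  Vol_rel: 4.41e-5     # nL, SR release compartment
  Vol_up: 0.0003969    # nL, SR uptake compartment
  Na_b: 130.0          # mM, bulk bath sodium
  K_b: 5.4             # mM
  Ca_b: 1.8            # mM
  tau_Na: 14.3         # s, cleft-bulk diffusion
  tau_K: 10.0          # s
  tau_Ca: 24.7         # s
  P_Na: 0.0016         # nL/s, sodium permeability
  g_CaL: 6.75          # nS
  E_Ca_app: 60.0       # mV
  k_Ca: 0.025          # mM
  g_t: 8.25            # nS, transient outward
  g_kur: 2.25          # nS, ultrarapid delayed rectifier
  g_Ks: 1.0            # nS
  g_Kr: 0.5            # nS
  g_K1: 3.1            # nS
  g_B_Na: 0.060599     # nS
  g_B_Ca: 0.078681     # nS
  i_NaK_max: 68.55     # pA
  K_NaK_K: 1.0         # mM
  k_NaK_Na: 11.0       # mM
  i_CaP_max: 4.0       # pA
  k_CaP: 0.0002        # mM
  k_NaCa: 0.0374842    # pA/mM^4
  gamma_na: 0.45
  d_NaCa: 0.0003       # 1/mM^4
  phi_Na_en: -1.68     # pA, electroneutral Na influx
  I_up_max: 2800.0     # pA
  k_cyca: 0.0003       # mM
  k_srca: 0.5          # mM
  k_xcs: 0.4
  tau_tr: 0.01         # s
  alpha_rel: 200000.0  # pA/mM
  r_recov: 0.815       # 1/s
  k_rel_i: 0.0003      # mM
  k_rel_d: 0.003       # mM
  Mg_i: 2.5            # mM
initial_state:
  V: -74.2525
  m_a: 0.0032017
  h1_a: 0.8814
  h2_a: 0.8742
  m_b: 0.0032017
  h1_b: 0.8814
  h2_b: 0.8742
  d_L: 1.3005e-5
  f_L1: 0.9986
  f_L2: 0.9986
  r: 0.0010678
  s: 0.949
  a_ur: 0.000367
  i_ur: 0.9673
  n: 0.0048357
  pa: 5.3e-5
  Na_c: 130.011        # mM
  K_c: 5.3581          # mM
  Ca_c: 1.8147         # mM
  Na_i: 8.5547         # mM
  K_i: 129.435         # mM
  Ca_i: 6.729e-5       # mM
  Ca_d: 7.2495e-5      # mM
  O_C: 0.0275
  O_TC: 0.0133
  O_TMgC: 0.1961
  O_TMgMg: 0.7094
  O_Calse: 0.44369
  Ca_rel: 0.6465       # mM
  Ca_up: 0.6646        # mM
  F1: 0.4284
  F2: 0.0028
step_size_ms: 0.01
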