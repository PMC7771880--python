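# Two-item working-memory architecture: two excitatory populations sharing
# one inhibitory pool.  Couplings are the base set {Jee_s, Jee_c, Jie, Jei,
# Jii} = {35, 5, 13, -16, -14} scaled by sqrt(0.4); this scale reproduces
# the printed equilibrium landmarks of the architecture (branch point at
# I_B = 1.25647, Hopf points at 1.34998 / 1.5363, upper saddle-node at
# 4.13715) to the quoted precision.
name: two_item
architecture:
  kind: working_memory
  n_items: 2
  Jee_s: 22.135943621178654   # 35 * sqrt(0.4)
  Jee_c: 3.1622776601683795   # 5  * sqrt(0.4)
  Jie: 8.221921916437785      # 13 * sqrt(0.4)
  Jei: -10.119288512538814    # -16 * sqrt(0.4)
  Jii: -8.854377448471462     # -14 * sqrt(0.4)
populations:
  - {tau_m: 15.0, H: 0.0, Delta: 0.1, role: inhibitory}
  - {tau_m: 15.0, H: 0.0, Delta: 0.1, role: excitatory}
  - {tau_m: 15.0, H: 0.0, Delta: 0.1, role: excitatory}
stp: {tau_d: 200.0, tau_f: 1500.0, U0: 0.2}
stimulus:
  I_B: 1.2
  pulses: []
t_total: 5000.0
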