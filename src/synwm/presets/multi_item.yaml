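# Seven-item architecture for multi-item loading and capacity scans.
# The cross coupling and the excitatory-to-inhibitory coupling are read as
# (4/7)*18.5 and (4/7)*97; this reading reproduces the printed burst-cycle
# period T_c = 0.2035 s with three loaded items.
name: multi_item
architecture:
  kind: working_memory
  n_items: 7
  Jee_s: 154.0
  Jee_c: 10.571428571428571   # (4/7) * 18.5
  Jie: 55.42857142857143      # (4/7) * 97
  Jei: -26.0
  Jii: -60.0
populations:
  - {tau_m: 10.0, H: -2.0, Delta: 0.1, role: inhibitory}
  - {tau_m: 15.0, H: 0.05, Delta: 0.1, role: excitatory}
  - {tau_m: 15.0, H: 0.05, Delta: 0.1, role: excitatory}
  - {tau_m: 15.0, H: 0.05, Delta: 0.1, role: excitatory}
  - {tau_m: 15.0, H: 0.05, Delta: 0.1, role: excitatory}
  - {tau_m: 15.0, H: 0.05, Delta: 0.1, role: excitatory}
  - {tau_m: 15.0, H: 0.05, Delta: 0.1, role: excitatory}
  - {tau_m: 15.0, H: 0.05, Delta: 0.1, role: excitatory}
stp: {tau_d: 200.0, tau_f: 1500.0, U0: 0.2}
stimulus:
  I_B: 0.0
  pulses: []
t_total: 10000.0
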