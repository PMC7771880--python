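# Single self-coupled excitatory population: two-pulse loading protocol.
name: single_pop
architecture:
  kind: single
  J: 15.0
populations:
  - {tau_m: 15.0, H: 0.0, Delta: 0.25, role: excitatory}
stp: {tau_d: 200.0, tau_f: 1500.0, U0: 0.2}
stimulus:
  I_B: -1.0
  pulses:
    # two identical rectangular pulses, 150 ms wide, 150 ms apart
    - {population: 0, amplitude: 2.0, t_on: 300.0, t_off: 450.0}
    - {population: 0, amplitude: 2.0, t_on: 600.0, t_off: 750.0}
t_total: 1000.0
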