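# synwm — exact neural mass modelling of synaptic working memory

`synwm` is a research package for simulating **synaptic-based working
memory** with a *next-generation* neural mass model: an exact mean-field
reduction of networks of quadratic integrate-and-fire (QIF) neurons with
Tsodyks–Markram short-term depression and facilitation.  It is aimed at
computational neuroscientists who want to reproduce and extend the
working-memory phenomenology of this model class — selective and
spontaneous item reactivation, persistent activity, two-item juggling and
competition, multi-item loading, capacity limits and the associated
theta/beta/gamma rhythms — without rebuilding the numerical machinery.

## The model

For `N_pop` excitatory populations (one per memory item) and one inhibitory
pool of heterogeneous QIF neurons with Lorentzian-distributed
excitabilities (median `H_k`, half-width `Δ_k`), the infinite-network
dynamics closes exactly on the firing rate `r_k` and mean membrane
potential `v_k` of each population:

```
τ_k ṙ_k = Δ_k/(τ_k π) + 2 r_k v_k
τ_k v̇_k = v_k² + H_k + I_B + I_S^(k)(t) − (π τ_k r_k)² + τ_k Σ_l J̃_kl r_l
```

Excitatory-to-excitatory synapses are plastic, `J̃_kl = J_kl u_l x_l`, with
mesoscopic resources/utilization

```
ẋ_l = (1 − x_l)/τ_d − u_l x_l r_l
u̇_l = (U0 − u_l)/τ_f + U0 (1 − u_l) r_l
```

(`τ_d = 200 ms`, `τ_f = 1500 ms`, `U0 = 0.2`).  Depression paces the
population bursts that refresh a memory; facilitation holds the item trace
between bursts.  Because the reduction keeps `v_k`, the model also gives
access to LFP/EEG-like observables that pure firing-rate models cannot
produce — the package ships the corresponding heuristic rate model
(`synwm.rate_model`) precisely to exhibit that contrast, and full spiking
simulators (`synwm.qif_network`, micro- and mesoscopic plasticity) to
validate the mean field.

On top of the dynamics sit experiment protocols (`synwm.protocols`),
spectral analysis and burst detection (`synwm.spectral`), equilibrium
continuation with Hopf/fold/branch-point detection (`synwm.bifurcation`)
and the analytic maximal-capacity theory
`N_c^max ≃ τ_d ln[(τ_f/τ_d)/(1−U0)] / T_b` (`synwm.capacity`).

## Worked example

Self-sustained reactivation of a loaded item in the two-item architecture:

```python
import numpy as np
from synwm.neural_mass import Pulse, StimulusSchedule
from synwm.protocols import (load_preset, quiescent_state, run_protocol,
                             burst_train)

model = load_preset("two_item")          # 2 items + inhibitory pool
I_B = 1.532                              # spontaneous-reactivation regime
low = quiescent_state(model, I_B=I_B)    # symmetric low-activity state
print(np.round(low.r * 1e3, 2))          # [14.06  3.12  3.12]  Hz

stim = StimulusSchedule(I_B=I_B, pulses=[Pulse(1, 0.2, 0.0, 350.0)])
traj = run_protocol(model, stim, (0.0, 3500.0), low)
bursts = burst_train(traj, 1, low.r[1] * 1e3, threshold_factor=2.0,
                     min_separation=100.0).restrict(350.0, 3350.0)
print(np.round(bursts.times))            # [ 360.  798. 1179. 1529. 1867. 2190. 2518. 2835. 3152.]
print(round(bursts.rate_hz, 2))          # 2.87
```

Loading population one for 350 ms leaves its synapses facilitated; the
population then re-ignites spontaneously every ~345 ms (2.9 Hz), each burst
restoring the facilitation — memory maintenance without persistent firing.
Raising `I_B` to 2.0 instead parks the population in a persistent state at
≈8.6 Hz; dropping it below ≈1.25 leaves only the silent, purely synaptic
trace.

The same protocols are available from the shell:

```
synwm run --preset single_pop --model mass --out out/        # two-pulse loading
synwm run --preset single_pop --model network-meso --n 20000 --out out_net/
synwm bifurcation --preset two_item --i-start 1.1 --i-stop 4.3
synwm capacity                                         # analytic capacity table
synwm capacity-scan --rates 2,8,16                     # simulated capacity
```

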