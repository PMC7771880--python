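# Methods

## Model

`synwm` implements a multi-population *next-generation* neural mass model
for synaptic-based working memory, together with the spiking networks it
reduces, a heuristic firing-rate contrast model, and the analysis layers
(spectral, bifurcation, capacity) needed to run the standard working-memory
experiments.

The network consists of `N_pop` excitatory populations — each coding for
one memory item — and a single inhibitory pool that innervates all of them.
Neurons are quadratic integrate-and-fire (QIF), all-to-all coupled, with
excitabilities drawn from a Lorentzian with median `H_k` and half-width
`Delta_k`.  For that distribution the infinite-network dynamics closes
exactly (via the Ott–Antonsen / Lorentzian ansatz) on two macroscopic
variables per population, the firing rate `r_k` and the mean membrane
potential `v_k`:

    tau_k dr_k/dt = Delta_k/(tau_k pi) + 2 r_k v_k
    tau_k dv_k/dt = v_k^2 + H_k + I_B + I_S^(k)(t) - (pi tau_k r_k)^2
                    + tau_k sum_l J~_kl r_l

Only excitatory-to-excitatory synapses are plastic.  Mesoscopic
Tsodyks–Markram short-term plasticity attaches to each excitatory
population a pair `(x_l, u_l)` — available resources and utilization — with

    dx_l/dt = (1 - x_l)/tau_d - u_l x_l r_l
    du_l/dt = (U0 - u_l)/tau_f + U0 (1 - u_l) r_l

and the effective coupling `J~_kl = J_kl u_l x_l` on plastic entries.
Depression (`tau_d = 200 ms`) paces the population bursts that refresh a
memory; facilitation (`tau_f = 1500 ms`, baseline `U0 = 0.2`) carries the
itemtrace silently between bursts.  These three constants are fixed across
every experiment.

Units: time in ms, rates in 1/ms internally (reported in Hz), currents and
voltages dimensionless.  Population 0 is the inhibitory pool; the coupling
matrix is target-index-first (`J[k, l]` couples `l -> k`), with signs fixed
by the pre-synaptic population.

## Architecture presets

Three presets ship as data files (`synwm/presets/*.yaml`) and are the only
place parameter sets live:

- **single_pop** — one self-coupled excitatory population
  (`tau_m = 15 ms`, `H = 0`, `Delta = 0.25`, `J = 15`, `I_B = -1`) probed
  with two 150 ms pulses of amplitude 2, 150 ms apart.
- **two_item** — two excitatory populations plus the inhibitory pool, all
  `tau_m = 15 ms`, `H = 0`, `Delta = 0.1`.  The couplings are the base set
  `{Jee_s, Jee_c, Jie, Jei, Jii} = {35, 5, 13, -16, -14}` scaled by
  `sqrt(0.4)`.  The scale was pinned by the architecture's own equilibrium
  landmarks: with it, the symmetry-breaking branch point falls at
  `I_B = 1.25647`, the Hopf pair at `1.34998` and `1.5363`, and the upper
  saddle-node at `4.13715` — each to the full precision with which these
  points are known for this architecture.  Linear (`x 0.4`) and divisive
  (`/ 0.4`) scalings reproduce none of them.
- **multi_item** — seven excitatory populations plus the pool
  (`tau_m^e = 15 ms`, `tau_m^i = 10 ms`, `H^e = 0.05`, `H^i = -2`,
  `Jee_s = 154`, `Jee_c = (4/7)·18.5`, `Jie = (4/7)·97`, `Jei = -26`,
  `Jii = -60`, `I_B = 0`).  The `4/7` factors are a documented reading of a
  typographically ambiguous source; the calibration check is the
  three-item burst-cycle period `T_c ~ 0.2035 s`, which this reading
  reproduces (203.6 ms) together with the splay offsets `T_c/3`.

## Spiking reference simulators

`qif_network` integrates the full QIF network with an Euler scheme at
`dt = 0.0015 ms` (= 1e-4 tau_m).  The spike divergence is truncated at
`V = +/-100`: on crossing, the voltage is reset to -100 and clamped for a
refractory period `2 tau_m/100`, with the spike registered halfway through
— this exactly compensates the truncated excursion, as verified by the
suprathreshold single-neuron rate test.  Excitabilities are deterministic
Lorentzian quantiles, so the only randomness is the seeded uniform draw of
initial voltages.

Plasticity modes: `micro` carries `(X_i, U_i)` per neuron, jumping at that
neuron's own spikes (facilitation update first, then depression using the
updated utilization — the standard Tsodyks–Pawelzik–Markram order);
`meso` carries one `(x, u)` pair per excitatory population driven by the
population activity.  In both modes the weight transmitted by a spike is
`J u+ x-` (post-facilitation utilization, pre-depression resources), which
makes the two modes coincide exactly in the synchronous identical-neuron
limit — the property the convergence test asserts.  Spikes registered in
one Euler step drive the next step (explicit causality).  Population mean
voltages exclude neurons inside their refractory window, whose clamped
+/-100 values would otherwise dominate the average.

For finite networks the mesoscopic plasticity is an approximation: it
neglects the correlation between a neuron's own `X` and `U` and assumes
Poisson-like spike trains.  For quasi-periodic single-neuron firing the
per-neuron averages therefore differ systematically from the mesoscopic
pair (resources sampled at spike times exceed their time average); this is
a property of the reduction, not an implementation artifact, and is why
the micro/meso agreement is asserted only in the synchronous limit while
the mass-model validation uses the meso network.

## Numerical choices

- Mass-model integration: adaptive Dormand–Prince (RK45) with default
  tolerances 1e-12; runs are split at every stimulus discontinuity so the
  stepper never straddles a current jump.  Long protocol runs
  (multi-second, 10–30 ODEs) use rtol 1e-8 / atol 1e-10 — burst times move
  by less than 0.1 ms relative to 1e-10 runs — and 0.5 ms output sampling.
- Equilibria: the fixed-point system is reduced to the rates alone
  (voltages and synaptic variables have closed forms at equilibrium) and
  solved in log-rate space so Newton iterates stay positive.  Stability and
  type come from the numerical (central-difference) Jacobian of the full
  flow.
- Low-activity initial states: every experiment starts from the state in
  which all item populations share the same spontaneous low rate.  Beyond
  the branch point this state is unstable; it is still an equilibrium of
  the symmetric subspace and is obtained by root-solving there, never by
  settling (which would fall onto an asymmetric attractor).
- Continuation: natural-parameter stepping with secant prediction and step
  halving.  Folds terminate continuation by step underflow; the fold
  location is then extrapolated from the last converged points using the
  saddle-node normal form (the leading real eigenvalue squared is linear in
  the parameter), which refines it to ~1e-5.  Hopf points are bisected on
  the real part of the leading complex pair.  Branch points are
  distinguished from folds by testing whether the near-zero eigenvector is
  odd under the item-population exchange symmetry.
- Burst detection: a population burst is a local rate maximum exceeding
  `threshold_factor` (default 5) times the low-activity baseline rate, at
  least `min_separation` (default 20 ms) from the previous one.  Both knobs
  are exposed: the self-sustained and juggling regimes use factor 2 /
  separation 100 ms because their late-time bursts decay towards the small
  oscillation around the focus, and the multi-item runs use separation
  50 ms (inter-burst spacing ~68 ms).
- Spectra: STFT with 95% overlap (0.2 s windows for two-item protocols,
  1 s for multi-item), power normalized to its maximum, log10, floored at
  1e-2.  Band powers integrate the periodogram over theta (3–11 Hz), beta
  (11–25 Hz) and gamma (25–100 Hz).  Dominant frequencies exclude bins
  below 0.5 Hz and refine the peak with a log-parabolic fit.

## Measurement conventions for the regime frequencies

The printed frequencies of the two-item regimes depend mildly on where one
measures, so the package fixes these conventions:

- *Loading oscillations* (I_B = 1.2): burst repetition rate of population
  one from stimulus onset through the first burst past the offset (the
  stimulus-triggered oscillation does not halt at the pulse edge).
- *Self-sustained bursts* (I_B = 1.532): inverse mean inter-burst interval
  over 3 s from the stimulation offset.  The cycle decelerates slowly
  towards its asymptotic period, so the window matters at the few-percent
  level.
- *Juggling* (I_B = 1.532, second item at 2.65 s): per-population burst
  rate over 3 s from the second offset, averaged over the two populations.
  The alternation also decelerates: values drift from ~1.47 Hz right after
  loading towards ~1.39 Hz, so the reported ~1.43 Hz carries that caveat.
- *Persistent activity* (I_B = 2): final rate of the persistently active
  population after a 3 s relaxation.

## Analytic capacity

`capacity` implements the closed-form bound on how many items can juggle in
one recovery cycle: `N_c^max = T_c^max / T_b` with
`T_c^max = tau_d ln[(tau_f/tau_d)/(1-U0)]` (~447.6 ms at the standard
constants) and the inter-burst time
`T_b = tau_m^e/sqrt(C) [arctan(V_th/sqrt(C)) - arctan(V_0/sqrt(C))]`, with
the drive constant
`C = H_e + I_B + tau_m^e(-|J_ei| + J-bar) sqrt(H_e + I_B)/pi` and
`J-bar = [Jee_s + (N_pop - 2) Jee_c] x u`.  `C` is implemented literally as
this expression and the intermediate quantities (`J-bar`, the mean-field
rate) are exposed for audit: evaluated on the seven-item couplings it
yields `T_b` in the 13–20 ms range, which does **not** reproduce the
93–126 ms inter-burst range the capacity worked example is quoted with.
The worked example therefore takes those endpoints as given inputs; the
monotonicity structure (capacity growing with `H_e`, `I_B` and the
excitatory couplings, shrinking with `|J_ei|`) holds and is tested.

## Synthetic-condition caveats

The model is deterministic and noiseless; all "experiments" are single
trials.  Stimuli are ideal rectangles, memories non-overlapping, and the
inhibitory pool unique — so passing tests show the mean-field and network
machinery reproduces this idealized circuit, not that a cortical network
with sparse connectivity, conduction delays, finite-width synaptic kernels
or trial-to-trial noise would behave identically.  Network validation runs
use 2,000–20,000 neurons per population; the mean-field agreement improves
with size and the burst counts are already exact at these sizes, but
quantitative trace agreement at the per-mille level requires the
hundreds-of-thousands scale.

## Known limitations

- Gamma-band power grows with the memory load overall, but not strictly
  monotonically: the second harmonic of the inter-burst frequency sweeps
  through the PING resonance (~27–30 Hz) as the load changes, producing a
  pronounced peak at three items in the inhibitory potential.  The
  band-power tests assert overall growth, not stepwise monotonicity.
- In the persistent two-item competition regime, long distractors
  (~0.85 s) fall in a genuinely multistable parameter region where the
  final outcome is sensitive to delivery details; the competition tests
  cover the robust short- and intermediate-duration columns only.
- Limit cycles are characterized by direct simulation; there is no cycle
  continuation or Floquet analysis.
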