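"""Reference spiking simulators: heterogeneous QIF networks with STP.

These fully coupled networks validate the mean-field description.  Each
neuron obeys

    tau_m dV_i/dt = V_i^2 + eta_i + I_B + I_S(t) + tau_m sum_l J~_kl A_l(t)

with deterministic Lorentzian-quantile excitabilities eta_i.  The divergence
to +infinity at a spike is handled by a threshold/reset at +/-100 with a
compensating refractory period 2 tau_m/100; the spike is registered halfway
through the refractory window.  Plasticity is carried either per neuron
("micro": X_i, U_i driven by the neuron's own spike train) or per population
("meso": a single (x, u) pair driven by the population activity), or not at
all ("none").

Integration is a plain Euler scheme; the default step is the one used for
all plastic-network validation runs, dt = 0.0015 ms = 1e-4 tau_m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from synwm.neural_mass import (
    Architecture,
    ConfigurationError,
    PopulationParams,
    STPParams,
    StimulusSchedule,
)

__all__ = [
    "SpikeRaster",
    "NetworkTraces",
    "lorentzian_excitabilities",
    "simulate_network",
    "population_rate",
]

V_PEAK = 100.0
V_RESET = -100.0


def lorentzian_excitabilities(N: int, H: float, Delta: float) -> np.ndarray:
    """Deterministic quantile-spaced samples of a Lorentzian(H, Delta).

    eta_i = H + Delta tan[(pi/2) (2i - N - 1)/(N + 1)],  i = 1..N

    Sorted ascending, symmetric about the median H.
    """
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    if Delta <= 0:
        raise ConfigurationError("Delta must be positive")
    i = np.arange(1, N + 1, dtype=float)
    return H + Delta * np.tan(0.5 * np.pi * (2 * i - N - 1) / (N + 1))


@dataclass
class SpikeRaster:
    """Spike events: times (ms, non-decreasing), neuron and population index."""

    times: np.ndarray
    neurons: np.ndarray
    populations: np.ndarray

    def for_population(self, k: int) -> np.ndarray:
        return self.times[self.populations == k]

    def __len__(self) -> int:
        return self.times.size


@dataclass
class NetworkTraces:
    """Macroscopic traces sampled on a uniform grid (times in ms).

    ``r`` is the instantaneous population rate (1/ms) from a sliding
    spike-count window; ``v`` the population mean voltage excluding neurons
    inside their refractory window; ``x``/``u`` the (mean) synaptic variables
    of the excitatory populations.
    """

    t: np.ndarray
    r: np.ndarray
    v: np.ndarray
    x: np.ndarray
    u: np.ndarray
    exc_idx: np.ndarray

    @property
    def r_hz(self) -> np.ndarray:
        return self.r * 1e3

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@njit(cache=True)
def _run_kernel(
    n_steps,
    dt,
    offsets,          # (P+1,) neuron block boundaries
    pop_of,           # (N,) population index per neuron
    tau_pop,          # (P,)
    eta,              # (N,)
    J,                # (P, P) bare couplings
    plastic,          # (P, P) bool
    exc_of_pop,       # (P,) index into exc arrays or -1
    IB_times, IB_vals,          # background current steps
    pulse_pop, pulse_amp, pulse_on, pulse_off,
    stp_mode,         # 0 none, 1 micro, 2 meso
    tau_d, tau_f, U0,
    V,                # (N,) initial voltages, modified in place
    Xi, Ui,           # (N,) micro synaptic variables (unused unless micro)
    xm, um,           # (E,) meso synaptic variables
    delay_steps,      # (P,) registration delay in steps (tau/100 / dt)
    rec_stride,
    max_spikes,
):
    P = offsets.shape[0] - 1
    N = V.shape[0]
    E = xm.shape[0]

    pend = np.full(N, -1, np.int64)       # step at which a pending spike registers
    refr_end = np.zeros(N, np.int64)      # first step at which the neuron is free

    counts = np.zeros((n_steps, P), np.int32)   # registered spikes per step/pop
    weff = np.zeros(P)                    # efferent micro-STP weight sum per pop (this step)
    drive_raw = np.zeros(P)               # count-based activity from previous step
    drive_w = np.zeros(P)                 # micro-STP weighted activity from previous step

    n_rec = n_steps // rec_stride + 1
    rec_v = np.zeros((n_rec, P))
    rec_x = np.zeros((n_rec, E))
    rec_u = np.zeros((n_rec, E))

    sp_t = np.zeros(max_spikes)
    sp_i = np.zeros(max_spikes, np.int64)
    n_sp = 0

    ib = IB_vals[0]
    for step in range(n_steps):
        t = step * dt
        # background current (piecewise constant)
        for q in range(IB_times.shape[0]):
            if t >= IB_times[q]:
                ib = IB_vals[q]
        # synaptic drive per population from last step's registered activity
        syn = np.zeros(P)
        for k in range(P):
            s = 0.0
            for l in range(P):
                if plastic[k, l] and stp_mode != 0:
                    s += J[k, l] * drive_w[l]
                else:
                    s += J[k, l] * drive_raw[l]
            syn[k] = s

        # per-population external current
        stim = np.zeros(P)
        for q in range(pulse_pop.shape[0]):
            if pulse_on[q] <= t < pulse_off[q]:
                stim[pulse_pop[q]] += pulse_amp[q]

        # mesoscopic synapse relaxation
        if stp_mode == 2:
            for e in range(E):
                xm[e] += dt * (1.0 - xm[e]) / tau_d
                um[e] += dt * (U0 - um[e]) / tau_f

        # micro synapse relaxation
        if stp_mode == 1:
            for i in range(N):
                Xi[i] += dt * (1.0 - Xi[i]) / tau_d
                Ui[i] += dt * (U0 - Ui[i]) / tau_f

        for k in range(P):
            weff[k] = 0.0

        # membrane update + threshold
        for i in range(N):
            if step < refr_end[i]:
                pass  # clamped at reset
            else:
                k = pop_of[i]
                tau = tau_pop[k]
                Vi = V[i]
                Vi += dt / tau * (Vi * Vi + eta[i] + ib + stim[k] + tau * syn[k])
                if Vi >= V_PEAK:
                    V[i] = V_RESET
                    pend[i] = step + delay_steps[k]
                    refr_end[i] = step + 2 * delay_steps[k]
                else:
                    V[i] = Vi

            # spike registration (independent of refractory clamp)
            if pend[i] == step:
                k = pop_of[i]
                counts[step, k] += 1
                if n_sp < max_spikes:
                    sp_t[n_sp] = t
                    sp_i[n_sp] = i
                    n_sp += 1
                if stp_mode == 1:
                    Ui[i] += U0 * (1.0 - Ui[i])
                    weff[k] += Ui[i] * Xi[i]
                    Xi[i] -= Ui[i] * Xi[i]
                pend[i] = -1

        # mesoscopic synapse jump from this step's registered activity; the
        # transmitted weight uses the facilitated utilization and the
        # pre-depression resources (same convention as the per-neuron model)
        if stp_mode == 2:
            for k in range(P):
                e = exc_of_pop[k]
                if e >= 0:
                    Nk = offsets[k + 1] - offsets[k]
                    A = counts[step, k] / Nk
                    um_new = um[e] + U0 * (1.0 - um[e]) * A
                    weff[k] = um_new * xm[e] * counts[step, k]
                    xm[e] -= um_new * xm[e] * A
                    um[e] = um_new

        # population drive for the next step
        for k in range(P):
            Nk = offsets[k + 1] - offsets[k]
            drive_raw[k] = counts[step, k] / (Nk * dt)
            if stp_mode != 0 and exc_of_pop[k] >= 0:
                drive_w[k] = weff[k] / (Nk * dt)

        # recording
        if step % rec_stride == 0:
            j = step // rec_stride
            for k in range(P):
                acc = 0.0
                m = 0
                for i in range(offsets[k], offsets[k + 1]):
                    if step >= refr_end[i]:
                        acc += V[i]
                        m += 1
                rec_v[j, k] = acc / m if m > 0 else V_RESET
            if stp_mode == 2:
                for e in range(E):
                    rec_x[j, e] = xm[e]
                    rec_u[j, e] = um[e]
            elif stp_mode == 1:
                for k in range(P):
                    e = exc_of_pop[k]
                    if e >= 0:
                        accx = 0.0
                        accu = 0.0
                        for i in range(offsets[k], offsets[k + 1]):
                            accx += Xi[i]
                            accu += Ui[i]
                        Nk = offsets[k + 1] - offsets[k]
                        rec_x[j, e] = accx / Nk
                        rec_u[j, e] = accu / Nk

    return counts, rec_v, rec_x, rec_u, sp_t[:n_sp], sp_i[:n_sp]


def simulate_network(
    pops: Sequence[PopulationParams],
    arch: Architecture,
    stp: STPParams,
    stimulus: StimulusSchedule,
    N_per_pop: int | Sequence[int],
    t_span: tuple[float, float],
    dt: float = 0.0015,
    stp_mode: str = "meso",
    seed: int = 0,
    v_init_range: tuple[float, float] = (-2.0, 0.0),
    init_synapse: tuple[float, float] | None = None,
    rate_window: float | None = None,
    record_dt: float = 0.1,
    max_spikes: int | None = None,
) -> tuple[SpikeRaster, NetworkTraces]:
    """Simulate the fully coupled multi-population QIF network.

    Parameters
    ----------
    N_per_pop : neurons per population (scalar or per-population sequence)
    stp_mode : "none", "micro" (per-neuron X_i, U_i) or "meso" (per-population x, u)
    seed : seeds the uniform initial-voltage draw (excitabilities are
        deterministic by construction)
    init_synapse : optional (x0, u0) initial synaptic state; defaults to the
        rest state (1, U0)
    rate_window : spike-count window for the rate estimate (ms); defaults to
        0.01 tau_m of the first excitatory population
    record_dt : sampling interval of the macroscopic traces (ms)

    Returns the spike raster and the macroscopic traces.
    """
    if stp_mode not in ("none", "micro", "meso"):
        raise ConfigurationError(f"unknown stp_mode {stp_mode!r}")
    P = arch.n_total
    if len(pops) != P:
        raise ConfigurationError("PopulationParams do not match architecture")
    sizes = np.full(P, N_per_pop, dtype=np.int64) if np.isscalar(N_per_pop) else np.asarray(
        N_per_pop, dtype=np.int64
    )
    if sizes.size != P:
        raise ConfigurationError("N_per_pop does not match number of populations")
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    N = int(offsets[-1])
    pop_of = np.repeat(np.arange(P), sizes)

    eta = np.empty(N)
    for k in range(P):
        eta[offsets[k] : offsets[k + 1]] = lorentzian_excitabilities(
            int(sizes[k]), pops[k].H, pops[k].Delta
        )
    tau_pop = np.array([p.tau_m for p in pops])
    delay_steps = np.maximum(1, np.round(tau_pop / 100.0 / dt)).astype(np.int64)

    rng = np.random.default_rng(seed)
    V = rng.uniform(v_init_range[0], v_init_range[1], size=N)

    x0, u0 = (1.0, stp.U0) if init_synapse is None else init_synapse
    E = arch.n_pop
    exc_of_pop = np.full(P, -1, dtype=np.int64)
    for j, k in enumerate(arch.exc_idx):
        exc_of_pop[k] = j
    Xi = np.full(N, x0)
    Ui = np.full(N, u0)
    xm = np.full(E, x0)
    um = np.full(E, u0)

    t0, t1 = float(t_span[0]), float(t_span[1])
    n_steps = int(round((t1 - t0) / dt))
    if np.isscalar(stimulus.I_B):
        IB_times = np.array([t0 - 1.0])
        IB_vals = np.array([float(stimulus.I_B)])
    else:
        IB_times = np.array([b[0] for b in stimulus.I_B]) - t0
        IB_vals = np.array([b[1] for b in stimulus.I_B])
    pulse_pop = np.array([p.population for p in stimulus.pulses], dtype=np.int64)
    pulse_amp = np.array([p.amplitude for p in stimulus.pulses])
    pulse_on = np.array([p.t_on for p in stimulus.pulses]) - t0
    pulse_off = np.array([p.t_off for p in stimulus.pulses]) - t0

    rec_stride = max(1, int(round(record_dt / dt)))
    if max_spikes is None:
        # generous bound: 200 Hz sustained average per neuron
        max_spikes = int(N * (t1 - t0) * 0.2) + 1000

    mode = {"none": 0, "micro": 1, "meso": 2}[stp_mode]
    counts, rec_v, rec_x, rec_u, sp_t, sp_i = _run_kernel(
        n_steps, dt, offsets, pop_of, tau_pop, eta, arch.J,
        arch.plastic_mask, exc_of_pop, IB_times, IB_vals,
        pulse_pop, pulse_amp, pulse_on, pulse_off,
        mode, stp.tau_d, stp.tau_f, stp.U0,
        V, Xi, Ui, xm, um, delay_steps, rec_stride, max_spikes,
    )

    raster = SpikeRaster(
        times=sp_t + t0, neurons=sp_i, populations=pop_of[sp_i]
    )
    # rate trace: causal sliding spike-count window
    W = rate_window
    if W is None:
        W = 0.01 * tau_pop[arch.exc_idx[0] if E else 0]
    w_steps = max(1, int(round(W / dt)))
    csum = np.cumsum(counts, axis=0)
    n_rec = counts.shape[0] // rec_stride + 1
    rec_idx = np.arange(n_rec) * rec_stride
    rec_idx = rec_idx[rec_idx < n_steps]
    lo = np.maximum(rec_idx - w_steps + 1, 0)
    win_counts = csum[rec_idx] - np.where(lo[:, None] > 0, csum[lo - 1], 0)
    eff_w = (rec_idx - lo + 1)[:, None] * dt
    r = (win_counts / (eff_w * sizes[None, :])).T  # (P, n_rec), 1/ms

    t_rec = t0 + rec_idx * dt
    traces = NetworkTraces(
        t=t_rec,
        r=r,
        v=rec_v[: rec_idx.size].T,
        x=rec_x[: rec_idx.size].T,
        u=rec_u[: rec_idx.size].T,
        exc_idx=arch.exc_idx,
    )
    if not np.all(np.isfinite(traces.v)):
        raise FloatingPointError("voltage trace overflowed beyond the reset guard")
    return raster, traces


def population_rate(
    raster: SpikeRaster,
    W: float,
    population: int,
    N: int,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Causal sliding-window rate estimate r(t) = N_s(W)/(W N) in 1/ms.

    Counts the spikes of ``population`` inside (t - W, t] for each grid time.
    An empty raster yields an all-zero trace.
    """
    if W <= 0:
        raise ValueError("window W must be positive")
    times = np.sort(raster.for_population(population))
    hi = np.searchsorted(times, t_grid, side="right")
    lo = np.searchsorted(times, t_grid - W, side="right")
    return (hi - lo) / (W * N)
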