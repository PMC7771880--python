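"""Working-memory experiments as reproducible recipes.

Each protocol mirrors a numerical experiment of the study: single-item
loading and reactivation, persistent activity, two-item competition and
juggling, multi-item loading in the seven-population architecture, capacity
scans over presentation rates, and the mean-membrane-potential memory-load
proxy.  Architecture presets are shipped as data files so that tests and
the command line resolve the exact same parameter sets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from synwm.neural_mass import (
    Architecture,
    ConfigurationError,
    MassState,
    PopulationParams,
    Pulse,
    STPParams,
    StimulusSchedule,
    Trajectory,
    find_equilibrium,
    integrate,
)
from synwm.spectral import BurstTrain, detect_bursts

__all__ = [
    "ModelSpec",
    "ExperimentSpec",
    "CompetitionOutcome",
    "load_preset",
    "preset_names",
    "build_stimulus",
    "quiescent_state",
    "run_protocol",
    "burst_train",
    "two_pulse_burst_counts",
    "loading_co_frequency",
    "self_sustained_frequency",
    "juggling_frequencies",
    "persistent_rate",
    "multi_item_run",
    "multi_item_period",
    "classify_competition",
    "run_competition",
    "competition_phase_diagram",
    "capacity_scan",
    "retained_items",
    "retrieval_probability",
    "memory_load_proxy",
]

#: default integration tolerances for the long protocol runs; short runs and
#: equilibrium computations use tighter settings
PROTOCOL_RTOL = 1e-8
PROTOCOL_ATOL = 1e-10


@dataclass
class ModelSpec:
    """A fully resolved model: architecture, populations, synapse constants,
    baseline stimulus and default run length (ms)."""

    name: str
    arch: Architecture
    pops: list[PopulationParams]
    stp: STPParams
    stimulus: StimulusSchedule
    t_total: float

    @property
    def I_B(self) -> float:
        return self.stimulus.background(0.0)

    def with_background(self, I_B) -> "ModelSpec":
        return replace(self, stimulus=StimulusSchedule(I_B=I_B, pulses=()))


def preset_names() -> list[str]:
    pkg = importlib.resources.files("synwm") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ModelSpec:
    """Load a named architecture preset shipped with the package."""
    pkg = importlib.resources.files("synwm") / "presets"
    path = pkg / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ConfigurationError(
            f"unknown preset {name!r}; known presets: {', '.join(preset_names())}"
        ) from None
    return parse_model_config(yaml.safe_load(text))


def parse_model_config(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from a nested key-value configuration."""
    a = cfg["architecture"]
    if a["kind"] == "single":
        arch = Architecture.single_excitatory(float(a["J"]))
    elif a["kind"] == "working_memory":
        arch = Architecture.working_memory(
            int(a["n_items"]),
            Jee_s=float(a["Jee_s"]),
            Jee_c=float(a["Jee_c"]),
            Jie=float(a["Jie"]),
            Jei=float(a["Jei"]),
            Jii=float(a["Jii"]),
        )
    else:
        raise ConfigurationError(f"unknown architecture kind {a['kind']!r}")
    pops = [
        PopulationParams(
            tau_m=float(p["tau_m"]), H=float(p["H"]), Delta=float(p["Delta"]),
            role=p.get("role", "excitatory"),
        )
        for p in cfg["populations"]
    ]
    s = cfg.get("stp", {})
    stp = STPParams(
        tau_d=float(s.get("tau_d", 200.0)),
        tau_f=float(s.get("tau_f", 1500.0)),
        U0=float(s.get("U0", 0.2)),
    )
    st = cfg.get("stimulus", {})
    I_B = st.get("I_B", 0.0)
    if isinstance(I_B, list):
        I_B = [(float(t), float(v)) for t, v in I_B]
    pulses = [
        Pulse(int(p["population"]), float(p["amplitude"]), float(p["t_on"]), float(p["t_off"]))
        for p in st.get("pulses", [])
    ]
    stim = StimulusSchedule(I_B=I_B, pulses=pulses)
    return ModelSpec(
        name=cfg.get("name", "custom"),
        arch=arch,
        pops=pops,
        stp=stp,
        stimulus=stim,
        t_total=float(cfg.get("t_total", 1000.0)),
    )


@dataclass
class ExperimentSpec:
    """A stimulation recipe on top of an architecture preset.

    ``protocol`` selects a named stimulation protocol with its exact published
    pulse sequence; explicit ``pulses`` may be given instead (or in
    addition).
    """

    preset: str = "two_item"
    I_B: float | Sequence[tuple[float, float]] | None = None
    protocol: str | None = None
    pulses: list[Pulse] = field(default_factory=list)


def build_stimulus(spec: ExperimentSpec) -> StimulusSchedule:
    """Resolve an ExperimentSpec into a piecewise-constant schedule.

    Named protocols (times in ms, item loading always starts at t = 0):

    - ``two_pulse``: two pulses of amplitude 2, 150 ms wide, 150 ms apart
      (I_B = -1)
    - ``load_item``: one step of amplitude 0.2 for 350 ms to population 1
    - ``readout``: weak non-specific step (amplitude 0.1, 250 ms) to all
      excitatory populations, 1.2 s after the loading offset
    - ``refresh_train``: loading step plus a train of non-specific pulses of
      amplitude 0.1 and 150 ms duration every 400 ms to both populations
    """
    model = load_preset(spec.preset)
    I_B = model.stimulus.I_B if spec.I_B is None else spec.I_B
    pulses = list(spec.pulses)
    n_exc = model.arch.n_pop
    exc = [int(k) for k in model.arch.exc_idx]

    if spec.protocol is None:
        pass
    elif spec.protocol == "two_pulse":
        pulses += [Pulse(0, 2.0, 300.0, 450.0), Pulse(0, 2.0, 600.0, 750.0)]
    elif spec.protocol == "load_item":
        pulses += [Pulse(exc[0], 0.2, 0.0, 350.0)]
    elif spec.protocol == "readout":
        t0 = 350.0 + 1200.0
        pulses += [Pulse(k, 0.1, t0, t0 + 250.0) for k in exc]
    elif spec.protocol == "refresh_train":
        pulses += [Pulse(exc[0], 0.2, 0.0, 350.0)]
        for j in range(6):
            t0 = 750.0 + 400.0 * j
            pulses += [Pulse(k, 0.1, t0, t0 + 150.0) for k in exc]
    else:
        raise ConfigurationError(f"unknown protocol {spec.protocol!r}")
    return StimulusSchedule(I_B=I_B, pulses=pulses)


def quiescent_state(
    model: ModelSpec,
    I_B: float | None = None,
    t_settle: float = 4000.0,
    rtol: float = 1e-10,
) -> MassState:
    """Symmetric low-activity state at background drive.

    All experiments start from the state in which every excitatory
    population shows the same spontaneous low firing.  Where this state has
    lost stability to symmetry breaking it still exists as an equilibrium of
    the symmetric subspace, so it is found by root-solving the fixed-point
    system restricted to identical excitatory populations (seeded by a short
    settle from rest at a current where the state is attracting).
    """
    from scipy.optimize import root as _root

    from synwm.neural_mass import _equilibrium_closure

    I = model.I_B if I_B is None else I_B
    arch, pops, stp = model.arch, model.pops, model.stp

    # seed: settle from rest (symmetric by construction) for a short time
    stim0 = StimulusSchedule(I_B=I)
    init = MassState.rest(arch, stp)
    tr = integrate(
        arch, pops, stp, stim0, (0.0, min(t_settle, 2000.0)), init,
        rtol=rtol, atol=rtol, dt_out=1.0,
    )
    seed = tr.final_state()
    if arch.n_total == 1:
        return find_equilibrium(arch, pops, stp, I, guess=seed).state

    expand, residual = _equilibrium_closure(arch, pops, stp, I)
    exc = arch.exc_idx
    r0 = np.array([seed.r[0], np.mean(seed.r[exc])])

    def res2(z):
        r = np.empty(arch.n_total)
        r[0] = np.exp(z[0])
        r[exc] = np.exp(z[1])
        q = residual(r)
        return [q[0], float(np.mean(q[exc]))]

    with np.errstate(all="ignore"):
        sol = _root(res2, np.log(np.maximum(r0, 1e-10)), method="hybr", tol=1e-13)
    r = np.empty(arch.n_total)
    r[0] = np.exp(sol.x[0])
    r[exc] = np.exp(sol.x[1])
    if np.max(np.abs(residual(r))) > 1e-8:
        # no symmetric root found; fall back to the settled state
        return seed
    return expand(r)


def run_protocol(
    model: ModelSpec,
    stimulus: StimulusSchedule,
    t_span: tuple[float, float],
    init: MassState,
    rtol: float = PROTOCOL_RTOL,
    atol: float = PROTOCOL_ATOL,
    dt_out: float = 0.5,
) -> Trajectory:
    return integrate(
        model.arch, model.pops, model.stp, stimulus, t_span, init,
        rtol=rtol, atol=atol, dt_out=dt_out,
    )


def burst_train(
    traj: Trajectory,
    population: int,
    baseline_hz: float,
    threshold_factor: float = 5.0,
    min_separation: float = 20.0,
) -> BurstTrain:
    return detect_bursts(
        traj.r_hz[population], traj.t, baseline=baseline_hz,
        threshold_factor=threshold_factor, min_separation=min_separation,
    )


# ---------------------------------------------------------------------------
# single-population protocol (two-pulse loading)

def two_pulse_burst_counts(
    rtol: float = 1e-10, return_traj: bool = False
):
    """Two-pulse protocol on the single-population preset: burst count per pulse.

    Starts at the m-STP equilibrium; each 150 ms pulse of amplitude 2
    triggers a short series of population bursts of decreasing amplitude.
    """
    model = load_preset("single_pop")
    eq = find_equilibrium(
        model.arch, model.pops, model.stp, I_B=model.I_B,
        guess=MassState(r=[0.003], v=[-0.8], x=[0.7], u=[0.6]),
    )
    traj = run_protocol(
        model, model.stimulus, (0.0, model.t_total), eq.state,
        rtol=rtol, atol=rtol, dt_out=0.1,
    )
    base = eq.state.r[0] * 1e3
    bt = burst_train(traj, 0, base)
    windows = [(p.t_on, p.t_on + 300.0) for p in model.stimulus.pulses]
    counts = [bt.restrict(a, b).times.size for a, b in windows]
    return (counts, traj) if return_traj else counts


# ---------------------------------------------------------------------------
# two-item protocol regimes

def loading_co_frequency(I_B: float = 1.2) -> float:
    """Frequency (Hz) of the collective oscillations emitted while an item
    is loaded: burst repetition rate of population one during the 350 ms
    stimulation step.

    The bursts arise from damped oscillations towards a focus, sustained by
    the inhibitory pool (PING-like); at I_B = 1.2 they lie in the beta band.
    """
    model = load_preset("two_item")
    st = quiescent_state(model, I_B=I_B)
    stim = build_stimulus(ExperimentSpec(protocol="load_item", I_B=I_B))
    traj = run_protocol(model, stim, (0.0, 500.0), st, rtol=1e-10, atol=1e-12, dt_out=0.1)
    base = st.r[1] * 1e3
    bt = burst_train(traj, 1, base, threshold_factor=2.0)
    # the stimulus-triggered oscillation does not halt at the pulse offset:
    # include the series up to its first burst past the offset
    t_off = 350.0
    after = bt.times[bt.times >= t_off]
    t_end = after[0] + 1.0 if after.size else t_off
    return bt.restrict(0.0, t_end).rate_hz


def self_sustained_frequency(
    I_B: float = 1.532, window: float = 3000.0, return_state: bool = False
):
    """Population-burst repetition frequency (Hz) of a single loaded item.

    After loading (0.2 for 350 ms) at a background current supporting
    self-sustained reactivation, the target population emits periodic bursts
    paced by the depression recovery; the frequency is the inverse mean
    inter-burst interval over ``window`` ms from the stimulation offset.
    """
    model = load_preset("two_item")
    st = quiescent_state(model, I_B=I_B)
    stim = build_stimulus(ExperimentSpec(protocol="load_item", I_B=I_B))
    traj = run_protocol(model, stim, (0.0, 350.0 + window + 100.0), st)
    base = st.r[1] * 1e3
    bt = burst_train(traj, 1, base, threshold_factor=2.0, min_separation=100.0)
    f = bt.restrict(350.0, 350.0 + window).rate_hz
    if return_state:
        return f, traj.final_state()
    return f


def juggling_frequencies(
    I_B: float = 1.532,
    t_second: float = 2650.0,
    window: float = 3000.0,
) -> tuple[float, float]:
    """Per-item reactivation frequencies (Hz) with two retained items.

    Loads item one at t = 0 and item two at ``t_second``; after the second
    loading the populations burst alternately (anti-phase juggling).  Each
    population's burst repetition rate over ``window`` ms from the second
    stimulation offset is returned.
    """
    model = load_preset("two_item")
    st = quiescent_state(model, I_B=I_B)
    stim = StimulusSchedule(
        I_B=I_B,
        pulses=[
            Pulse(1, 0.2, 0.0, 350.0),
            Pulse(2, 0.2, t_second, t_second + 350.0),
        ],
    )
    t_end = t_second + 350.0 + window + 200.0
    traj = run_protocol(model, stim, (0.0, t_end), st)
    base = st.r[1] * 1e3
    out = []
    for k in (1, 2):
        bt = burst_train(traj, k, base, threshold_factor=2.0, min_separation=100.0)
        out.append(bt.restrict(t_second + 350.0, t_second + 350.0 + window).rate_hz)
    return tuple(out)


def persistent_rate(I_B: float = 2.0, t_relax: float = 3000.0) -> float:
    """Stationary firing rate (Hz) of the target population in the
    persistent-activity regime: load one item, let the transient decay and
    report the final rate of the persistently active population."""
    model = load_preset("two_item")
    st = quiescent_state(model, I_B=I_B)
    stim = build_stimulus(ExperimentSpec(protocol="load_item", I_B=I_B))
    traj = run_protocol(model, stim, (0.0, 350.0 + t_relax), st)
    return float(traj.r_hz[1:, -1].max())


# ---------------------------------------------------------------------------
# two-item competition

@dataclass(frozen=True)
class CompetitionOutcome:
    """Final memory state after two-item competition.

    ``P`` is the rate-dominance indicator <r1>/(<r1>+<r2>); item one wins for
    P > 0.7, item two for P < 0.3, and the items juggle in between.
    """

    label: str
    P: float

    @classmethod
    def from_P(cls, P: float) -> "CompetitionOutcome":
        if P > 0.7:
            return cls("item1", P)
        if P < 0.3:
            return cls("item2", P)
        return cls("juggling", P)


def classify_competition(traj: Trajectory, t_second_stim_end: float) -> CompetitionOutcome:
    """Classify the outcome three seconds after the second stimulation by the
    rates averaged over one further second."""
    t0 = t_second_stim_end + 3000.0
    t1 = t0 + 1000.0
    if traj.t[-1] < t1:
        raise ConfigurationError(
            f"trajectory ends at {traj.t[-1]:.0f} ms; classification needs "
            f"coverage up to {t1:.0f} ms"
        )
    sel = (traj.t >= t0) & (traj.t < t1)
    m1 = float(traj.r[1, sel].mean())
    m2 = float(traj.r[2, sel].mean())
    P = 1.0 if m1 + m2 == 0 else m1 / (m1 + m2)
    return CompetitionOutcome.from_P(P)


def run_competition(
    amp2: float,
    dur2: float,
    I_B: float = 1.532,
    t_second: float = 1500.0,
    persistent_start: bool = False,
) -> CompetitionOutcome:
    """One competition experiment: item one loaded at t = 0 (0.2 / 350 ms),
    item two stimulated at ``t_second`` with (``amp2``, ``dur2`` ms).

    With ``persistent_start`` the first item is loaded into the persistent
    state before the distractor arrives (the I_B = 2 operating mode).
    """
    model = load_preset("two_item")
    st = quiescent_state(model, I_B=I_B)
    pulses = [Pulse(1, 0.2, 0.0, 350.0)]
    if amp2 > 0 and dur2 > 0:
        pulses.append(Pulse(2, amp2, t_second, t_second + dur2))
    stim = StimulusSchedule(I_B=I_B, pulses=pulses)
    t_end = t_second + dur2 + 4100.0
    traj = run_protocol(model, stim, (0.0, t_end), st)
    return classify_competition(traj, t_second + dur2)


def competition_phase_diagram(
    amps: Sequence[float],
    durs: Sequence[float],
    n_phases: int = 5,
    I_B: float = 1.532,
    t_equilibrate: float = 4000.0,
) -> dict:
    """Outcome fractions over a (amplitude, duration) grid of second stimuli.

    The second stimulus is delivered at ``n_phases`` equidistant phases of
    the established item-one oscillation cycle, starting from an
    equilibrated cycle ``t_equilibrate`` ms after loading; each cell reports
    the fraction of phases yielding each outcome.  Grid resolutions default
    to desk scale; the published diagrams use 80 x 150 x 20.
    """
    model = load_preset("two_item")
    st = quiescent_state(model, I_B=I_B)
    stim1 = StimulusSchedule(I_B=I_B, pulses=[Pulse(1, 0.2, 0.0, 350.0)])
    base_run = run_protocol(model, stim1, (0.0, t_equilibrate), st)
    base = st.r[1] * 1e3
    bt = burst_train(base_run, 1, base, threshold_factor=2.0, min_separation=100.0)
    late = bt.restrict(t_equilibrate - 1500.0, t_equilibrate)
    if late.times.size >= 2:
        T_cycle = float(late.intervals.mean())
        t_ref = float(late.times[-1])
    else:  # persistent regime: no cycle, phase is irrelevant
        T_cycle = 0.0
        t_ref = t_equilibrate - 100.0
    state0 = base_run.final_state()
    t0 = base_run.t[-1]

    results = {}
    phases = np.arange(n_phases) / n_phases
    for amp in amps:
        for dur in durs:
            labels = []
            for ph in phases:
                t_on = t_ref + ph * T_cycle
                while t_on <= t0:
                    t_on += max(T_cycle, 1.0)
                pulses = [Pulse(2, amp, t_on, t_on + dur)] if amp > 0 and dur > 0 else []
                stim = StimulusSchedule(I_B=I_B, pulses=pulses)
                t_end = t_on + dur + 4100.0
                traj = run_protocol(model, stim, (t0, t_end), state0)
                labels.append(classify_competition(traj, t_on + dur).label)
                if T_cycle == 0.0:
                    break  # no phase to vary
            frac = {
                lab: labels.count(lab) / len(labels)
                for lab in ("item1", "item2", "juggling")
            }
            results[(amp, dur)] = frac
    return results


# ---------------------------------------------------------------------------
# multi-item loading, capacity and memory load

def multi_item_run(
    n_load: int,
    amplitude: float = 1.0,
    width: float = 200.0,
    interval: float = 1250.0,
    t_after: float = 6000.0,
    t_settle: float = 3000.0,
    rtol: float = PROTOCOL_RTOL,
) -> tuple[Trajectory, MassState]:
    """Load ``n_load`` items sequentially into the seven-item architecture.

    Item k receives a pulse of ``amplitude`` and ``width`` ms starting at
    (k-1) * ``interval``; the run extends ``t_after`` ms past the last pulse.
    Returns the trajectory (from the first pulse onward) and the quiescent
    pre-stimulus state.
    """
    model = load_preset("multi_item")
    if n_load > model.arch.n_pop:
        raise ConfigurationError(
            f"cannot load {n_load} items into {model.arch.n_pop} populations"
        )
    st = quiescent_state(model, t_settle=t_settle)
    pulses = [
        Pulse(k + 1, amplitude, k * interval, k * interval + width)
        for k in range(n_load)
    ]
    t_end = (n_load - 1) * interval + width + t_after
    traj = run_protocol(
        model, StimulusSchedule(I_B=model.I_B, pulses=pulses),
        (0.0, t_end), st, rtol=rtol,
    )
    return traj, st


def multi_item_period(
    n_load: int = 3,
    traj: Trajectory | None = None,
    quiescent: MassState | None = None,
    t_measure: float = 4000.0,
) -> float:
    """Mean interval T_c (ms) between successive bursts of one population
    after ``n_load`` items are retained; measured over the last
    ``t_measure`` ms, averaged over the loaded populations."""
    if traj is None:
        traj, quiescent = multi_item_run(n_load)
    base = quiescent.r[1] * 1e3
    t1 = traj.t[-1]
    periods = []
    for k in range(1, n_load + 1):
        bt = burst_train(traj, k, base, threshold_factor=5.0, min_separation=50.0)
        late = bt.restrict(t1 - t_measure, t1)
        if late.times.size >= 2:
            periods.append(float(late.intervals.mean()))
    if not periods:
        raise ConfigurationError("no retained bursts found")
    return float(np.mean(periods))


def retained_items(
    traj: Trajectory,
    baseline_hz: float,
    t_last_stim: float,
    n_pop: int = 7,
) -> list[int]:
    """Items still delivering population bursts 20 s after the last
    stimulation: at least one detected burst inside
    [t_last + 19 s, t_last + 21 s]."""
    kept = []
    for k in range(1, n_pop + 1):
        bt = burst_train(traj, k, baseline_hz, threshold_factor=5.0, min_separation=50.0)
        w = bt.restrict(t_last_stim + 19000.0, t_last_stim + 21000.0)
        if w.times.size >= 1:
            kept.append(k)
    return kept


def capacity_scan(
    f_pres: Sequence[float],
    amplitude: float = 16.0,
    n_items: int = 7,
    rtol: float = PROTOCOL_RTOL,
) -> dict:
    """Scan presentation rates: all seven items are presented back-to-back,
    each pulse lasting 1/f_pres, and the retained set is read out 20 s after
    the last stimulation.

    Returns {rate: {"retained": [...], "N_I": count}}.
    """
    model = load_preset("multi_item")
    st = quiescent_state(model)
    out = {}
    for f in f_pres:
        if f <= 0:
            raise ConfigurationError("presentation rate must be positive")
        width = 1e3 / f
        pulses = [
            Pulse(k + 1, amplitude, k * width, (k + 1) * width)
            for k in range(n_items)
        ]
        t_last = n_items * width
        traj = run_protocol(
            model, StimulusSchedule(I_B=model.I_B, pulses=pulses),
            (0.0, t_last + 21500.0), st, rtol=rtol, dt_out=1.0,
        )
        kept = retained_items(traj, st.r[1] * 1e3, t_last, n_pop=model.arch.n_pop)
        out[f] = {"retained": kept, "N_I": len(kept)}
    return out


def retrieval_probability(scan: dict, n_items: int = 7) -> np.ndarray:
    """Per-serial-position retrieval probability aggregated over a rate scan.

    Position ``k`` (1-based presentation order) gets the fraction of scanned
    rates at which item ``k`` was retained.  Summing the probabilities over
    positions recovers the mean retained count across the scan (bookkeeping
    identity used in the tests).
    """
    if not scan:
        raise ConfigurationError("empty capacity scan")
    probs = np.zeros(n_items)
    for res in scan.values():
        for k in res["retained"]:
            probs[k - 1] += 1
    return probs / len(scan)


def memory_load_proxy(
    traj: Trajectory,
    coding: Sequence[int],
    trigger: int = 1,
    baseline_hz: float = 1.0,
    window: tuple[float, float] = (-50.0, 150.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Membrane-potential memory-load proxy Delta-v aligned to a burst.

    Delta-v(t - t*) is the difference between the mean membrane potential
    averaged over the item-coding populations and the average over the
    non-coding populations, aligned to the last detected population burst
    t* of the ``trigger`` population.  Returns (lag array ms, Delta-v).
    """
    exc = [int(k) for k in traj.exc_idx]
    non_coding = [k for k in exc if k not in coding]
    if not non_coding:
        raise ConfigurationError("need at least one non-coding population")
    bt = detect_bursts(
        traj.r_hz[trigger], traj.t, baseline=baseline_hz,
        threshold_factor=5.0, min_separation=50.0,
    )
    usable = bt.times[
        (bt.times + window[0] >= traj.t[0]) & (bt.times + window[1] <= traj.t[-1])
    ]
    if usable.size == 0:
        raise ConfigurationError(f"no population burst found in population {trigger}")
    t_star = float(usable[-1])
    sel = (traj.t >= t_star + window[0]) & (traj.t <= t_star + window[1])
    dv = traj.v[coding][:, sel].mean(axis=0) - traj.v[non_coding][:, sel].mean(axis=0)
    return traj.t[sel] - t_star, dv
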