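"""Exact mean-field (neural mass) model for QIF populations with short-term plasticity.

The model describes ``n_pop`` excitatory populations plus (optionally) one
inhibitory pool of heterogeneous quadratic integrate-and-fire neurons.  For
Lorentzian-distributed excitabilities the infinite-size network dynamics
closes exactly on two macroscopic variables per population -- the firing rate
``r_k`` and the mean membrane potential ``v_k`` -- via the Ott-Antonsen
reduction.  Excitatory-to-excitatory synapses carry mesoscopic
Tsodyks-Markram depression/facilitation variables ``(x_l, u_l)`` which
multiply the bare coupling, ``J~_kl = J_kl u_l x_l``.

Units: time in ms, rates in 1/ms (multiply by 1e3 for Hz), currents and
voltages dimensionless.  With these conventions the equations are
dimensionally consistent as written:

    tau_k dr_k/dt = Delta_k/(tau_k pi) + 2 r_k v_k
    tau_k dv_k/dt = v_k^2 + H_k + I_B + I_S^(k)(t) - (pi tau_k r_k)^2
                    + tau_k sum_l J~_kl r_l
    dx_l/dt = (1 - x_l)/tau_d - u_l x_l r_l
    du_l/dt = (U0 - u_l)/tau_f + U0 (1 - u_l) r_l
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "PopulationParams",
    "STPParams",
    "Architecture",
    "MassState",
    "Pulse",
    "StimulusSchedule",
    "Trajectory",
    "Equilibrium",
    "ConfigurationError",
    "NumericalError",
    "mass_rhs",
    "integrate",
    "find_equilibrium",
    "normalized_synapse",
    "jacobian",
]

EXC = "excitatory"
INH = "inhibitory"


class ConfigurationError(ValueError):
    """Inconsistent architecture / parameter / state dimensions."""


class NumericalError(RuntimeError):
    """Non-finite state or integrator failure."""


@dataclass(frozen=True)
class PopulationParams:
    """Constants of one QIF population.

    tau_m : membrane time constant (ms)
    H     : median excitability of the Lorentzian distribution
    Delta : half-width at half-maximum of the excitability distribution
    role  : "excitatory" or "inhibitory"
    """

    tau_m: float
    H: float
    Delta: float
    role: str = EXC

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ConfigurationError(f"tau_m must be positive, got {self.tau_m}")
        if self.Delta <= 0:
            raise ConfigurationError(f"Delta must be positive, got {self.Delta}")
        if self.role not in (EXC, INH):
            raise ConfigurationError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class STPParams:
    """Tsodyks-Markram synapse constants.

    tau_d : depression recovery time (ms)
    tau_f : facilitation decay time (ms); facilitation must outlast depression
    U0    : baseline utilization factor, in (0, 1)
    """

    tau_d: float = 200.0
    tau_f: float = 1500.0
    U0: float = 0.2

    def __post_init__(self):
        if not (self.tau_f > self.tau_d > 0):
            raise ConfigurationError(
                f"require tau_f > tau_d > 0, got tau_f={self.tau_f}, tau_d={self.tau_d}"
            )
        if not (0 < self.U0 < 1):
            raise ConfigurationError(f"U0 must lie in (0,1), got {self.U0}")


class Architecture:
    """Coupling matrix of the multi-population network.

    ``J[k, l]`` couples pre-synaptic population ``l`` into post-synaptic
    population ``k`` (target-index-first).  Entries are plastic exactly where
    both indices are excitatory; there the effective coupling is
    ``J[k, l] * u_l * x_l``.
    """

    def __init__(self, J: np.ndarray, roles: Sequence[str], plastic: bool = True):
        J = np.asarray(J, dtype=float)
        roles = list(roles)
        if J.ndim != 2 or J.shape[0] != J.shape[1] or J.shape[0] != len(roles):
            raise ConfigurationError(
                f"J must be square with one row per population, got {J.shape} "
                f"for {len(roles)} populations"
            )
        for r in roles:
            if r not in (EXC, INH):
                raise ConfigurationError(f"unknown role {r!r}")
        exc = np.array([r == EXC for r in roles])
        # sign convention is fixed by the pre-synaptic population
        for l in range(len(roles)):
            col = J[:, l]
            if exc[l] and np.any(col < 0):
                raise ConfigurationError(f"excitatory column {l} has negative entries")
            if not exc[l] and np.any(col > 0):
                raise ConfigurationError(f"inhibitory column {l} has positive entries")
        self.J = J
        self.roles = roles
        self.exc_mask = exc
        self.exc_idx = np.flatnonzero(exc)
        # excitatory-to-excitatory synapses carry STP; ``plastic=False`` gives
        # the plasticity-free network with fixed couplings
        self.plastic_mask = np.outer(exc, exc) if plastic else np.zeros_like(np.outer(exc, exc))

    @property
    def n_total(self) -> int:
        return len(self.roles)

    @property
    def n_pop(self) -> int:
        """Number of excitatory (item-coding) populations."""
        return int(self.exc_mask.sum())

    @classmethod
    def single_excitatory(cls, J: float) -> "Architecture":
        """One self-coupled excitatory population (no inhibitory pool)."""
        return cls(np.array([[J]]), [EXC])

    @classmethod
    def working_memory(
        cls,
        n_items: int,
        Jee_s: float,
        Jee_c: float,
        Jie: float,
        Jei: float,
        Jii: float,
    ) -> "Architecture":
        """``n_items`` identical excitatory populations plus one inhibitory pool.

        Population 0 is inhibitory.  Self couplings within an item population
        (``Jee_s``) exceed cross couplings between items (``Jee_c``) so that
        each population codes selectively for one memory item.
        """
        if n_items < 1:
            raise ConfigurationError("need at least one excitatory population")
        if not Jee_s > Jee_c:
            raise ConfigurationError(
                f"within-item coupling must exceed cross coupling, "
                f"got Jee_s={Jee_s}, Jee_c={Jee_c}"
            )
        n = n_items + 1
        J = np.full((n, n), Jee_c)
        J[np.arange(1, n), np.arange(1, n)] = Jee_s
        J[0, 0] = Jii
        J[0, 1:] = Jie
        J[1:, 0] = Jei
        return cls(J, [INH] + [EXC] * n_items)


@dataclass
class MassState:
    """Mean-field state: rates and mean voltages for every population,
    synaptic resources/utilization for excitatory populations only."""

    r: np.ndarray  # (n_total,), 1/ms
    v: np.ndarray  # (n_total,)
    x: np.ndarray  # (n_exc,)
    u: np.ndarray  # (n_exc,)

    def __post_init__(self):
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.r, self.v, self.x, self.u])

    @classmethod
    def unpack(cls, y: np.ndarray, n_total: int, n_exc: int) -> "MassState":
        if y.size != 2 * n_total + 2 * n_exc:
            raise ConfigurationError(
                f"state vector of size {y.size} does not match "
                f"{n_total} populations / {n_exc} plastic populations"
            )
        r = y[:n_total]
        v = y[n_total : 2 * n_total]
        x = y[2 * n_total : 2 * n_total + n_exc]
        u = y[2 * n_total + n_exc :]
        return cls(r=r, v=v, x=x, u=u)

    @classmethod
    def rest(cls, arch: Architecture, stp: STPParams) -> "MassState":
        """Low-activity guess: small positive rate, synapses at rest."""
        n, e = arch.n_total, arch.n_pop
        return cls(
            r=np.full(n, 1e-4),
            v=np.full(n, -1.0),
            x=np.ones(e),
            u=np.full(e, stp.U0),
        )


@dataclass(frozen=True)
class Pulse:
    """Rectangular stimulus step to one excitatory population."""

    population: int
    amplitude: float
    t_on: float
    t_off: float

    def __post_init__(self):
        if not self.t_off > self.t_on:
            raise ConfigurationError(
                f"pulse must have t_off > t_on, got [{self.t_on}, {self.t_off}]"
            )


@dataclass
class StimulusSchedule:
    """Background current common to all populations plus per-population pulses.

    ``I_B`` is either a constant or a sorted list of ``(t_from, value)`` pairs
    (piecewise constant, first entry active from the start of the run).
    """

    I_B: float | Sequence[tuple[float, float]] = 0.0
    pulses: Sequence[Pulse] = field(default_factory=tuple)

    def background(self, t: float) -> float:
        if np.isscalar(self.I_B):
            return float(self.I_B)
        value = self.I_B[0][1]
        for t_from, v in self.I_B:
            if t >= t_from:
                value = v
        return float(value)

    def stimulus(self, t: float, n_total: int) -> np.ndarray:
        """Per-population stimulus current I_S^(k)(t) (background excluded)."""
        I = np.zeros(n_total)
        for p in self.pulses:
            if p.t_on <= t < p.t_off:
                I[p.population] += p.amplitude
        return I

    def breakpoints(self) -> np.ndarray:
        """Times where the drive is discontinuous (integrator restart points)."""
        ts = set()
        for p in self.pulses:
            ts.add(p.t_on)
            ts.add(p.t_off)
        if not np.isscalar(self.I_B):
            for t_from, _ in self.I_B:
                ts.add(t_from)
        return np.array(sorted(ts))


def _effective_J(arch: Architecture, x: np.ndarray, u: np.ndarray) -> np.ndarray:
    ux = np.ones(arch.n_total)
    ux[arch.exc_idx] = u * x
    Jeff = np.where(arch.plastic_mask, arch.J * ux[None, :], arch.J)
    return Jeff


def mass_rhs(
    state: MassState,
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    stimulus: StimulusSchedule,
    t: float,
) -> MassState:
    """Time derivative of the mean-field state at time ``t`` (ms)."""
    n, e = arch.n_total, arch.n_pop
    if len(pops) != n:
        raise ConfigurationError(
            f"{len(pops)} PopulationParams for {n}-population architecture"
        )
    if state.r.size != n or state.v.size != n or state.x.size != e or state.u.size != e:
        raise ConfigurationError(
            f"state dimensions (r={state.r.size}, v={state.v.size}, "
            f"x={state.x.size}, u={state.u.size}) do not match architecture "
            f"({n} populations, {e} excitatory)"
        )
    for name, arr in (("r", state.r), ("v", state.v), ("x", state.x), ("u", state.u)):
        if not np.all(np.isfinite(arr)):
            bad = np.flatnonzero(~np.isfinite(arr))
            raise NumericalError(f"non-finite state component {name}[{bad.tolist()}]")

    tau = np.array([p.tau_m for p in pops])
    H = np.array([p.H for p in pops])
    Delta = np.array([p.Delta for p in pops])
    r, v, x, u = state.r, state.v, state.x, state.u

    Jeff = _effective_J(arch, x, u)
    I = H + stimulus.background(t) + stimulus.stimulus(t, n)
    dr = (Delta / (tau * np.pi) + 2.0 * r * v) / tau
    dv = (v**2 + I - (np.pi * tau * r) ** 2 + tau * (Jeff @ r)) / tau

    r_e = r[arch.exc_idx]
    dx = (1.0 - x) / stp.tau_d - u * x * r_e
    du = (stp.U0 - u) / stp.tau_f + stp.U0 * (1.0 - u) * r_e
    return MassState(r=dr, v=dv, x=dx, u=du)


def _rhs_flat(arch, pops, stp, stimulus, freeze_stp=False):
    n, e = arch.n_total, arch.n_pop
    tau = np.array([p.tau_m for p in pops])
    H = np.array([p.H for p in pops])
    Delta = np.array([p.Delta for p in pops])
    exc_idx = arch.exc_idx
    J = arch.J
    plastic = arch.plastic_mask

    def f(t, y):
        r = y[:n]
        v = y[n : 2 * n]
        x = y[2 * n : 2 * n + e]
        u = y[2 * n + e :]
        ux = np.ones(n)
        ux[exc_idx] = u * x
        Jeff = np.where(plastic, J * ux[None, :], J)
        I = H + stimulus.background(t) + stimulus.stimulus(t, n)
        dr = (Delta / (tau * np.pi) + 2.0 * r * v) / tau
        dv = (v**2 + I - (np.pi * tau * r) ** 2 + tau * (Jeff @ r)) / tau
        if freeze_stp:
            dx = np.zeros_like(x)
            du = np.zeros_like(u)
        else:
            r_e = r[exc_idx]
            dx = (1.0 - x) / stp.tau_d - u * x * r_e
            du = (stp.U0 - u) / stp.tau_f + stp.U0 * (1.0 - u) * r_e
        return np.concatenate([dr, dv, dx, du])

    return f


@dataclass
class Trajectory:
    """Sampled mean-field trajectory.  Times in ms, rates in 1/ms."""

    t: np.ndarray
    r: np.ndarray  # (n_total, n_t)
    v: np.ndarray
    x: np.ndarray  # (n_exc, n_t)
    u: np.ndarray
    exc_idx: np.ndarray

    @property
    def t_s(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t * 1e-3

    @property
    def r_hz(self) -> np.ndarray:
        """Firing rates in Hz."""
        return self.r * 1e3

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def state_at(self, i: int) -> MassState:
        return MassState(r=self.r[:, i], v=self.v[:, i], x=self.x[:, i], u=self.u[:, i])

    def final_state(self) -> MassState:
        return self.state_at(-1)

    def mean_exc_v(self) -> np.ndarray:
        """Mean membrane potential averaged over excitatory populations."""
        return self.v[self.exc_idx].mean(axis=0)

    def to_frame(self):
        """Tabular view, one column per state variable (rates in Hz)."""
        import pandas as pd

        data = {"t_ms": self.t}
        for k in range(self.r.shape[0]):
            data[f"r_{k}"] = self.r[k] * 1e3
            data[f"v_{k}"] = self.v[k]
        for j, k in enumerate(self.exc_idx):
            data[f"x_{k}"] = self.x[j]
            data[f"u_{k}"] = self.u[j]
        return pd.DataFrame(data)


def integrate(
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    stimulus: StimulusSchedule,
    t_span: tuple[float, float],
    init: MassState,
    rtol: float = 1e-12,
    atol: float = 1e-12,
    dt_out: float = 0.1,
    freeze_stp: bool = False,
) -> Trajectory:
    """Integrate the mass model with the adaptive Dormand-Prince scheme.

    The run is split at stimulus discontinuities so the adaptive stepper
    never straddles a current jump.  Output is sampled every ``dt_out`` ms.
    ``freeze_stp`` clamps the synaptic variables at their initial values
    (the frozen-synapse limit of infinitely slow plasticity).
    """
    n, e = arch.n_total, arch.n_pop
    y0 = init.pack()
    if y0.size != 2 * n + 2 * e:
        raise ConfigurationError("initial state does not match architecture")
    f = _rhs_flat(arch, pops, stp, stimulus, freeze_stp=freeze_stp)

    t0, t1 = float(t_span[0]), float(t_span[1])
    t_eval = np.arange(t0, t1 + 0.5 * dt_out, dt_out)
    cuts = [t for t in stimulus.breakpoints() if t0 < t < t1]
    edges = [t0] + cuts + [t1]

    ts, ys = [], []
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        last = b == edges[-1]
        mask = (t_eval >= a) & ((t_eval <= b) if last else (t_eval < b))
        seg_eval = np.unique(np.concatenate([t_eval[mask], [b]]))
        sol = solve_ivp(
            f, (a, b), y, method="RK45", rtol=rtol, atol=atol, t_eval=seg_eval
        )
        if not sol.success:
            raise NumericalError(
                f"integration failed at t={sol.t[-1]:.6g} ms: {sol.message}"
            )
        y = sol.y[:, -1]
        keep = np.isin(sol.t, t_eval[mask])
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    return Trajectory(
        t=t_all,
        r=y_all[:n],
        v=y_all[n : 2 * n],
        x=y_all[2 * n : 2 * n + e],
        u=y_all[2 * n + e :],
        exc_idx=arch.exc_idx,
    )


@dataclass
class Equilibrium:
    """Fixed point of the mass model together with its Jacobian spectrum."""

    state: MassState
    eigenvalues: np.ndarray
    residual: float

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigenvalues.real) < 0)

    @property
    def kind(self) -> str:
        """'focus' if the leading eigenvalues are a complex pair, else 'node'."""
        lead = self.eigenvalues[np.argmax(self.eigenvalues.real)]
        return "focus" if abs(lead.imag) > 1e-10 else "node"


def _equilibrium_closure(arch, pops, stp, I_B):
    """Reduce the fixed-point system to the rates alone.

    At a fixed point with r_k > 0 the rate equation gives
    v_k = -Delta_k / (2 pi tau_k r_k) and the synaptic equations give
    u_l, x_l in closed form, leaving one residual per population from the
    voltage equation.
    """
    n = arch.n_total
    tau = np.array([p.tau_m for p in pops])
    H = np.array([p.H for p in pops])
    Delta = np.array([p.Delta for p in pops])

    def expand(r):
        v = -Delta / (2.0 * np.pi * tau * r)
        r_e = r[arch.exc_idx]
        u = stp.U0 * (1.0 + stp.tau_f * r_e) / (1.0 + stp.U0 * stp.tau_f * r_e)
        x = 1.0 / (1.0 + u * r_e * stp.tau_d)
        return MassState(r=r, v=v, x=x, u=u)

    def residual(r):
        st = expand(r)
        Jeff = _effective_J(arch, st.x, st.u)
        return st.v**2 + H + I_B - (np.pi * tau * r) ** 2 + tau * (Jeff @ r)

    return expand, residual


def find_equilibrium(
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    I_B: float,
    guess: MassState | None = None,
    tol: float = 1e-12,
) -> Equilibrium:
    """Solve for a fixed point of the mass model at constant background drive.

    The system is reduced to the rate variables (all other variables have
    closed forms at equilibrium), solved in log-rate space so the solution
    stays positive, and classified via the full numerical Jacobian.
    """
    if guess is None:
        guess = MassState.rest(arch, stp)
    expand, residual = _equilibrium_closure(arch, pops, stp, I_B)
    r0 = np.maximum(np.atleast_1d(np.asarray(guess.r, dtype=float)), 1e-12)

    sol = root(lambda s: residual(np.exp(s)), np.log(r0), method="hybr", tol=1e-13)
    r = np.exp(sol.x)
    res = float(np.max(np.abs(residual(r))))
    if res > max(tol, 1e-9):
        raise NumericalError(
            f"equilibrium solve did not converge: final residual {res:.3g}"
        )
    state = expand(r)
    eig = np.linalg.eigvals(jacobian(state, arch, pops, stp, I_B))
    return Equilibrium(state=state, eigenvalues=eig, residual=res)


def jacobian(
    state: MassState,
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    I_B: float,
) -> np.ndarray:
    """Numerical Jacobian of the autonomous flow at ``state`` (central differences)."""
    stim = StimulusSchedule(I_B=I_B)
    f = _rhs_flat(arch, pops, stp, stim)
    y = state.pack()
    m = y.size
    Jm = np.empty((m, m))
    for j in range(m):
        h = 1e-7 * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        Jm[:, j] = (f(0.0, yp) - f(0.0, ym)) / (2 * h)
    return Jm


def normalized_synapse(
    x: np.ndarray, u: np.ndarray, stp: STPParams
) -> tuple[np.ndarray, np.ndarray]:
    """Package convention for reporting synaptic variables on a [0, 1] scale.

    ``x`` is already a fraction of available resources and is returned
    unchanged; ``u`` is affinely rescaled so the baseline ``U0`` maps to 0 and
    full utilization maps to 1.  This is a *reporting* convention only -- it
    never enters the dynamics.
    """
    return np.asarray(x), (np.asarray(u) - stp.U0) / (1.0 - stp.U0)
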