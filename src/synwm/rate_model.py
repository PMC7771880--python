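"""Heuristic Wilson-Cowan-type firing-rate model with short-term plasticity.

The rate model shares the fixed points of the exact mass model by
construction -- its activation function Phi is the steady-state rate of the
QIF population -- but it discards the mean-membrane-potential dynamics.  As
a consequence the stimulated excited state is a node rather than a focus,
and the fast (beta-gamma) transient oscillations of the exact model are
absent.  Local field potential proxies are provided for spectral comparison
since the model carries no membrane potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from synwm.neural_mass import (
    Architecture,
    ConfigurationError,
    NumericalError,
    PopulationParams,
    STPParams,
    StimulusSchedule,
    _effective_J,
)

__all__ = ["RateState", "RateTrajectory", "phi", "rate_rhs", "integrate_rate", "lfp"]


@dataclass
class RateState:
    """Rates for every population, synaptic variables for excitatory ones."""

    r: np.ndarray
    x: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.r, self.x, self.u])


def phi(I: np.ndarray | float, Delta: float, tau_m: float) -> np.ndarray | float:
    """Steady-state firing rate of a QIF population with Lorentzian heterogeneity.

    Phi(I) = 1/(sqrt(2) pi tau_m) * sqrt(I + sqrt(I^2 + Delta^2))

    Strictly increasing in I; for Delta -> 0 it reduces to the familiar
    sqrt(I)/(pi tau_m) above threshold and 0 below.
    """
    I = np.asarray(I, dtype=float)
    out = np.sqrt(I + np.sqrt(I * I + Delta * Delta)) / (np.sqrt(2.0) * np.pi * tau_m)
    return float(out) if out.ndim == 0 else out


def rate_rhs(
    state: RateState,
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    stimulus: StimulusSchedule,
    t: float,
) -> RateState:
    """Time derivative of the rate-model state at time ``t`` (ms)."""
    n, e = arch.n_total, arch.n_pop
    if state.r.size != n or state.x.size != e or state.u.size != e:
        raise ConfigurationError(
            f"state dimensions (r={state.r.size}, x={state.x.size}, "
            f"u={state.u.size}) do not match architecture"
        )
    if not np.all(np.isfinite(state.r)):
        raise NumericalError("non-finite rate component")
    tau = np.array([p.tau_m for p in pops])
    H = np.array([p.H for p in pops])
    r, x, u = state.r, state.x, state.u
    Jeff = _effective_J(arch, x, u)
    I = H + stimulus.background(t) + stimulus.stimulus(t, n) + tau * (Jeff @ r)
    dr = (-r + np.array([phi(I[k], pops[k].Delta, tau[k]) for k in range(n)])) / tau
    r_e = r[arch.exc_idx]
    dx = (1.0 - x) / stp.tau_d - u * x * r_e
    du = (stp.U0 - u) / stp.tau_f + stp.U0 * (1.0 - u) * r_e
    return RateState(r=dr, x=dx, u=du)


@dataclass
class RateTrajectory:
    t: np.ndarray
    r: np.ndarray
    x: np.ndarray
    u: np.ndarray
    exc_idx: np.ndarray

    @property
    def r_hz(self) -> np.ndarray:
        return self.r * 1e3

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def final_state(self) -> RateState:
        return RateState(r=self.r[:, -1], x=self.x[:, -1], u=self.u[:, -1])


def integrate_rate(
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    stimulus: StimulusSchedule,
    t_span: tuple[float, float],
    init: RateState,
    rtol: float = 1e-10,
    atol: float = 1e-10,
    dt_out: float = 0.1,
) -> RateTrajectory:
    """Integrate the rate model (adaptive Dormand-Prince, split at stimulus jumps)."""
    n, e = arch.n_total, arch.n_pop
    tau = np.array([p.tau_m for p in pops])
    H = np.array([p.H for p in pops])
    Delta = np.array([p.Delta for p in pops])
    exc_idx = arch.exc_idx
    J, plastic = arch.J, arch.plastic_mask
    sq2pi = np.sqrt(2.0) * np.pi

    def f(t, y):
        r = y[:n]
        x = y[n : n + e]
        u = y[n + e :]
        ux = np.ones(n)
        ux[exc_idx] = u * x
        Jeff = np.where(plastic, J * ux[None, :], J)
        I = H + stimulus.background(t) + stimulus.stimulus(t, n) + tau * (Jeff @ r)
        Phi = np.sqrt(I + np.sqrt(I * I + Delta * Delta)) / (sq2pi * tau)
        dr = (-r + Phi) / tau
        r_e = r[exc_idx]
        dx = (1.0 - x) / stp.tau_d - u * x * r_e
        du = (stp.U0 - u) / stp.tau_f + stp.U0 * (1.0 - u) * r_e
        return np.concatenate([dr, dx, du])

    t0, t1 = float(t_span[0]), float(t_span[1])
    t_eval = np.arange(t0, t1 + 0.5 * dt_out, dt_out)
    cuts = [c for c in stimulus.breakpoints() if t0 < c < t1]
    edges = [t0] + cuts + [t1]
    y = init.pack()
    ts, ys = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        last = b == edges[-1]
        mask = (t_eval >= a) & ((t_eval <= b) if last else (t_eval < b))
        seg_eval = np.unique(np.concatenate([t_eval[mask], [b]]))
        sol = solve_ivp(f, (a, b), y, method="RK45", rtol=rtol, atol=atol, t_eval=seg_eval)
        if not sol.success:
            raise NumericalError(f"integration failed at t={sol.t[-1]:.6g} ms")
        y = sol.y[:, -1]
        keep = np.isin(sol.t, t_eval[mask])
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    return RateTrajectory(
        t=t_all,
        r=y_all[:n],
        x=y_all[n : n + e],
        u=y_all[n + e :],
        exc_idx=exc_idx,
    )


def lfp(
    r: np.ndarray,
    x: np.ndarray,
    u: np.ndarray,
    arch: Architecture,
) -> np.ndarray:
    """Local field potential proxies for the two-item architecture.

    LFP_0 = -( |J_ie| (r_1 + r_2) + |J_ii| r_0 )
    LFP_1 = -( |J_ee_s| x_1 u_1 r_1 + |J_ee_c| x_2 u_2 r_2 + |J_ei| r_0 )
    LFP_2 = -( |J_ee_s| x_2 u_2 r_2 + |J_ee_c| x_1 u_1 r_1 + |J_ei| r_0 )

    Sum of absolute synaptic input magnitudes, sign reversed so that high
    activity shows as an LFP minimum; constant currents are omitted since
    they carry no spectral content.

    ``r`` has shape (3, n_t) with population 0 inhibitory; ``x``, ``u`` have
    shape (2, n_t).
    """
    if arch.n_total != 3 or arch.n_pop != 2:
        raise ConfigurationError(
            "LFP proxies are defined for the two-item architecture "
            "(two excitatory + one inhibitory population)"
        )
    Jie = abs(arch.J[0, 1])
    Jii = abs(arch.J[0, 0])
    Jei = abs(arch.J[1, 0])
    Js = abs(arch.J[1, 1])
    Jc = abs(arch.J[1, 2])
    s1 = x[0] * u[0] * r[1]
    s2 = x[1] * u[1] * r[2]
    lfp0 = -(Jie * (r[1] + r[2]) + Jii * r[0])
    lfp1 = -(Js * s1 + Jc * s2 + Jei * r[0])
    lfp2 = -(Js * s2 + Jc * s1 + Jei * r[0])
    return np.vstack([lfp0, lfp1, lfp2])
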