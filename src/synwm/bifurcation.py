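"""Equilibrium branch tracing and codimension-1 bifurcation detection.

Natural-parameter continuation in the background current I_B with secant
prediction and step halving.  Folds are detected as continuation failures
accompanied by a leading real eigenvalue approaching zero and located by
extrapolating lambda^2 (linear in I_B near a saddle-node); Hopf points are
located by bisection on the real part of the leading complex pair.
Branch points (symmetry-breaking of the two-item architecture) are
distinguished from folds by comparing the full spectrum with the spectrum
restricted to the symmetric subspace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, root

from synwm.neural_mass import (
    Architecture,
    MassState,
    NumericalError,
    PopulationParams,
    STPParams,
    _equilibrium_closure,
    jacobian,
)

__all__ = [
    "Branch",
    "BifurcationPoint",
    "trace_branch",
    "locate_bifurcations",
    "classify_equilibrium",
    "solve_equilibrium_rates",
    "find_hopf",
    "find_fold",
]


def solve_equilibrium_rates(
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    I_B: float,
    r_guess: np.ndarray,
    res_tol: float = 1e-9,
) -> tuple[MassState, np.ndarray] | None:
    """Solve the reduced (rate-space) fixed-point system; None if not converged.

    Returns the full state and the Jacobian eigenvalues.
    """
    expand, residual = _equilibrium_closure(arch, pops, stp, I_B)
    with np.errstate(all="ignore"):
        sol = root(
            lambda z: residual(np.exp(z)),
            np.log(np.maximum(r_guess, 1e-12)),
            method="hybr",
            tol=1e-13,
        )
        r = np.exp(sol.x)
        if np.max(np.abs(residual(r))) > res_tol:
            return None
    state = expand(r)
    eig = np.linalg.eigvals(jacobian(state, arch, pops, stp, I_B))
    return state, eig


def classify_equilibrium(eigenvalues: np.ndarray) -> tuple[str, str]:
    """Classify a fixed point from its spectrum.

    Returns ``(stability, kind)`` with stability in {"stable", "unstable"}
    and kind in {"node", "focus", "saddle"}: focus iff the leading (largest
    real part) eigenvalues form a complex pair; saddle iff the spectrum is
    real-led with eigenvalues of both signs.
    """
    eigenvalues = np.asarray(eigenvalues)
    lead = eigenvalues[np.argmax(eigenvalues.real)]
    stability = "stable" if lead.real < 0 else "unstable"
    if abs(lead.imag) > 1e-10:
        return stability, "focus"
    reals = eigenvalues[np.abs(eigenvalues.imag) <= 1e-10].real
    if reals.size and reals.max() > 0 > reals.min():
        return stability, "saddle"
    return stability, "node"


@dataclass
class Branch:
    """Equilibrium branch: states, spectra and stability along I_B."""

    I_B: list[float] = field(default_factory=list)
    states: list[MassState] = field(default_factory=list)
    eigenvalues: list[np.ndarray] = field(default_factory=list)
    truncated: bool = False

    def append(self, I: float, state: MassState, eig: np.ndarray):
        self.I_B.append(float(I))
        self.states.append(state)
        self.eigenvalues.append(eig)

    @property
    def stable(self) -> np.ndarray:
        return np.array([e.real.max() < 0 for e in self.eigenvalues])

    def leading_real(self) -> np.ndarray:
        """Largest real part among purely real eigenvalues at each point."""
        out = []
        for e in self.eigenvalues:
            reals = e[np.abs(e.imag) <= 1e-8].real
            out.append(reals.max() if reals.size else -np.inf)
        return np.array(out)

    def leading_complex_real(self) -> np.ndarray:
        """Largest real part among complex-pair eigenvalues at each point."""
        out = []
        for e in self.eigenvalues:
            cplx = e[np.abs(e.imag) > 1e-8].real
            out.append(cplx.max() if cplx.size else -np.inf)
        return np.array(out)

    def __len__(self) -> int:
        return len(self.I_B)


@dataclass(frozen=True)
class BifurcationPoint:
    kind: str  # "saddle-node" | "branch-point" | "hopf"
    I_B: float
    state: MassState


def trace_branch(
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    I_start: float,
    I_stop: float,
    step: float,
    seed: MassState,
    min_step: float = 1e-7,
) -> Branch:
    """Continue an equilibrium branch from ``I_start`` towards ``I_stop``.

    Secant prediction of the rates, step halving on Newton failure or branch
    jumps; the branch is truncated (with a warning) when the step underflows,
    which at a fold is the expected terminating event.
    """
    branch = Branch()
    direction = 1.0 if I_stop >= I_start else -1.0
    h = abs(step) * direction

    out = solve_equilibrium_rates(arch, pops, stp, I_start, np.asarray(seed.r))
    if out is None:
        raise NumericalError(f"seed equilibrium did not converge at I_B={I_start}")
    branch.append(I_start, *out)

    I = I_start
    while direction * (I_stop - I) > 1e-12:
        h = direction * min(abs(h), abs(I_stop - I))
        I_try = I + h
        r_prev = np.asarray(branch.states[-1].r)
        if len(branch) >= 2:
            # secant prediction in log-rate space
            r_pp = np.asarray(branch.states[-2].r)
            dI = branch.I_B[-1] - branch.I_B[-2]
            pred = np.exp(
                np.log(r_prev)
                + (np.log(r_prev) - np.log(r_pp)) * (h / dI if dI != 0 else 0.0)
            )
        else:
            pred = r_prev
        out = solve_equilibrium_rates(arch, pops, stp, I_try, pred)
        connected = out is not None and np.all(
            np.abs(np.log(np.asarray(out[0].r)) - np.log(r_prev))
            < 0.5 + 10 * abs(h)
        )
        if connected:
            branch.append(I_try, *out)
            I = I_try
            if abs(h) < abs(step):
                h *= 2.0
        else:
            h *= 0.5
            if abs(h) < min_step:
                branch.truncated = True
                warnings.warn(
                    f"branch lost at I_B={I:.6f} (step underflow); truncating",
                    RuntimeWarning,
                    stacklevel=2,
                )
                break
    return branch


def _refine_crossing(arch, pops, stp, branch, i, which: str) -> tuple[float, MassState]:
    """Bisect the zero of the leading (real|complex) eigenvalue between
    branch points i and i+1."""
    guess = {"I": None, "r": np.asarray(branch.states[i].r)}

    def g(I):
        out = solve_equilibrium_rates(arch, pops, stp, I, guess["r"])
        if out is None:
            raise NumericalError(f"equilibrium lost during refinement at I_B={I}")
        st, eig = out
        guess["r"] = np.asarray(st.r)
        guess["I"] = (I, st)
        if which == "complex":
            sel = eig[np.abs(eig.imag) > 1e-8].real
        else:
            sel = eig[np.abs(eig.imag) <= 1e-8].real
        return sel.max() if sel.size else -np.inf

    I_c = brentq(g, branch.I_B[i], branch.I_B[i + 1], xtol=1e-7)
    g(I_c)
    return I_c, guess["I"][1]


def locate_bifurcations(
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    branch: Branch,
    tol: float = 1e-5,
) -> list[BifurcationPoint]:
    """Find codim-1 bifurcations along a traced branch.

    Sign changes of the leading complex-pair real part give Hopf points;
    sign changes of the leading real eigenvalue give saddle-node or
    branch-point candidates (labelled "branch-point" when the zero
    eigenvector breaks the permutation symmetry of a symmetric two-item
    state, "saddle-node" otherwise).  A truncated branch end with a real
    eigenvalue tending to zero is reported as a saddle-node located by
    extrapolating lambda^2 linearly in I_B.
    """
    points: list[BifurcationPoint] = []
    lam_c = branch.leading_complex_real()
    lam_r = branch.leading_real()

    for i in range(len(branch) - 1):
        if np.isfinite(lam_c[i]) and np.isfinite(lam_c[i + 1]) and lam_c[i] * lam_c[i + 1] < 0:
            I_c, st = _refine_crossing(arch, pops, stp, branch, i, "complex")
            points.append(BifurcationPoint("hopf", I_c, st))
        if np.isfinite(lam_r[i]) and np.isfinite(lam_r[i + 1]) and lam_r[i] * lam_r[i + 1] < 0:
            I_c, st = _refine_crossing(arch, pops, stp, branch, i, "real")
            kind = "branch-point" if _breaks_symmetry(arch, pops, stp, st, I_c) else "saddle-node"
            points.append(BifurcationPoint(kind, I_c, st))

    if branch.truncated and len(branch) >= 4:
        tail = slice(max(0, len(branch) - 8), len(branch))
        lam_tail = lam_r[tail]
        I_tail = np.array(branch.I_B[tail])
        if np.all(np.isfinite(lam_tail)) and abs(lam_tail[-1]) < 1e-3:
            a, b = np.polyfit(I_tail, lam_tail**2, 1)
            I_sn = -b / a
            points.append(BifurcationPoint("saddle-node", float(I_sn), branch.states[-1]))

    points.sort(key=lambda p: p.I_B)
    return points


def _breaks_symmetry(arch, pops, stp, state: MassState, I_B: float) -> bool:
    """True when the near-zero eigenvalue's eigenvector breaks the
    excitatory permutation symmetry of a symmetric state."""
    if arch.n_pop != 2:
        return False
    r = np.asarray(state.r)
    if abs(r[1] - r[2]) > 1e-6 * max(r[1], r[2]):
        return False  # asymmetric state: a real zero is a plain fold
    Jm = jacobian(state, arch, pops, stp, I_B)
    w, V = np.linalg.eig(Jm)
    idx = np.argmin(np.abs(w.real) + np.abs(w.imag))
    vec = V[:, idx].real
    # state packing: [r0 r1 r2 v0 v1 v2 x1 x2 u1 u2]
    swap = np.array([0, 2, 1, 3, 5, 4, 7, 6, 9, 8])
    asym = np.linalg.norm(vec + vec[swap])  # odd under 1<->2 exchange -> small
    sym = np.linalg.norm(vec - vec[swap])
    return asym < sym


def find_hopf(
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    I_lo: float,
    I_hi: float,
    seed: MassState,
    xtol: float = 1e-7,
) -> BifurcationPoint:
    """Bisection for the I_B at which the leading complex pair crosses zero,
    following the branch seeded at ``I_lo`` by ``seed``."""
    guess = {"r": np.asarray(seed.r), "st": None}

    def g(I):
        out = solve_equilibrium_rates(arch, pops, stp, I, guess["r"])
        if out is None:
            raise NumericalError(f"equilibrium lost at I_B={I}")
        st, eig = out
        guess["r"] = np.asarray(st.r)
        guess["st"] = st
        c = eig[np.abs(eig.imag) > 1e-8].real
        if not c.size:
            raise NumericalError(f"no complex pair at I_B={I}")
        return c.max()

    I_c = brentq(g, I_lo, I_hi, xtol=xtol)
    g(I_c)
    return BifurcationPoint("hopf", I_c, guess["st"])


def find_fold(
    arch: Architecture,
    pops: Sequence[PopulationParams],
    stp: STPParams,
    I_start: float,
    seed: MassState,
    step: float = 0.1,
    min_step: float = 1e-7,
    direction: float = 1.0,
) -> BifurcationPoint:
    """Continue a branch until it folds; return the extrapolated fold point.

    Near a saddle-node the leading real eigenvalue behaves as
    -c sqrt(I_sn - I), so lambda^2 is linear in I_B and extrapolates cleanly
    to the fold from the last converged points.
    """
    branch = trace_branch(
        arch, pops, stp, I_start, I_start + direction * 1e3, step, seed,
        min_step=min_step,
    )
    if not branch.truncated:
        raise NumericalError("branch did not fold within the scanned range")
    pts = locate_bifurcations(arch, pops, stp, branch)
    folds = [p for p in pts if p.kind == "saddle-node"]
    if not folds:
        raise NumericalError("fold not identified at branch truncation")
    return folds[-1]
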