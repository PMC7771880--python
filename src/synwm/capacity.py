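"""Analytic estimate of the maximal working-memory capacity.

The capacity of the multi-item architecture is bounded by how many
item-coding populations can interleave their population bursts within one
synaptic recovery cycle:

    N_c^max ~ T_c^max / T_b

``T_c^max`` is the time a population's synaptic efficacy ``u x`` needs to
recover after a burst, governed by the depression/facilitation time scales;
``T_b`` is the inter-burst interval, the time the mean membrane potential of
the next-firing population needs to climb from the post-inhibition value
``V_0`` to the burst threshold ``V_th`` under an effectively constant drive
``C``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from synwm.neural_mass import STPParams

__all__ = [
    "CapacityInputs",
    "recovery_time",
    "effective_coupling",
    "mean_field_rate",
    "drive_constant",
    "interburst_time",
    "max_capacity",
]


@dataclass(frozen=True)
class CapacityInputs:
    """Ingredients of the inter-burst time estimate.

    stp       : synapse constants
    tau_m_e   : excitatory membrane time constant (ms)
    H_e       : excitatory median excitability
    I_B       : background current
    J_ei      : inhibitory-to-excitatory coupling (enters via its magnitude)
    J_ee_self : within-item excitatory coupling
    J_ee_cross: between-item excitatory coupling
    n_pop     : number of excitatory populations
    xbar_ubar : effective stationary synaptic efficacy x*u, in (0, 1]
    V_th, V_0 : integration bounds of the voltage excursion (V_th > 0 > V_0)
    """

    stp: STPParams
    tau_m_e: float
    H_e: float
    I_B: float
    J_ei: float
    J_ee_self: float
    J_ee_cross: float
    n_pop: int
    xbar_ubar: float = 1.0
    V_th: float = 100.0
    V_0: float = -100.0

    def __post_init__(self):
        if not (0 < self.xbar_ubar <= 1):
            raise ValueError(f"xbar_ubar must lie in (0,1], got {self.xbar_ubar}")
        if not (self.V_th > 0 > self.V_0):
            raise ValueError("require V_th > 0 > V_0")


def recovery_time(stp: STPParams) -> float:
    """Maximal period of the burst cycle: synaptic-efficacy recovery time (ms).

    T_c^max = tau_d * ln[ (tau_f / tau_d) / (1 - U0) ]

    The recovery is ruled by the depression time scale, with a weaker
    logarithmic dependence on the facilitation/depression ratio.
    """
    return stp.tau_d * np.log((stp.tau_f / stp.tau_d) / (1.0 - stp.U0))


def effective_coupling(inputs: CapacityInputs) -> float:
    """Effective excitatory coupling J-bar = [J_ee_s + (N_pop - 2) J_ee_c] x u."""
    return (
        inputs.J_ee_self + (inputs.n_pop - 2) * inputs.J_ee_cross
    ) * inputs.xbar_ubar


def mean_field_rate(inputs: CapacityInputs) -> float:
    """Firing rate sqrt(H_e + I_B)/pi (per tau_m_e) of an isolated QIF neuron
    driven by the mean excitability and the background current (1/ms)."""
    drive = inputs.H_e + inputs.I_B
    if drive <= 0:
        raise ValueError(
            f"mean drive H_e + I_B = {drive} must be positive for the estimate"
        )
    return np.sqrt(drive) / (np.pi * inputs.tau_m_e)


def drive_constant(inputs: CapacityInputs) -> float:
    """Constant C of the voltage excursion between bursts.

    C = H_e + I_B + tau_m_e (-|J_ei| + J-bar) sqrt(H_e + I_B)/pi,
    with both population rates replaced by the isolated-neuron estimate.
    """
    rbar = mean_field_rate(inputs)
    return (
        inputs.H_e
        + inputs.I_B
        + inputs.tau_m_e * (-abs(inputs.J_ei) + effective_coupling(inputs)) * rbar
    )


def interburst_time(inputs: CapacityInputs, exact: bool = True) -> float:
    """Inter-burst interval T_b (ms).

    exact form:      T_b = tau_m_e / sqrt(C) [arctan(V_th/sqrt(C)) - arctan(V_0/sqrt(C))]
    asymptotic form: T_b ~ tau_m_e pi / sqrt(C)   (V_th -> inf, V_0 -> -inf)

    The asymptotic form always exceeds the exact one and converges to it as
    the voltage bounds widen.
    """
    C = drive_constant(inputs)
    if C <= 0:
        raise ValueError(
            f"drive constant C = {C:.4g} <= 0: no burst re-ignition under "
            "this approximation"
        )
    sq = np.sqrt(C)
    if not exact:
        return inputs.tau_m_e * np.pi / sq
    return (
        inputs.tau_m_e
        / sq
        * (np.arctan(inputs.V_th / sq) - np.arctan(inputs.V_0 / sq))
    )


def max_capacity(T_c: float, T_b: float) -> float:
    """Maximal number of retainable items, N_c^max = T_c / T_b (real-valued)."""
    if T_c <= 0 or T_b <= 0:
        raise ValueError("both times must be positive")
    return T_c / T_b
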