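import numpy as np
import pytest

from synwm.neural_mass import (
    Architecture,
    ConfigurationError,
    MassState,
    NumericalError,
    PopulationParams,
    Pulse,
    STPParams,
    StimulusSchedule,
    find_equilibrium,
    integrate,
    mass_rhs,
    normalized_synapse,
)
from synwm.rate_model import phi


def rest_state(arch, stp, r=1e-4, v=-1.0):
    n, e = arch.n_total, arch.n_pop
    return MassState(r=np.full(n, r), v=np.full(n, v), x=np.ones(e), u=np.full(e, stp.U0))


class TestTypes:
    def test_population_params_validation(self):
        with pytest.raises(ConfigurationError):
            PopulationParams(tau_m=-1.0, H=0.0, Delta=0.1)
        with pytest.raises(ConfigurationError):
            PopulationParams(tau_m=15.0, H=0.0, Delta=0.0)
        with pytest.raises(ConfigurationError):
            PopulationParams(tau_m=15.0, H=0.0, Delta=0.1, role="modulatory")

    def test_stp_params_validation(self):
        with pytest.raises(ConfigurationError):
            STPParams(tau_d=300.0, tau_f=200.0)
        with pytest.raises(ConfigurationError):
            STPParams(U0=1.5)

    def test_architecture_sign_constraints(self):
        # inhibitory column must be non-positive, excitatory non-negative
        with pytest.raises(ConfigurationError):
            Architecture(np.array([[1.0, 1.0], [1.0, 1.0]]), ["inhibitory", "excitatory"])
        with pytest.raises(ConfigurationError):
            Architecture(np.array([[-1.0, -1.0], [-1.0, 1.0]]), ["inhibitory", "excitatory"])

    def test_working_memory_architecture_structure(self):
        arch = Architecture.working_memory(2, Jee_s=14.0, Jee_c=2.0, Jie=5.2, Jei=-6.4, Jii=-5.6)
        assert arch.n_pop == 2 and arch.n_total == 3
        # plastic exactly on excitatory-excitatory entries
        assert not arch.plastic_mask[0].any() and not arch.plastic_mask[:, 0].any()
        assert arch.plastic_mask[1:, 1:].all()
        assert arch.J[1, 1] == arch.J[2, 2] == 14.0
        assert arch.J[1, 2] == arch.J[2, 1] == 2.0
        with pytest.raises(ConfigurationError):
            Architecture.working_memory(2, Jee_s=2.0, Jee_c=14.0, Jie=5.2, Jei=-6.4, Jii=-5.6)

    def test_pulse_validation(self):
        with pytest.raises(ConfigurationError):
            Pulse(1, 0.2, 100.0, 50.0)

    def test_piecewise_background(self):
        stim = StimulusSchedule(I_B=[(0.0, 1.532), (2150.0, 1.2)])
        assert stim.background(1000.0) == 1.532
        assert stim.background(2150.0) == 1.2
        assert 2150.0 in stim.breakpoints()


class TestMassRhs:
    def test_zero_rate_axis_is_repelled(self, single_pop, stp):
        arch, pops = single_pop
        st = MassState(r=[0.0], v=[-0.7], x=[1.0], u=[stp.U0])
        d = mass_rhs(st, arch, pops, stp, StimulusSchedule(I_B=-1.0), 0.0)
        expected = pops[0].Delta / (pops[0].tau_m**2 * np.pi)
        assert d.r[0] == pytest.approx(expected)
        assert d.r[0] > 0

    def test_synaptic_rest_state(self, single_pop, stp):
        arch, pops = single_pop
        st = MassState(r=[0.0], v=[-0.7], x=[1.0], u=[stp.U0])
        d = mass_rhs(st, arch, pops, stp, StimulusSchedule(I_B=-1.0), 0.0)
        assert d.x[0] == 0.0
        assert d.u[0] == 0.0

    def test_dimension_mismatch_is_configuration_error(self, single_pop, stp):
        arch, pops = single_pop
        st = MassState(r=[0.0, 0.0], v=[-0.7, -0.7], x=[1.0], u=[stp.U0])
        with pytest.raises(ConfigurationError):
            mass_rhs(st, arch, pops, stp, StimulusSchedule(), 0.0)

    def test_nonfinite_state_identifies_component(self, single_pop, stp):
        arch, pops = single_pop
        st = MassState(r=[np.nan], v=[-0.7], x=[1.0], u=[stp.U0])
        with pytest.raises(NumericalError, match=r"r\[\[0\]\]"):
            mass_rhs(st, arch, pops, stp, StimulusSchedule(), 0.0)

    def test_derivative_vanishes_at_equilibrium(self, single_pop, stp):
        arch, pops = single_pop
        eq = find_equilibrium(arch, pops, stp, I_B=-1.0, guess=rest_state(arch, stp))
        d = mass_rhs(eq.state, arch, pops, stp, StimulusSchedule(I_B=-1.0), 0.0)
        assert np.max(np.abs(d.pack())) < 1e-12


class TestEquilibrium:
    @pytest.mark.parametrize(
        "H,Delta,J,I_B",
        [(0.0, 0.25, 15.0, -1.0), (0.5, 0.1, 8.0, 0.3), (-0.2, 0.5, 3.0, 1.0), (0.0, 0.05, 0.0, 0.7)],
    )
    def test_matches_phi_self_consistency(self, stp, H, Delta, J, I_B):
        """At any fixed point the rate satisfies r = Phi(total input)."""
        arch = Architecture.single_excitatory(J)
        pops = [PopulationParams(tau_m=15.0, H=H, Delta=Delta)]
        eq = find_equilibrium(arch, pops, stp, I_B=I_B, guess=rest_state(arch, stp))
        r, x, u = eq.state.r[0], eq.state.x[0], eq.state.u[0]
        I_tot = H + I_B + 15.0 * J * u * x * r
        assert r == pytest.approx(phi(I_tot, Delta, 15.0), rel=1e-8)

    def test_uncoupled_equilibrium_equals_phi(self, stp):
        """With J = 0 the rate is the closed form Phi(H + I_B) directly."""
        arch = Architecture.single_excitatory(0.0)
        pops = [PopulationParams(tau_m=15.0, H=0.1, Delta=0.3)]
        eq = find_equilibrium(arch, pops, stp, I_B=0.5, guess=rest_state(arch, stp))
        assert eq.state.r[0] == pytest.approx(phi(0.6, 0.3, 15.0), rel=1e-10)

    def test_two_item_symmetric_equilibrium(self, two_item_model):
        m = two_item_model
        eq = find_equilibrium(
            m.arch, m.pops, m.stp, I_B=1.2,
            guess=MassState(r=[0.012, 0.0026, 0.0026], v=[-1, -1, -1], x=[0.8, 0.8], u=[0.5, 0.5]),
        )
        assert eq.state.r[1] == pytest.approx(eq.state.r[2], rel=1e-10)
        assert eq.state.v[1] == pytest.approx(eq.state.v[2], rel=1e-10)
        assert eq.state.x[0] == pytest.approx(eq.state.x[1], rel=1e-10)
        assert eq.state.u[0] == pytest.approx(eq.state.u[1], rel=1e-10)


class TestIntegrate:
    def test_equilibrium_persists(self, stp):
        from synwm.rate_model import phi

        arch = Architecture.single_excitatory(0.0)
        pops = [PopulationParams(tau_m=15.0, H=-0.5, Delta=1e-3)]
        guess = rest_state(arch, stp, r=phi(-0.5, 1e-3, 15.0))
        eq = find_equilibrium(arch, pops, stp, I_B=0.0, guess=guess)
        traj = integrate(arch, pops, stp, StimulusSchedule(I_B=0.0), (0, 500.0), eq.state)
        assert np.allclose(traj.r, eq.state.r[0], rtol=1e-8, atol=1e-12)
        assert np.allclose(traj.v, eq.state.v[0], rtol=1e-8)

    def test_state_invariants_along_trajectory(self, single_pop_model):
        """r > 0, 0 < x <= 1, U0 <= u < 1 at every output sample."""
        m = single_pop_model
        eq = find_equilibrium(
            m.arch, m.pops, m.stp, I_B=m.I_B,
            guess=MassState(r=[0.003], v=[-0.8], x=[0.7], u=[0.6]),
        )
        traj = integrate(m.arch, m.pops, m.stp, m.stimulus, (0, m.t_total), eq.state,
                         rtol=1e-10, atol=1e-10)
        assert np.all(traj.r > 0)
        assert np.all((traj.x > 0) & (traj.x <= 1.0))
        assert np.all((traj.u >= m.stp.U0 - 1e-12) & (traj.u < 1.0))

    def test_bitwise_reproducible(self, single_pop_model):
        m = single_pop_model
        init = MassState(r=[0.003], v=[-0.85], x=[0.73], u=[0.59])
        kw = dict(rtol=1e-10, atol=1e-10, dt_out=0.5)
        a = integrate(m.arch, m.pops, m.stp, m.stimulus, (0, 500.0), init, **kw)
        b = integrate(m.arch, m.pops, m.stp, m.stimulus, (0, 500.0), init, **kw)
        assert np.array_equal(a.r, b.r) and np.array_equal(a.v, b.v)

    def test_frozen_synapse_limit(self, stp):
        """With the synaptic variables frozen at (x, u) = (1, U0) the model
        reproduces the plasticity-free dynamics with coupling J * U0."""
        arch = Architecture.single_excitatory(15.0)
        arch_eff = Architecture(np.array([[15.0 * stp.U0]]), ["excitatory"], plastic=False)
        pops = [PopulationParams(tau_m=15.0, H=0.0, Delta=0.25)]
        stim = StimulusSchedule(I_B=-1.0, pulses=[Pulse(0, 2.0, 50.0, 200.0)])
        init = MassState(r=[0.002], v=[-0.9], x=[1.0], u=[stp.U0])
        a = integrate(arch, pops, stp, stim, (0, 400.0), init,
                      rtol=1e-10, atol=1e-10, freeze_stp=True)
        b = integrate(arch_eff, pops, stp, stim, (0, 400.0), init,
                      rtol=1e-10, atol=1e-10, freeze_stp=True)
        assert np.allclose(a.r, b.r, rtol=1e-6, atol=1e-10)
        assert np.all(a.x == 1.0) and np.all(a.u == stp.U0)

    def test_permutation_symmetry(self, two_item_model):
        """Exchanging the two item populations together with their stimuli
        permutes the trajectory exactly."""
        m = two_item_model
        init = MassState(r=[0.012, 0.004, 0.002], v=[-0.5, -0.6, -0.9],
                         x=[0.7, 0.9], u=[0.5, 0.3])
        init_swapped = MassState(r=[0.012, 0.002, 0.004], v=[-0.5, -0.9, -0.6],
                                 x=[0.9, 0.7], u=[0.3, 0.5])
        stim1 = StimulusSchedule(I_B=1.2, pulses=[Pulse(1, 0.2, 0.0, 350.0)])
        stim2 = StimulusSchedule(I_B=1.2, pulses=[Pulse(2, 0.2, 0.0, 350.0)])
        kw = dict(rtol=1e-12, atol=1e-12, dt_out=1.0)
        a = integrate(m.arch, m.pops, m.stp, stim1, (0, 1000.0), init, **kw)
        b = integrate(m.arch, m.pops, m.stp, stim2, (0, 1000.0), init_swapped, **kw)
        assert np.allclose(a.r[1], b.r[2], rtol=1e-7, atol=1e-12)
        assert np.allclose(a.r[2], b.r[1], rtol=1e-7, atol=1e-12)
        assert np.allclose(a.r[0], b.r[0], rtol=1e-7, atol=1e-12)


class TestNormalizedSynapse:
    def test_conventions(self, stp):
        x, u = normalized_synapse(np.array([1.0, 0.5]), np.array([stp.U0, 1.0]), stp)
        assert x[0] == 1.0 and x[1] == 0.5     # identity on x
        assert u[0] == 0.0                      # baseline maps to zero
        assert u[1] == pytest.approx(1.0)       # saturation maps to one

    def test_monotone(self, stp):
        us = np.linspace(stp.U0, 0.999, 50)
        _, un = normalized_synapse(np.ones_like(us), us, stp)
        assert np.all(np.diff(un) > 0)
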