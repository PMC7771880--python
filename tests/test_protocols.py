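import numpy as np
import pytest

from synwm.neural_mass import ConfigurationError, Pulse, Trajectory
from synwm.protocols import (
    CompetitionOutcome,
    ExperimentSpec,
    build_stimulus,
    classify_competition,
    load_preset,
    memory_load_proxy,
    preset_names,
    run_competition,
)


class TestPresets:
    def test_known_presets_load(self):
        for name in preset_names():
            m = load_preset(name)
            assert m.arch.n_total == len(m.pops)

    def test_unknown_preset_lists_alternatives(self):
        with pytest.raises(ConfigurationError, match="two_item"):
            load_preset("no_such_preset")

    def test_two_item_couplings_are_immutable_published_set(self):
        m = load_preset("two_item")
        s = np.sqrt(0.4)
        assert m.arch.J[1, 1] == pytest.approx(35 * s)
        assert m.arch.J[1, 2] == pytest.approx(5 * s)
        assert m.arch.J[0, 1] == pytest.approx(13 * s)
        assert m.arch.J[1, 0] == pytest.approx(-16 * s)
        assert m.arch.J[0, 0] == pytest.approx(-14 * s)

    def test_multi_item_couplings(self):
        m = load_preset("multi_item")
        assert m.arch.n_pop == 7
        assert m.arch.J[1, 1] == 154.0
        assert m.arch.J[1, 2] == pytest.approx(4 / 7 * 18.5)
        assert m.arch.J[0, 1] == pytest.approx(4 / 7 * 97)
        assert m.pops[0].tau_m == 10.0 and m.pops[1].tau_m == 15.0


class TestBuildStimulus:
    def test_two_pulse_protocol(self):
        stim = build_stimulus(ExperimentSpec(preset="single_pop", protocol="two_pulse"))
        assert len(stim.pulses) == 2
        for p in stim.pulses:
            assert p.amplitude == 2.0
            assert p.t_off - p.t_on == 150.0
        gap = stim.pulses[1].t_on - stim.pulses[0].t_off
        assert gap == 150.0

    def test_refresh_train(self):
        stim = build_stimulus(ExperimentSpec(protocol="refresh_train", I_B=1.2))
        refresh = [p for p in stim.pulses if p.amplitude == 0.1]
        # non-specific pulses go to both excitatory populations every 400 ms
        assert {p.population for p in refresh} == {1, 2}
        onsets = sorted({p.t_on for p in refresh})
        assert np.allclose(np.diff(onsets), 400.0)
        assert all(p.t_off - p.t_on == 150.0 for p in refresh)

    def test_empty_spec_is_background_only(self):
        stim = build_stimulus(ExperimentSpec())
        assert len(stim.pulses) == 0

    def test_unknown_protocol(self):
        with pytest.raises(ConfigurationError):
            build_stimulus(ExperimentSpec(protocol="no_such_protocol"))


def synthetic_traj(r1, r2, dt=1.0):
    n = r1.size
    t = np.arange(n) * dt
    r = np.vstack([np.full(n, 5e-3), r1, r2])
    return Trajectory(t=t, r=r, v=np.zeros_like(r), x=np.ones((2, n)),
                      u=np.full((2, n), 0.2), exc_idx=np.array([1, 2]))


class TestClassifyCompetition:
    def test_silent_competitor_gives_item1(self):
        n = 6000
        traj = synthetic_traj(np.full(n, 8e-3), np.zeros(n))
        out = classify_competition(traj, 1000.0)
        assert out.P == 1.0
        assert out.label == "item1"

    def test_balanced_rates_give_juggling(self):
        n = 6000
        traj = synthetic_traj(np.full(n, 5e-3), np.full(n, 5e-3))
        assert classify_competition(traj, 1000.0).label == "juggling"

    def test_short_trajectory_rejected(self):
        traj = synthetic_traj(np.ones(100), np.ones(100))
        with pytest.raises(ConfigurationError):
            classify_competition(traj, 1000.0)

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(5)
        r1 = rng.uniform(0, 0.02, 6000)
        r2 = rng.uniform(0, 0.02, 6000)
        a = classify_competition(synthetic_traj(r1, r2), 1000.0)
        b = classify_competition(synthetic_traj(r2, r1), 1000.0)
        assert a.P == pytest.approx(1.0 - b.P)
        swap = {"item1": "item2", "item2": "item1", "juggling": "juggling"}
        assert a.label == swap[b.label]

    def test_thresholds(self):
        assert CompetitionOutcome.from_P(0.71).label == "item1"
        assert CompetitionOutcome.from_P(0.29).label == "item2"
        assert CompetitionOutcome.from_P(0.5).label == "juggling"


class TestCompetitionExperiments:
    """Final outcome of the two-item competition versus the duration of the
    second stimulation (self-sustained regime, I_B = 1.532): short
    distractors leave item one, intermediate durations produce juggling,
    long ones switch to item two."""

    @pytest.mark.parametrize(
        "dur,expected",
        [(200.0, "item1"), (600.0, "juggling"), (1200.0, "item2")],
    )
    def test_outcome_vs_duration(self, dur, expected):
        out = run_competition(0.2, dur, I_B=1.532, t_second=1500.0)
        assert out.label == expected

    def test_zero_amplitude_distractor_cannot_switch(self):
        out = run_competition(0.0, 500.0, I_B=1.532, t_second=1500.0)
        assert out.label == "item1"


class TestRetrievalProbability:
    def test_bookkeeping_identity(self):
        """Summed over serial positions, the retrieval probability equals
        the mean retained count of the scan."""
        from synwm.protocols import retrieval_probability

        scan = {
            2.0: {"retained": [4, 5, 6, 7], "N_I": 4},
            8.0: {"retained": [3, 4, 5, 6, 7], "N_I": 5},
            16.0: {"retained": [1, 2, 5, 6, 7], "N_I": 5},
        }
        probs = retrieval_probability(scan)
        assert probs.sum() == pytest.approx(np.mean([4, 5, 5]))
        assert np.all((probs >= 0) & (probs <= 1))
        # recency: the last position is retained everywhere in this scan
        assert probs[6] == 1.0

    def test_empty_scan_rejected(self):
        from synwm.protocols import retrieval_probability

        with pytest.raises(ConfigurationError):
            retrieval_probability({})


class TestMemoryLoadProxy:
    def test_identical_dynamics_give_zero(self):
        n = 4000
        t = np.arange(n) * 1.0
        burst = np.full(n, 2e-3)
        burst[2000:2010] = 0.05
        r = np.vstack([np.full(n, 5e-3)] + [burst] * 3)
        v = np.vstack([np.zeros(n)] + [np.sin(t / 50.0)] * 3)
        traj = Trajectory(t=t, r=r, v=v, x=np.ones((3, n)), u=np.full((3, n), 0.2),
                          exc_idx=np.array([1, 2, 3]))
        lag, dv = memory_load_proxy(traj, coding=[1, 2], trigger=1, baseline_hz=2.0)
        assert np.allclose(dv, 0.0, atol=1e-12)

    def test_requires_noncoding_population(self):
        n = 4000
        traj = synthetic_traj(np.full(n, 5e-3), np.full(n, 5e-3))
        with pytest.raises(ConfigurationError):
            memory_load_proxy(traj, coding=[1, 2], trigger=1)


class TestPhaseDiagram:
    def test_zero_amplitude_cell_is_item1_at_every_phase(self):
        """A second stimulus of zero amplitude can never displace the first
        item, whatever its delivery phase."""
        from synwm.protocols import competition_phase_diagram

        res = competition_phase_diagram([0.0], [300.0], n_phases=2, I_B=1.532,
                                        t_equilibrate=3000.0)
        frac = res[(0.0, 300.0)]
        assert frac["item1"] == 1.0
        assert frac["item2"] == 0.0 and frac["juggling"] == 0.0
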