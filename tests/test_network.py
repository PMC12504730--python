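"""Spiking circuit: LIF dynamics, gates, dopamine delivery, trial execution."""

import numpy as np
import pytest

import striatumsim as ss
from striatumsim.plasticity import REWARD, PUNISH, TraceState, step_plasticity
from striatumsim.task import ConfigurationError


def lif_isi_closed_form(I, tau_m, threshold, dt, ref_steps):
    """Analytic interspike interval of the discrete leaky integrator.

    V_{n+1} = a V_n + I from reset 0 crosses threshold after the smallest n
    with I (1 - a^n) / (1 - a) >= threshold.
    """
    a = np.exp(-dt / tau_m)
    v_inf = I / (1 - a)
    if v_inf < threshold:
        return np.inf
    n = int(np.ceil(np.log(1 - threshold * (1 - a) / I) / np.log(a)))
    return ref_steps + n


def make_state(quiet_net, n_input=20, seed=0):
    return ss.build_network(quiet_net, n_input, seed)


class TestBuild:
    def test_per_channel_populations_and_constant_init(self, quiet_net):
        state = make_state(quiet_net)
        assert state.v_act.shape == (2,)
        assert state.w_d1.shape == (20, 8)
        assert state.w_d2.shape == (20, 8)
        assert np.all(state.w_d1 == quiet_net.w_init)
        assert np.all(state.w_d2 == quiet_net.w_init)

    def test_lateral_inhibition_asymmetry_enforced(self):
        with pytest.raises(ConfigurationError, match="asymmetric"):
            ss.ChannelWiring(w_d2_d1=0.01, w_d1_d2=0.02)

    def test_zero_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.ChannelWiring(n_channels=0)


class TestStepDynamics:
    def test_rest_without_input_stays_silent(self, quiet_net):
        state = make_state(quiet_net)
        for _ in range(100):
            out = ss.step_network(state, noise=False)
            assert not out["d1"].any() and not out["d2"].any() and not out["action"].any()

    @pytest.mark.parametrize("drive", [0.15, 0.2, 0.3, 0.5])
    def test_firing_matches_analytic_lif_interspike_interval(self, quiet_net, drive):
        state = make_state(quiet_net)
        spikes = []
        for t in range(400):
            out = ss.step_network(state, ext_d1=drive, noise=False)
            if out["d1"][0]:
                spikes.append(t)
        isis = np.diff(spikes)
        p = quiet_net.d1_params
        expected = lif_isi_closed_form(
            drive, p.tau_m, p.effective_threshold, quiet_net.dt,
            int(round(p.refractory / quiet_net.dt)),
        )
        assert len(spikes) >= 2
        assert np.all(np.abs(isis - expected) <= 1)  # within one dt of discretization

    def test_d2_at_least_as_fast_as_d1_across_drive_grid(self, quiet_net):
        for drive in (0.12, 0.15, 0.2, 0.4, 0.8):
            state = make_state(quiet_net)
            n1 = n2 = 0
            for _ in range(300):
                out = ss.step_network(state, ext_d1=drive, ext_d2=drive, noise=False)
                n1 += out["d1"].sum()
                n2 += out["d2"].sum()
            assert n2 >= n1

    def test_non_finite_membrane_raises(self, quiet_net, small_task, rng):
        state = make_state(quiet_net, n_input=small_task.n_input_neurons)
        state.w_d1[:] = np.nan
        pats = ss.make_stimulus_patterns(small_task)
        spikes = ss.generate_trial_spikes(pats, small_task.trial_duration, rng)
        amap = ss.initial_action_map(small_task)
        with pytest.raises(ss.SimulationError):
            ss.run_trial(state, spikes, amap, 0, (), 0, small_task)


class TestModulators:
    def test_action_spike_opens_channel_gate_only(self, quiet_net):
        state = make_state(quiet_net)
        ss.on_action_spike(state, 1, 900.0)
        assert state.modulators.gate_open(1000.0).tolist() == [False, True]
        assert state.modulators.gate_open(1050.0).tolist() == [False, True]
        assert state.modulators.gate_open(1051.0).tolist() == [False, False]

    def test_no_action_spikes_keeps_all_gates_closed(self, quiet_net):
        state = make_state(quiet_net)
        assert not state.modulators.gate_open(0.0).any()
        assert not state.modulators.gate_open(1999.0).any()

    def test_second_spike_refreshes_gate_expiry(self, quiet_net):
        state = make_state(quiet_net)
        ss.on_action_spike(state, 0, 100.0)
        ss.on_action_spike(state, 0, 150.0)
        assert state.modulators.gate_open(300.0).tolist() == [True, False]
        assert not state.modulators.gate_open(301.0).any()

    def test_outcome_pulses_are_global_and_valence_tagged(self, quiet_net, small_task):
        state = make_state(quiet_net)
        rewarded = ss.TrialOutcome(0, 0, (), ((0, 500.0),), True, False, False, 500.0)
        ss.deliver_outcome(state, rewarded, small_task)
        (pulse,) = state.modulators.pulses
        assert pulse.valence == REWARD
        assert pulse.onset == small_task.trial_duration

        state.modulators.reset()
        punished = ss.TrialOutcome(0, 0, (), ((1, 500.0),), False, True, False, 500.0)
        ss.deliver_outcome(state, punished, small_task)
        assert state.modulators.pulses[0].valence == PUNISH

    def test_no_response_trial_gets_no_pulse(self, quiet_net, small_task):
        state = make_state(quiet_net)
        silent = ss.TrialOutcome(0, 0, (), (), False, False, False)
        ss.deliver_outcome(state, silent, small_task)
        assert state.modulators.pulses == []


def driven_trial(small_task, quiet_net, *, stim=0, seed=0, **run_kw):
    """Fixture trial: stimulus-0 inputs wired strongly to channel-0 D1 only,
    so channel 0's action neuron is reliably driven above threshold."""
    state = make_state(quiet_net, n_input=small_task.n_input_neurons, seed=seed)
    state.w_d1[:] = 0.0
    state.w_d2[:] = 0.0
    pop = small_task.input_pop_size_per_stimulus
    state.w_d1[stim * pop : (stim + 1) * pop, : quiet_net.wiring.n_d1] = 0.9
    pats = ss.make_stimulus_patterns(small_task)
    spikes = ss.generate_trial_spikes(
        [pats[stim]], small_task.trial_duration, np.random.default_rng(seed)
    )
    amap = ss.initial_action_map(small_task)
    outcome, logs = ss.run_trial(state, spikes, amap, stim, (), 0, small_task, **run_kw)
    return state, outcome, logs


class TestRunTrial:
    def test_hand_wired_stimulus_selects_its_channel(self, small_task, quiet_net):
        _, outcome, logs = driven_trial(small_task, quiet_net)
        channels = {c for c, _t in logs.action_spikes}
        assert channels == {0}
        assert outcome.rewarded and not outcome.punished

    def test_gate_opens_only_in_acting_channel(self, small_task, quiet_net):
        _, _, logs = driven_trial(small_task, quiet_net)
        assert logs.gate_intervals[0]
        assert logs.gate_intervals[1] == []
        # gate locality: every interval starts at an action spike of that
        # channel and extends no further than one window past the last
        # contributing spike (refreshes merge, they do not stack)
        ch0 = [t for c, t in logs.action_spikes if c == 0]
        for lo, hi in logs.gate_intervals[0]:
            inside = [t for t in ch0 if lo <= t <= hi]
            assert inside and inside[0] == lo
            assert hi <= max(inside) + quiet_net.ach_window + 1e-9

    def test_non_acting_channel_weights_untouched(self, small_task, quiet_net):
        state, outcome, _ = driven_trial(small_task, quiet_net)
        assert outcome.rewarded
        n_d1 = quiet_net.wiring.n_d1
        # channel 1 had no gate, no activity: exact equality with init
        assert np.all(state.w_d1[:, n_d1:] == 0.0)
        assert np.all(state.w_d2[:, quiet_net.wiring.n_d2 :] == 0.0)
        # channel 0 received the rewarded update
        assert state.w_d1[:, :n_d1].max() > 0.9

    def test_weight_bounds_after_learning(self, small_task):
        net = ss.NetworkConfig(wiring=ss.ChannelWiring(n_d1=4, n_d2=4))
        state = ss.build_network(net, small_task.n_input_neurons, 3)
        pats = ss.make_stimulus_patterns(small_task)
        amap = ss.initial_action_map(small_task)
        rng = np.random.default_rng(3)
        for ep in range(15):
            stim = ep % 2
            spikes = ss.generate_trial_spikes([pats[stim]], small_task.trial_duration, rng)
            ss.run_trial(state, spikes, amap, stim, (), ep, small_task)
            for w in (state.w_d1, state.w_d2):
                assert np.all(w >= 0.0) and np.all(w <= net.w_max)

    def test_identical_seed_reproduces_outcome_and_logs(self, small_task, quiet_net):
        _, out_a, logs_a = driven_trial(small_task, quiet_net, seed=11)
        _, out_b, logs_b = driven_trial(small_task, quiet_net, seed=11)
        assert out_a == out_b
        assert logs_a.action_spikes == logs_b.action_spikes
        assert np.array_equal(logs_a.d1_counts, logs_b.d1_counts)

    def test_dynamic_state_resets_between_trials_weights_persist(
        self, small_task, quiet_net
    ):
        state, _, _ = driven_trial(small_task, quiet_net)
        assert state.t == 0.0
        assert np.all(state.v_d1 == 0.0)
        assert not state.modulators.gate_open(10.0).any()
        assert state.w_d1.max() > 0.0  # learned weights carried over


class TestPlasticityModes:
    """Mode contract at the circuit level: classic STDP updates from spike
    timing alone; the gated rule accumulates nothing without an action."""

    def run_mode(self, small_task, mode):
        # no action-neuron drive and no noise: SPNs fire from the stimulus,
        # but no action ever happens, so no gate opens and no DA arrives
        net = ss.NetworkConfig(
            wiring=ss.ChannelWiring(n_d1=4, n_d2=4, w_d1_act=0.0, w_d2_act=0.0),
            noise_spn=0.0,
            noise_act=0.0,
            w_init=0.8,
            plasticity_mode=mode,
        )
        state = ss.build_network(net, small_task.n_input_neurons, 2)
        pats = ss.make_stimulus_patterns(small_task)
        spikes = ss.generate_trial_spikes(
            [pats[0]], small_task.trial_duration, np.random.default_rng(2)
        )
        amap = ss.initial_action_map(small_task)
        outcome, logs = ss.run_trial(
            state, spikes, amap, 0, (), 0, small_task, return_eligibility=True
        )
        assert logs.action_spikes == []
        assert not outcome.rewarded and not outcome.punished
        return state, logs

    def test_classic_mode_updates_from_timing_alone(self, small_task):
        state, logs = self.run_mode(small_task, "classic")
        assert np.abs(logs.eligibility["d1_reward"]).max() > 0
        assert state.w_d1.max() > 0.8  # potentiated without any dopamine

    def test_reward_modulated_accumulates_but_needs_dopamine(self, small_task):
        state, logs = self.run_mode(small_task, "reward_modulated")
        assert np.abs(logs.eligibility["d1_reward"]).max() > 0
        assert state.w_d1.max() <= 0.8  # eligibility unused: no DA pulse

    def test_gated_mode_accumulates_nothing_without_an_action(self, small_task):
        state, logs = self.run_mode(small_task, "da_ach_gated")
        for elig in logs.eligibility.values():
            assert np.all(elig == 0)
        assert state.w_d1.max() <= 0.8


class TestCoreReplayEquivalence:
    """The jitted trial loop must agree with a replay through the reference
    plasticity operations, driven by its own spike logs."""

    def test_d1_eligibility_matches_reference_replay(self, small_task):
        net = ss.NetworkConfig(wiring=ss.ChannelWiring(n_d1=3, n_d2=3))
        state = ss.build_network(net, small_task.n_input_neurons, 5)
        pats = ss.make_stimulus_patterns(small_task)
        rng = np.random.default_rng(5)
        spikes = ss.generate_trial_spikes(pats, small_task.trial_duration, rng)
        amap = ss.initial_action_map(small_task)
        _, logs = ss.run_trial(
            state, spikes, amap, 0, (), 0, small_task,
            plasticity_on=False, record_spikes=True, return_eligibility=True,
        )
        n_steps = int(small_task.trial_duration)
        n_in = small_task.n_input_neurons
        n_d1 = net.wiring.n_d1
        n1t = 2 * n_d1
        pre = spikes.to_raster(n_steps, n_in).astype(float)
        post = np.zeros((n_steps, n1t))
        is_d1 = logs.spike_log.population_tags == "d1"
        for t, j in zip(logs.spike_log.times[is_d1], logs.spike_log.neuron_ids[is_d1]):
            post[int(t), int(j)] = 1.0
        action_steps = [(c, int(t)) for c, t in logs.action_spikes]
        kernels = {REWARD: net.kernels.d1_reward, PUNISH: net.kernels.d1_punish}
        traces = TraceState.zeros(n_in, n1t)
        for t in range(n_steps):
            open_ch = np.array(
                [
                    any(s < t <= s + net.ach_window for c2, s in action_steps if c2 == c)
                    for c in range(2)
                ]
            )
            gate = np.repeat(open_ch, n_d1)
            step_plasticity(traces, pre[t], post[t], gate, kernels, net.dt)
        assert logs.eligibility["d1_reward"] == pytest.approx(
            traces.eligibility[REWARD], abs=1e-9
        )
        assert logs.eligibility["d1_punish"] == pytest.approx(
            traces.eligibility[PUNISH], abs=1e-9
        )
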