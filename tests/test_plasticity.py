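"""Three-factor rule: traces, gated eligibility, dopamine conversion, LTD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import striatumsim as ss
from striatumsim.plasticity import REWARD, PUNISH, TraceState, step_plasticity


KERN = ss.KernelParams(a_plus=1.0, a_minus=-0.5, tau_plus=20.0, tau_minus=20.0)


def run_steps(pre_trains, post_trains, n_steps, gate_open, kernels, dt=1.0):
    """Drive step_plasticity over dense spike rasters; returns TraceState."""
    n_pre, n_post = len(pre_trains), len(post_trains)
    traces = TraceState.zeros(n_pre, n_post)
    pre = np.zeros((n_steps, n_pre))
    post = np.zeros((n_steps, n_post))
    for i, ts in enumerate(pre_trains):
        pre[np.asarray(ts, dtype=int), i] = 1
    for j, ts in enumerate(post_trains):
        post[np.asarray(ts, dtype=int), j] = 1
    for t in range(n_steps):
        step_plasticity(traces, pre[t], post[t], gate_open, kernels, dt)
    return traces


class TestTraces:
    def test_pure_decay_over_time(self):
        traces = TraceState.zeros(1, 1)
        traces.x_pre[0] = 1.0
        for _ in range(50):
            ss.update_traces(traces, np.zeros(1), np.zeros(1), 1.0, KERN)
        assert traces.x_pre[0] == pytest.approx(np.exp(-50 / 20.0), rel=1e-12)

    def test_unit_decay_after_one_time_constant(self):
        traces = TraceState.zeros(1, 1)
        ss.update_traces(traces, np.ones(1), np.zeros(1), 1.0, KERN)
        for _ in range(20):
            ss.update_traces(traces, np.zeros(1), np.zeros(1), 1.0, KERN)
        assert traces.x_pre[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_spike_train_matches_direct_exponential_sum(self):
        # spikes at 0, 5, 10 ms with tau=20: e^-0.5 + e^-0.25 + 1 at t=10
        traces = TraceState.zeros(1, 1)
        for t in range(11):
            spikes = np.array([1.0 if t in (0, 5, 10) else 0.0])
            ss.update_traces(traces, spikes, np.zeros(1), 1.0, KERN)
        expected = np.exp(-0.5) + np.exp(-0.25) + 1.0
        assert traces.x_pre[0] == pytest.approx(expected, rel=1e-12)


class TestEligibilityOracle:
    def kernels(self):
        return {REWARD: KERN, PUNISH: ss.KernelParams(-1.0, 0.5, 20.0, 20.0)}

    def test_single_pair_inside_gate(self):
        traces = run_steps([[100]], [[110]], 150, np.ones(1, bool), self.kernels())
        expected = 1.0 * np.exp(-10 / 20.0)
        assert traces.eligibility[REWARD][0, 0] == pytest.approx(expected, rel=1e-12)
        assert traces.eligibility[PUNISH][0, 0] == pytest.approx(-expected, rel=1e-12)

    def test_all_gates_closed_accumulates_nothing(self):
        traces = run_steps([[5, 10]], [[7, 12]], 30, np.zeros(1, bool), self.kernels())
        assert np.all(traces.eligibility[REWARD] == 0)
        assert np.all(traces.eligibility[PUNISH] == 0)

    def test_trace_eligibility_equals_pairwise_sum_on_random_trains(self):
        """Independent oracle: brute-force double sum over all spike pairs."""
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(100):
            n_steps = 400
            pre = np.sort(rng.choice(n_steps, size=rng.integers(1, 40), replace=False))
            post = np.sort(rng.choice(n_steps, size=rng.integers(1, 40), replace=False))
            traces = run_steps(
                [pre], [post], n_steps, np.ones(1, bool), {REWARD: KERN}
            )
            got = traces.eligibility[REWARD][0, 0]
            want = ss.pairwise_eligibility(pre.astype(float), post.astype(float), KERN)
            worst = max(worst, abs(got - want) / max(abs(want), 1e-12))
        assert worst <= 1e-9

    @settings(max_examples=25, deadline=None)
    @given(
        pre=st.lists(st.integers(0, 199), min_size=1, max_size=20, unique=True),
        post=st.lists(st.integers(0, 199), min_size=1, max_size=20, unique=True),
    )
    def test_pairwise_property_holds_for_arbitrary_trains(self, pre, post):
        traces = run_steps([sorted(pre)], [sorted(post)], 200, np.ones(1, bool),
                           {REWARD: KERN})
        want = ss.pairwise_eligibility(np.array(pre, float), np.array(post, float), KERN)
        assert traces.eligibility[REWARD][0, 0] == pytest.approx(want, abs=1e-9, rel=1e-9)


class TestDopamineConversion:
    def test_zero_eligibility_gives_zero_update(self):
        w = np.full((2, 2), 0.5)
        traces = TraceState.zeros(2, 2)
        ss.apply_dopamine(w, traces, REWARD, learning_rate=0.1, w_max=1.0)
        assert np.all(w == 0.5)

    def test_update_is_exactly_learning_rate_times_eligibility(self):
        w = np.zeros((1, 1))
        traces = TraceState.zeros(1, 1)
        traces.eligibility[REWARD][0, 0] = 3.0
        ss.apply_dopamine(w, traces, REWARD, learning_rate=0.01, w_max=10.0)
        assert w[0, 0] == pytest.approx(0.03, rel=1e-15)

    def test_eligibility_consumed_and_weights_clipped(self):
        w = np.full((1, 1), 0.9)
        traces = TraceState.zeros(1, 1)
        traces.eligibility[REWARD][0, 0] = 100.0
        traces.eligibility[PUNISH][0, 0] = -5.0
        ss.apply_dopamine(w, traces, REWARD, 1.0, w_max=1.0)
        assert w[0, 0] == 1.0
        assert np.all(traces.eligibility[REWARD] == 0)
        assert np.all(traces.eligibility[PUNISH] == 0)

    def test_unknown_valence_rejected(self):
        with pytest.raises(ValueError, match="valence"):
            ss.apply_dopamine(np.zeros((1, 1)), TraceState.zeros(1, 1),
                              "surprise", 0.1, 1.0)


class TestThreeFactorNecessity:
    """Factorial check: remove any single factor and the update vanishes."""

    @pytest.mark.parametrize("pre_on", [False, True])
    @pytest.mark.parametrize("post_on", [False, True])
    @pytest.mark.parametrize("gate_on", [False, True])
    @pytest.mark.parametrize("da_on", [False, True])
    def test_update_nonzero_only_with_all_factors(self, pre_on, post_on, gate_on, da_on):
        kernels = {REWARD: KERN, PUNISH: ss.KernelParams(-1.0, 0.5)}
        traces = run_steps(
            [[50] if pre_on else []],
            [[55] if post_on else []],
            80,
            np.array([gate_on]),
            kernels,
        )
        w = np.zeros((1, 1))
        if da_on:
            ss.apply_dopamine(w, traces, REWARD, learning_rate=1.0, w_max=10.0)
        changed = w[0, 0] != 0.0
        assert changed == (pre_on and post_on and gate_on and da_on)


class TestMultiplicativeLTD:
    def test_zero_weight_stays_zero(self):
        w = np.zeros((3, 2))
        ss.multiplicative_ltd(w, np.array([5.0, 9.0]), ss.LTDParams(lam=0.01))
        assert np.all(w == 0)

    def test_fixed_point_matches_closed_form_within_two_percent(self):
        # constant LTP inflow P per episode, constant post activity r:
        # w* = P / (lam * r) to first order
        P, lam, r = 0.02, 2e-4, 25.0
        ltd = ss.LTDParams(lam=lam)
        w = np.zeros((1, 1))
        for _ in range(2000):
            w += P
            ss.multiplicative_ltd(w, np.array([r]), ltd)
        assert w[0, 0] == pytest.approx(P / (lam * r), rel=0.02)

    def test_doubling_lambda_halves_the_asymptote(self):
        P, lam, r = 0.02, 2e-4, 25.0

        def asymptote(l):
            w = np.zeros((1, 1))
            ltd = ss.LTDParams(lam=l)
            for _ in range(3000):
                w += P
                ss.multiplicative_ltd(w, np.array([r]), ltd)
            return w[0, 0]

        assert asymptote(2 * lam) == pytest.approx(asymptote(lam) / 2, rel=0.02)

    def test_overshoot_clamped_at_zero_with_warning(self, caplog):
        w = np.full((1, 1), 0.7)
        with caplog.at_level("WARNING"):
            ss.multiplicative_ltd(w, np.array([2000.0]), ss.LTDParams(lam=1e-3))
        assert w[0, 0] == 0.0
        assert any("clamped" in r.message for r in caplog.records)


class TestModes:
    def test_mode_flags(self):
        assert ss.resolve_mode("classic") == (False, False)
        assert ss.resolve_mode("reward_modulated") == (False, True)
        assert ss.resolve_mode("da_ach_gated") == (True, True)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown plasticity mode"):
            ss.resolve_mode("bogus")

    def test_kernel_table_validation(self):
        with pytest.raises(ValueError, match="potentiating"):
            ss.STDPKernelSpec(d1_reward=ss.KernelParams(-1.0, 0.5))
        with pytest.raises(ValueError, match="time constants"):
            ss.KernelParams(1.0, -0.5, tau_plus=0.0)
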