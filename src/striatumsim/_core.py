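"""Clock-driven inner loop of one trial, jitted with numba.

Leaky integrate-and-fire dynamics with current-based delta synapses, one
step per ``dt``. Recurrent couplings (lateral inhibition, SPN -> action
neuron) act with a one-step delay; feed-forward input spikes act within
their own step. Plasticity traces and per-valence eligibility follow the
order documented in :mod:`striatumsim.plasticity`: decay, pair
contributions against pre-increment traces, then unit increments, so
coincident (Δt = 0) spike pairs contribute nothing.

The jitted function mutates nothing it is handed except its own outputs;
weights are read-only here — eligibility-to-weight conversion happens at
trial end in :mod:`striatumsim.network`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_ACTION_SPIKES = 4096


@njit(cache=True)
def simulate_trial(
    input_spikes,   # uint8 [T, n_in]
    noise,          # float64 [T, n1t + n2t + n_ch]
    w1,             # float64 [n_in, n1t]
    w2,             # float64 [n_in, n2t]
    n_channels,
    n_d1,
    n_d2,
    decay_m,        # exp(-dt/tau_m) for SPNs
    decay_act,      # exp(-dt/tau_m) for action neurons
    th_d1,
    th_d2,
    th_act,
    v_reset,
    ref_steps,
    ref_steps_act,
    w_d1_act,
    w_d2_act,
    w_d2_d1,
    w_d1_d2,
    lat_cross_factor,
    w_act_act,
    hold_steps,
    decay_plus,     # exp(-dt/tau_plus)
    decay_minus,    # exp(-dt/tau_minus)
    amps,           # float64 [2 type, 2 valence, 2 branch(plus, minus)]
    ach_steps,      # gate window length in steps
    gate_always_open,
    record_spikes,
    max_logged_spikes,
):
    T, n_in = input_spikes.shape
    n1t = n_channels * n_d1
    n2t = n_channels * n_d2

    v1 = np.zeros(n1t)
    v2 = np.zeros(n2t)
    va = np.zeros(n_channels)
    r1 = np.zeros(n1t, dtype=np.int64)
    r2 = np.zeros(n2t, dtype=np.int64)
    ra = np.zeros(n_channels, dtype=np.int64)

    x_pre = np.zeros(n_in)
    y1 = np.zeros(n1t)
    y2 = np.zeros(n2t)
    e1r = np.zeros((n_in, n1t))
    e1p = np.zeros((n_in, n1t))
    e2r = np.zeros((n_in, n2t))
    e2p = np.zeros((n_in, n2t))

    gate_until = np.full(n_channels, -1, dtype=np.int64)

    d1_counts = np.zeros(n1t, dtype=np.int64)
    d2_counts = np.zeros(n2t, dtype=np.int64)

    action_t = np.empty(MAX_ACTION_SPIKES, dtype=np.int64)
    action_c = np.empty(MAX_ACTION_SPIKES, dtype=np.int64)
    n_actions = 0

    log_t = np.empty(max_logged_spikes if record_spikes else 0, dtype=np.int64)
    log_id = np.empty(max_logged_spikes if record_spikes else 0, dtype=np.int64)
    log_pop = np.empty(max_logged_spikes if record_spikes else 0, dtype=np.int64)
    n_logged = 0

    # previous-step spike counts driving delayed recurrent couplings
    prev_d1_per_ch = np.zeros(n_channels, dtype=np.int64)
    prev_d2_per_ch = np.zeros(n_channels, dtype=np.int64)
    prev_d1_tot = 0
    prev_d2_tot = 0
    prev_act = np.zeros(n_channels, dtype=np.int64)
    prev_act_tot = 0

    s1 = np.zeros(n1t, dtype=np.uint8)
    s2 = np.zeros(n2t, dtype=np.uint8)
    finite = True

    for t in range(T):
        # --- trace decay -------------------------------------------------
        for i in range(n_in):
            x_pre[i] *= decay_plus
        for j in range(n1t):
            y1[j] *= decay_minus
        for j in range(n2t):
            y2[j] *= decay_minus

        # --- gate state for this step ------------------------------------
        # an action spike at step s opens (s, s+window]: closed at s itself,
        # open for s < t <= s + ach_steps. Computed before this step's
        # action spikes can refresh gate_until.
        open_c = np.zeros(n_channels, dtype=np.uint8)
        for c in range(n_channels):
            if gate_always_open or t <= gate_until[c]:
                open_c[c] = 1

        # --- synaptic input currents + pre-spike eligibility -------------
        cur1 = np.zeros(n1t)
        cur2 = np.zeros(n2t)
        for i in range(n_in):
            if input_spikes[t, i]:
                for j in range(n1t):
                    cur1[j] += w1[i, j]
                for j in range(n2t):
                    cur2[j] += w2[i, j]
                # post-before-pre branch, gated by the post neuron's channel
                for c in range(n_channels):
                    if open_c[c]:
                        for j in range(c * n_d1, (c + 1) * n_d1):
                            e1r[i, j] += amps[0, 0, 1] * y1[j]
                            e1p[i, j] += amps[0, 1, 1] * y1[j]
                        for j in range(c * n_d2, (c + 1) * n_d2):
                            e2r[i, j] += amps[1, 0, 1] * y2[j]
                            e2p[i, j] += amps[1, 1, 1] * y2[j]

        # --- SPN membrane update -----------------------------------------
        # lateral inhibition: full strength within a channel, scaled by
        # lat_cross_factor across channels
        for j in range(n1t):
            c = j // n_d1
            lat1 = -w_d2_d1 * (
                prev_d2_per_ch[c]
                + lat_cross_factor * (prev_d2_tot - prev_d2_per_ch[c])
            )
            if r1[j] > 0:
                r1[j] -= 1
                v1[j] = v_reset
                s1[j] = 0
            else:
                v1[j] = v1[j] * decay_m + cur1[j] + lat1 + noise[t, j]
                if v1[j] >= th_d1:
                    s1[j] = 1
                    v1[j] = v_reset
                    r1[j] = ref_steps
                    d1_counts[j] += 1
                else:
                    s1[j] = 0
        for j in range(n2t):
            c = j // n_d2
            lat2 = -w_d1_d2 * (
                prev_d1_per_ch[c]
                + lat_cross_factor * (prev_d1_tot - prev_d1_per_ch[c])
            )
            if r2[j] > 0:
                r2[j] -= 1
                v2[j] = v_reset
                s2[j] = 0
            else:
                v2[j] = v2[j] * decay_m + cur2[j] + lat2 + noise[t, n1t + j]
                if v2[j] >= th_d2:
                    s2[j] = 1
                    v2[j] = v_reset
                    r2[j] = ref_steps
                    d2_counts[j] += 1
                else:
                    s2[j] = 0

        # --- action neurons (one per channel) ----------------------------
        new_act = np.zeros(n_channels, dtype=np.int64)
        for c in range(n_channels):
            if ra[c] > 0:
                ra[c] -= 1
                va[c] = v_reset
            else:
                drive = (
                    w_d1_act * prev_d1_per_ch[c]
                    - w_d2_act * prev_d2_per_ch[c]
                    - w_act_act * (prev_act_tot - prev_act[c])
                )
                va[c] = va[c] * decay_act + drive + noise[t, n1t + n2t + c]
                if va[c] >= th_act:
                    va[c] = v_reset
                    ra[c] = ref_steps_act
                    new_act[c] = 1
                    if n_actions < MAX_ACTION_SPIKES:
                        action_t[n_actions] = t
                        action_c[n_actions] = c
                        n_actions += 1
                    gate_until[c] = t + ach_steps
                    # motor mutual exclusion: executing an action holds the
                    # other channels' action neurons refractory for a while
                    for c2 in range(n_channels):
                        if c2 != c and ra[c2] < hold_steps:
                            ra[c2] = hold_steps
                    if record_spikes and n_logged < max_logged_spikes:
                        log_t[n_logged] = t
                        log_id[n_logged] = c
                        log_pop[n_logged] = 2
                        n_logged += 1

        # --- post-spike eligibility (pre-increment x_pre) ----------------
        for c in range(n_channels):
            if not open_c[c]:
                continue
            for j in range(c * n_d1, (c + 1) * n_d1):
                if s1[j]:
                    for i in range(n_in):
                        e1r[i, j] += amps[0, 0, 0] * x_pre[i]
                        e1p[i, j] += amps[0, 1, 0] * x_pre[i]
            for j in range(c * n_d2, (c + 1) * n_d2):
                if s2[j]:
                    for i in range(n_in):
                        e2r[i, j] += amps[1, 0, 0] * x_pre[i]
                        e2p[i, j] += amps[1, 1, 0] * x_pre[i]

        # --- trace increments + spike logging ----------------------------
        for i in range(n_in):
            if input_spikes[t, i]:
                x_pre[i] += 1.0
        nd1 = 0
        nd2 = 0
        for c in range(n_channels):
            prev_d1_per_ch[c] = 0
            prev_d2_per_ch[c] = 0
        for j in range(n1t):
            if s1[j]:
                y1[j] += 1.0
                prev_d1_per_ch[j // n_d1] += 1
                nd1 += 1
                if record_spikes and n_logged < max_logged_spikes:
                    log_t[n_logged] = t
                    log_id[n_logged] = j
                    log_pop[n_logged] = 0
                    n_logged += 1
        for j in range(n2t):
            if s2[j]:
                y2[j] += 1.0
                prev_d2_per_ch[j // n_d2] += 1
                nd2 += 1
                if record_spikes and n_logged < max_logged_spikes:
                    log_t[n_logged] = t
                    log_id[n_logged] = j
                    log_pop[n_logged] = 1
                    n_logged += 1
        prev_d1_tot = nd1
        prev_d2_tot = nd2
        prev_act_tot = 0
        for c in range(n_channels):
            prev_act[c] = new_act[c]
            prev_act_tot += new_act[c]

    for j in range(n1t):
        if not np.isfinite(v1[j]):
            finite = False
    for j in range(n2t):
        if not np.isfinite(v2[j]):
            finite = False

    return (
        e1r, e1p, e2r, e2p,
        d1_counts, d2_counts,
        action_t[:n_actions], action_c[:n_actions],
        log_t[:n_logged], log_id[:n_logged], log_pop[:n_logged],
        finite,
    )
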