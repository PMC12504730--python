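"""Channel-gated vs. globally modulated learning on the two-choice task.

Trains the spiking circuit on 2 stimuli / 2 action channels for 400
episodes, once with the full DA+ACh-gated three-factor rule and once with
gate-free (global) reward-modulated STDP, then compares behavioral accuracy
and the stimulus->channel weight structure.
"""

import numpy as np
from dataclasses import replace

import striatumsim as ss

task = ss.TaskConfig(n_channels=2, n_relevant_stimuli=2, n_episodes=400, seed=0)

for mode in ("da_ach_gated", "reward_modulated"):
    net = replace(ss.NetworkConfig(), plasticity_mode=mode)
    run = ss.run_snn_run(task, net, seed=0)
    acc = ss.smooth_accuracy(run.accuracy * 100.0)
    d1 = run.snapshot_d1[-1]  # block means: stimulus population x channel
    eye = np.eye(2, dtype=bool)
    diag, off = d1[eye].mean(), d1[~eye].mean()
    print(f"\n--- plasticity mode: {mode} ---")
    print(f"smoothed accuracy at episode 300: {acc[300]:5.1f} %")
    print(f"final D1 weight means: matched pairs {diag:.3f}, mismatched {off:.3f}")

print(
    "\nWith channel-local ACh gating, only the acting channel's synapses are"
    "\neligible for the dopamine update, so each stimulus wires to its own"
    "\nchannel (large matched/mismatched contrast) and accuracy climbs above"
    "\n80%. Global modulation reinforces both channels alike: weights stay"
    "\noverlapping and the task is not learned."
)
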