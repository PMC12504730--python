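"""Structural credit assignment: 8 distractor stimuli, 2 action channels.

Every trial presents one behaviorally relevant stimulus together with eight
always-on distractors. Only the action mapped to the relevant stimulus is
rewarded, so the network must discover which of nine concurrent inputs
predicts the outcome.
"""

import numpy as np

import striatumsim as ss

task = ss.TaskConfig(
    n_channels=2, n_relevant_stimuli=2, n_distractors=8, n_episodes=1000
)
run = ss.run_snn_run(task, ss.NetworkConfig(), seed=0)
acc = ss.smooth_accuracy(run.accuracy * 100.0)

diff = run.snapshot_d1[-1] - run.snapshot_d2[-1]  # net selectivity D1 - D2
eye = np.eye(2, dtype=bool)
print(f"smoothed accuracy at episode 1000: {acc[-1]:5.1f} % (chance = 50 %)")
print(f"net D1-D2 weight, relevant pairs:   {diff[:2][eye].mean():+.3f}")
print(f"net D1-D2 weight, wrong pairings:   {diff[:2][~eye].mean():+.3f}")
print(f"net D1-D2 weight, distractors:      {diff[2:].mean():+.3f}")
print(
    "\nThe relevant stimulus->action pairs develop the strongest net"
    "\nselectivity; distractor inputs stay intermediate and unspecific, and"
    "\nthe mismatched pairings are suppressed — credit is assigned to the"
    "\ninputs that actually predicted the reward, despite 8:1 sensory"
    "\nambiguity."
)
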