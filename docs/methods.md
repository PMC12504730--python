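# Methods

## Model overview

The circuit is a set of parallel *action channels*. Channel `c` contains a
D1 population (default 20 neurons), a D2 population (20 neurons, enhanced
excitability), and one action neuron. All input neurons project plastically
to every SPN (two dense matrices, one per SPN type). Static wiring: D1 → own
action neuron excitatory, D2 → own action neuron inhibitory; SPN lateral
inhibition with the biological asymmetry D2→D1 > D1→D2, applied at full
strength within a channel and scaled by 0.25 across channels; and mutual
inhibition between action neurons forming a competitive winner-take-all
output stage. An executed action additionally holds the *other* channels'
action neurons refractory for 250 ms ("you cannot execute two movements at
once"); this motor mutual exclusion is what keeps simultaneous
multi-channel responses — which the adjudicator punishes even when one of
them was correct — rare enough for learning to bootstrap.

Neurons are leaky integrate-and-fire with current-based delta synapses,
advanced clock-driven at dt = 1 ms (dimensionless voltage): V ← V·e^(−dt/τm)
+ I + ξ with τm = 10 ms, threshold 1, reset 0, refractory 2 ms (SPNs) /
20 ms (action neurons). D2 excitability is a 10 % threshold reduction
(0.9). ξ is Gaussian background noise per step, σ = 0.20 for SPNs and 0.16
for action neurons; together with the Poisson input spikes it is the model's
only exploration mechanism — there is no explicit ε-greedy in the spiking
agent. Feed-forward input acts within its time step; all recurrent
couplings act with a one-step delay.

## Tasks

Each stimulus owns a disjoint block of 40 input neurons, split into 5
sub-blocks whose 40 Hz activation windows tile the 2 s trial sequentially,
so activity sweeps across the population. Trials present one relevant
stimulus (drawn uniformly) plus all configured distractors (0–8, the same
set every trial). Spikes are Bernoulli per 1 ms bin (p = rate·dt), the
clock-driven Poisson approximation. Responses in the first 200 ms are
premature and ignored. Adjudication: any counted incorrect action ⇒
punishment (even alongside a correct one); reward requires exclusively
correct actions; no counted action ⇒ neither (no DA pulse at all — the
model is not punished for inaction). Reversals permute the
stimulus→action map (swap for two stimuli, cyclic shift beyond) at
configured episodes.

## Plasticity

Traces and eligibility follow a strict per-step order — decay by
e^(−dt/τ); pair contributions computed against the decayed,
not-yet-incremented traces; then +1 increments — so spikes in the same
1 ms bin do not interact, and the accumulated eligibility equals the
brute-force pairwise kernel sum exactly (tested to 1e−9 on random trains).
Eligibility is kept separately per outcome valence because the reward and
punishment kernels differ in amplitude, not just sign; it persists to the
end of the trial (covering the delayed reward) and is zeroed at the trial
boundary.

Kernel amplitude table (A₊ pre→post, A₋ post→pre; τ₊ = τ₋ = 20 ms):

| pathway | reward | punishment |
|---|---|---|
| D1 | +1.0 / −0.5 | −1.0 / +0.5 |
| D2 | −1.0 / +0.5 | +1.0 / −0.5 |

The DA pulse is delivered at the end of the response period (trial end);
since eligibility accumulation has finished by then, delivering it earlier
within the trial would produce the same update. Learning rate η = 0.008;
weights clipped to [0, 1]; initial weights uniform 0.1. Multiplicative LTD
(λ = 2·10⁻⁴ per postsynaptic spike) is applied once per trial from that
trial's spike counts — equivalent to per-step application to first order
and much cheaper.

Three modes support ablation: `classic` (eligibility applied every trial,
no gate, no DA), `reward_modulated` (DA-dependent but gate-free — the
"global modulation" control), and `da_ach_gated` (the full rule). The ACh
gate applies to eligibility *accumulation*; since eligibility is zeroed
every trial and converted at trial end, gating the accumulation or the
conversion is behaviorally equivalent here.

## Why these free parameters

Only the task timing (2 s trials, 200 ms exclusion, 150 ms ACh window,
σ = 10 smoothing, accuracy < 79 % regime) and the experiment sizes are
fixed by design; the circuit gains and kernel amplitudes were set once so
that the model both explores and learns, and then frozen:

- **Full-strength punishment kernels.** With softened D1 punishment the
  distractor task collapses into a one-channel attractor: reward LTP
  accrues to distractor (context) synapses of the winning channel exactly
  as fast as to the relevant pair, so the winner acts on context alone and
  the loser channel never gets rewarded. Error-driven D1 depression at the
  same magnitude as reward LTP erodes exactly those context weights
  (relevant pairs escape it — their stimulus is absent on the other
  stimulus' error trials), which is what makes relevant and distractor
  weights separate.
- **Winner-take-all + action hold.** Without output competition, both
  channels' action neurons eventually fire somewhere in the 1.8 s response
  window, so most trials are punished as mixed even when one action was
  correct, and D1 weights collapse globally.
- **Within-channel-biased lateral inhibition.** A purely global D2→D1 term
  lets the dominant channel's (highly active) D2 population suppress the
  *other* channel's D1 neurons, entrenching the dominance; biasing the
  inhibition within-channel makes a channel's D2 activity oppose its own
  direct pathway instead.
- **D2→action gain (0.4) above D1→action (0.3).** The indirect pathway
  must be able to veto an action whose D1 drive is context-saturated;
  punishment-driven D2 weights for a specific wrong pairing ratchet up
  (they never see reward-depression), which is the stimulus-specific
  suppression signal in the distractor tasks.

## Analyses

Accuracy is the percentage of rewarded trials, smoothed with a reflective
Gaussian filter (σ = 10 episodes). Weight summaries are block means over
(stimulus population × channel); net selectivity is the D1 − D2 block
difference. Power-law fits regress log₁₀(smoothed seed-mean accuracy
fraction, floored at 1/(2·n_seeds)) on log₁₀(episode) over the
accuracy < 0.79 regime; scaling analyses drop the first 3σ episodes, where
the reflective filter provably mixes later (higher-accuracy) episodes into
the early samples and flattens the log-log curve. Paired comparisons use
two-sided paired t-tests with the paired Cohen's d (d_z = mean(diff)/
sd(diff) = t/√n); no multiple-testing correction. Remap time counts
episodes from a reversal until smoothed accuracy, having dropped below the
criterion (pre-reversal 100-episode mean minus 5 points), first re-reaches
it; 0 if it never drops, undefined (NaN) if it never recovers. D2/D1 ratios
compare total spike counts in the 100 episodes before vs. after the
reversal.

## Problem sizes

The shipped experiment presets carry the full-scale settings (10,000
episodes, 50–100 seeds). The test suite and the acceptance script run
scaled-down versions chosen for single-CPU desk use — 5 seeds × 400
episodes (gating), 5 × 1,000 (credit assignment), 10 × 1,200 (reversal),
10 × 8,000 (Q-learning) — which are large enough for every qualitative
contrast and for the paired statistics at p < 0.05, but give wider error
bars than the full-scale runs and weight values on this implementation's
own scale (w_max = 1).

## What the synthetic data does and does not capture

Stimuli are stationary Poisson processes over fixed neuron blocks with a
deterministic sequential envelope; real cortical/hippocampal sequences have
rate fluctuations, overlapping assemblies, and trial-to-trial timing
jitter. Distractors are the same set every trial (constant context), which
is the hardest case for context-driven interference but does not probe
generalization across distractor sets. Dopamine is a fixed-amplitude pulse
regardless of reward history — no reward-prediction-error scaling — so
learned associations are actively erased after reversals rather than
suppressed (no spontaneous recovery), and weights never stop updating at
asymptote. Passing tests therefore demonstrate the credit-assignment and
flexibility properties of the gating mechanism under idealized input
statistics, not quantitative fidelity to in vivo striatal recordings.

## Known limitations

- The one-channel-attractor failure mode is tamed, not eliminated: in the
  8-distractor task individual seeds still acquire the two mappings
  serially, which caps scaled-run accuracy near 60 % at episode 1,000
  (well above the 50 % chance level, with specificity still increasing).
- Neuron and kernel parameters are this implementation's own calibration;
  weight magnitudes are not comparable to other implementations of the
  same architecture.
- The Q-learning baseline's ±1 rewards make its greedy policy independent
  of the learning rate (an elimination process), and on the smallest task
  (N = 4) it leaves the accuracy < 79 % regime within the smoothing
  boundary, so no meaningful power-law fit exists there at these sizes.
- dt = 1 ms quantizes spike timing; STDP contributions between spikes in
  the same bin are defined as zero.
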