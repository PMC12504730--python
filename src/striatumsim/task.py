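"""Behavioral task environment.

Stimuli are spatiotemporal spike patterns: each stimulus owns a disjoint block
of input neurons which it activates in sequential sub-blocks tiling the 2 s
trial. Trials present one behaviorally relevant stimulus (plus optional,
always-on distractor stimuli), collect the agent's channel responses, and
adjudicate them into reward / punishment outcomes. Responses inside the
initial exclusion period are premature and ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "StimulusPattern",
    "StimulusActionMap",
    "TrialOutcome",
    "SpikeEventLog",
    "make_stimulus_patterns",
    "generate_trial_spikes",
    "schedule_trials",
    "initial_action_map",
    "apply_reversal",
    "evaluate_response",
]


class ConfigurationError(ValueError):
    """Raised for invalid task or experiment configurations."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one behavioral task.

    Times are in milliseconds; rates in Hz. ``n_distractors`` distractor
    stimuli are co-presented on every trial alongside the single relevant
    stimulus drawn for that episode.
    """

    n_channels: int = 2
    n_relevant_stimuli: int = 2
    n_distractors: int = 0
    trial_duration: float = 2000.0
    exclusion_period: float = 200.0
    n_episodes: int = 1000
    reversal_episodes: tuple[int, ...] = ()
    input_pop_size_per_stimulus: int = 40
    n_blocks: int = 5
    firing_rate_active: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError("need at least one action channel")
        if self.n_relevant_stimuli < 1:
            raise ConfigurationError("need at least one relevant stimulus")
        if not (0 <= self.n_distractors <= 8):
            raise ConfigurationError("n_distractors must be in 0..8")
        if self.input_pop_size_per_stimulus < 1:
            raise ConfigurationError("input population size must be >= 1")
        if not (self.trial_duration > self.exclusion_period > 0):
            raise ConfigurationError("require trial_duration > exclusion_period > 0")
        if self.n_relevant_stimuli > self.n_channels:
            raise ConfigurationError("more relevant stimuli than action channels")
        if self.n_blocks < 1 or self.n_blocks > self.input_pop_size_per_stimulus:
            raise ConfigurationError("n_blocks must be in 1..input_pop_size_per_stimulus")
        rev = tuple(self.reversal_episodes)
        if any(b <= a for a, b in zip(rev, rev[1:])) or any(
            not (0 <= e < self.n_episodes) for e in rev
        ):
            raise ConfigurationError(
                "reversal episodes must be strictly increasing and < n_episodes"
            )
        if rev and self.n_relevant_stimuli < 2:
            raise ConfigurationError("reversals undefined with a single relevant stimulus")

    @property
    def n_stimuli(self) -> int:
        return self.n_relevant_stimuli + self.n_distractors

    @property
    def n_input_neurons(self) -> int:
        return self.n_stimuli * self.input_pop_size_per_stimulus

    @property
    def relevant_ids(self) -> tuple[int, ...]:
        return tuple(range(self.n_relevant_stimuli))

    @property
    def distractor_ids(self) -> tuple[int, ...]:
        return tuple(range(self.n_relevant_stimuli, self.n_stimuli))


@dataclass(frozen=True)
class StimulusPattern:
    """Spatiotemporal template of one stimulus.

    ``segments`` is an ordered list of ``(lo, hi, onset, offset, rate)``:
    input neurons ``lo..hi-1`` fire Poisson spikes at ``rate`` Hz during
    ``[onset, offset)`` ms. Onsets are non-decreasing (sequential activation).
    """

    stimulus_id: int
    segments: tuple[tuple[int, int, float, float, float], ...]

    @property
    def neuron_range(self) -> tuple[int, int]:
        lo = min(s[0] for s in self.segments)
        hi = max(s[1] for s in self.segments)
        return lo, hi


@dataclass
class StimulusActionMap:
    """Current stimulus -> correct action channel contingency."""

    mapping: dict[int, int]
    epoch: int = 0

    def correct_action(self, stimulus_id: int) -> int:
        return self.mapping[stimulus_id]


@dataclass(frozen=True)
class TrialOutcome:
    """Adjudicated result of one episode."""

    episode: int
    relevant_stimulus: int
    distractors: tuple[int, ...]
    actions_taken: tuple[tuple[int, float], ...]
    rewarded: bool
    punished: bool
    premature_only: bool
    latency_ms: float = float("nan")


@dataclass
class SpikeEventLog:
    """Time-ordered spike events: (time_ms, neuron_id), 0-based indices.

    ``population_tags`` is either a single tag for all events or a per-event
    array of tags.
    """

    times: np.ndarray
    neuron_ids: np.ndarray
    population_tags: "str | np.ndarray" = "input"

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times,
                "neuron_id": self.neuron_ids,
                "population_tag": self.population_tags,
            }
        )

    def to_raster(self, n_steps: int, n_neurons: int, dt: float = 1.0) -> np.ndarray:
        """Bin events into a dense [n_steps, n_neurons] uint8 raster."""
        raster = np.zeros((n_steps, n_neurons), dtype=np.uint8)
        steps = np.floor(self.times / dt).astype(np.intp)
        keep = (steps >= 0) & (steps < n_steps)
        raster[steps[keep], self.neuron_ids[keep].astype(np.intp)] = 1
        return raster


def make_stimulus_patterns(config: TaskConfig) -> list[StimulusPattern]:
    """Build one sequential-activation template per stimulus.

    Each stimulus owns ``input_pop_size_per_stimulus`` consecutive input
    neurons, split into ``n_blocks`` sub-blocks whose activation windows tile
    ``[0, trial_duration)`` in order, so activity sweeps across the population
    over the course of a trial.
    """
    pop = config.input_pop_size_per_stimulus
    patterns: list[StimulusPattern] = []
    block_edges_n = np.linspace(0, pop, config.n_blocks + 1).astype(int)
    block_edges_t = np.linspace(0.0, config.trial_duration, config.n_blocks + 1)
    for s in range(config.n_stimuli):
        base = s * pop
        segs = []
        for b in range(config.n_blocks):
            lo, hi = base + block_edges_n[b], base + block_edges_n[b + 1]
            if hi == lo:
                continue
            segs.append(
                (lo, hi, float(block_edges_t[b]), float(block_edges_t[b + 1]),
                 float(config.firing_rate_active))
            )
        patterns.append(StimulusPattern(stimulus_id=s, segments=tuple(segs)))
    return patterns


def generate_trial_spikes(
    patterns: Sequence[StimulusPattern],
    trial_duration: float,
    rng: np.random.Generator,
    dt: float = 1.0,
) -> SpikeEventLog:
    """Draw one trial's input spikes for the active stimulus patterns.

    Spikes are Bernoulli per time bin with p = rate*dt (clock-driven Poisson
    approximation); at most one spike per neuron per bin. Only neurons of
    active patterns fire. The returned log is sorted by time.
    """
    if patterns:
        ranges = sorted(p.neuron_range for p in patterns)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ranges, ranges[1:]):
            if b_lo < a_hi:
                raise ValueError("active stimulus patterns overlap in neuron indices")
    n_steps = int(round(trial_duration / dt))
    all_steps: list[np.ndarray] = []
    all_ids: list[np.ndarray] = []
    for pat in patterns:
        for lo, hi, onset, offset, rate in pat.segments:
            p = rate * dt / 1000.0
            if p <= 0.0:
                continue
            s0 = int(np.ceil(onset / dt))
            s1 = min(int(np.ceil(offset / dt)), n_steps)
            if s1 <= s0:
                continue
            draws = rng.random((s1 - s0, hi - lo)) < p
            step_idx, neuron_idx = np.nonzero(draws)
            all_steps.append(step_idx + s0)
            all_ids.append(neuron_idx + lo)
    if not all_steps:
        return SpikeEventLog(np.empty(0), np.empty(0, dtype=np.int64))
    steps = np.concatenate(all_steps)
    ids = np.concatenate(all_ids)
    order = np.lexsort((ids, steps))
    return SpikeEventLog((steps[order] * dt).astype(float), ids[order].astype(np.int64))


def schedule_trials(
    config: TaskConfig, rng: np.random.Generator
) -> list[tuple[int, tuple[int, ...]]]:
    """Per-episode (relevant stimulus, distractor set) sequence.

    The relevant stimulus is drawn uniformly; every configured distractor is
    co-presented on every trial.
    """
    if config.n_episodes < 1:
        raise ConfigurationError("n_episodes must be >= 1")
    relevant = rng.integers(0, config.n_relevant_stimuli, size=config.n_episodes)
    distractors = config.distractor_ids
    return [(int(r), distractors) for r in relevant]


def initial_action_map(config: TaskConfig) -> StimulusActionMap:
    """Identity contingency: relevant stimulus i -> channel i."""
    return StimulusActionMap(mapping={s: s for s in config.relevant_ids}, epoch=0)


def apply_reversal(
    action_map: StimulusActionMap, episode: int, config: TaskConfig
) -> StimulusActionMap:
    """Permute the contingency if ``episode`` is a configured reversal point.

    Two relevant stimuli swap their actions; for more, the assignment is
    cyclically shifted (a derangement in both cases). Off-reversal episodes
    return the map unchanged.
    """
    if episode not in config.reversal_episodes:
        return action_map
    if config.n_relevant_stimuli < 2:
        raise ConfigurationError("cannot reverse a single-stimulus contingency")
    stimuli = sorted(action_map.mapping)
    actions = [action_map.mapping[s] for s in stimuli]
    shifted = actions[1:] + actions[:1]  # swap for 2, cyclic shift beyond
    return StimulusActionMap(
        mapping=dict(zip(stimuli, shifted)), epoch=action_map.epoch + 1
    )


def evaluate_response(
    actions: Sequence[tuple[int, float]],
    action_map: StimulusActionMap,
    relevant_stimulus: int,
    distractors: Sequence[int],
    episode: int,
    config: TaskConfig,
) -> TrialOutcome:
    """Adjudicate a trial's channel responses.

    Actions before the exclusion period are premature and discarded. Among
    the remaining actions, any incorrect channel yields punishment (even if a
    correct action also occurred); reward requires exclusively correct
    actions. No counted action at all yields neither reward nor punishment.
    """
    for channel, _t in actions:
        if not (0 <= channel < config.n_channels):
            raise ValueError(f"unknown action channel {channel}")
    times = [t for _c, t in actions]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("actions must be sorted by time")
    correct = action_map.correct_action(relevant_stimulus)
    counted = [(c, t) for c, t in actions if t >= config.exclusion_period]
    rewarded = bool(counted) and all(c == correct for c, _ in counted)
    punished = any(c != correct for c, _ in counted)
    latency = counted[0][1] if counted else float("nan")
    return TrialOutcome(
        episode=episode,
        relevant_stimulus=relevant_stimulus,
        distractors=tuple(distractors),
        actions_taken=tuple((int(c), float(t)) for c, t in actions),
        rewarded=rewarded,
        punished=punished,
        premature_only=(not counted) and bool(actions),
        latency_ms=float(latency),
    )
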