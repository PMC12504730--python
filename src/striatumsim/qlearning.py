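"""Tabular Q-learning baseline on the identical task battery.

The tasks are episodic one-shot decisions (one stimulus, one action,
immediate outcome), i.e. a contextual bandit, so the update drops the
discounted bootstrap term: ``q[s,a] += alpha * (r - q[s,a])``. Action
selection is epsilon-greedy with uniform random tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import TaskConfig, apply_reversal, initial_action_map, schedule_trials

__all__ = ["QLConfig", "QTable", "select_action", "update_q", "run_ql_experiment"]


@dataclass(frozen=True)
class QLConfig:
    alpha: float = 0.1
    epsilon: float = 0.1
    r_reward: float = 1.0
    r_punish: float = -1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.epsilon <= 1):
            raise ValueError("epsilon must be in [0, 1]")


@dataclass
class QTable:
    """Zero-initialized stimulus x action value table."""

    q: np.ndarray
    config: QLConfig = field(default_factory=QLConfig)

    @classmethod
    def zeros(cls, n_stimuli: int, n_actions: int, config: QLConfig | None = None) -> "QTable":
        return cls(q=np.zeros((n_stimuli, n_actions)), config=config or QLConfig())


def select_action(table: QTable, stimulus: int, rng: np.random.Generator) -> int:
    """Epsilon-greedy: explore uniformly with probability epsilon, otherwise
    pick the argmax with ties broken uniformly at random."""
    n_actions = table.q.shape[1]
    if rng.random() < table.config.epsilon:
        return int(rng.integers(n_actions))
    row = table.q[stimulus]
    best = np.nonzero(row == row.max())[0]
    return int(best[rng.integers(best.size)])


def update_q(table: QTable, stimulus: int, action: int, reward: float) -> QTable:
    """Bandit-form value update toward the observed return."""
    table.q[stimulus, action] += table.config.alpha * (reward - table.q[stimulus, action])
    return table


def run_ql_experiment(
    task: TaskConfig,
    ql: QLConfig,
    n_seeds: int,
    base_seed: int = 0,
) -> np.ndarray:
    """Run the agent over the task schedule for several seeds.

    Uses the same schedule generator and reversal bookkeeping as the spiking
    runs. Returns a ``[n_seeds, n_episodes]`` 0/1 correctness array (the
    per-episode accuracy curves before smoothing/averaging).
    """
    correct = np.zeros((n_seeds, task.n_episodes), dtype=np.int8)
    for s in range(n_seeds):
        ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(s,))
        rng_env, rng_agent = (np.random.default_rng(c) for c in ss.spawn(2))
        schedule = schedule_trials(task, rng_env)
        amap = initial_action_map(task)
        table = QTable.zeros(task.n_relevant_stimuli, task.n_channels, ql)
        for ep, (stim, _distr) in enumerate(schedule):
            amap = apply_reversal(amap, ep, task)
            action = select_action(table, stim, rng_agent)
            is_correct = action == amap.correct_action(stim)
            r = ql.r_reward if is_correct else ql.r_punish
            update_q(table, stim, action, r)
            correct[s, ep] = is_correct
    return correct
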