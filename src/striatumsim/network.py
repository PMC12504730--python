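"""Channelized striatal circuit simulation.

Each action channel holds a D1 SPN population (excitatory onto its action
neuron, direct pathway), a D2 SPN population (inhibitory onto it, indirect
pathway, with enhanced excitability), and one action neuron whose spikes
both constitute the behavioral response and open a 150 ms channel-local
acetylcholine gate for plasticity. Lateral inhibition between SPN
populations is asymmetric (D2->D1 stronger than D1->D2). Dopamine pulses
are global: every channel sees the same reward/punishment signal.

Neurons are leaky integrate-and-fire with current-based delta synapses,
advanced clock-driven at ``dt`` (default 1 ms). Exploration comes from the
Poisson input spikes plus Gaussian background noise currents. Network
dynamic state (membranes, traces, gates) resets at trial boundaries; only
the plastic cortico-striatal weights carry across episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _core
from .plasticity import (
    LTDParams,
    STDPKernelSpec,
    REWARD,
    PUNISH,
    multiplicative_ltd,
    resolve_mode,
)
from .task import (
    ConfigurationError,
    SpikeEventLog,
    StimulusActionMap,
    TaskConfig,
    TrialOutcome,
    evaluate_response,
)

__all__ = [
    "NeuronParams",
    "ChannelWiring",
    "DAPulse",
    "ModulatorState",
    "NetworkConfig",
    "NetworkState",
    "SimulationError",
    "TrialLogs",
    "build_network",
    "step_network",
    "on_action_spike",
    "deliver_outcome",
    "run_trial",
]


class SimulationError(RuntimeError):
    """Raised when the simulation reaches an invalid numerical state."""


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire parameters (dimensionless voltage units).

    ``excitability_offset`` lowers the effective threshold; it is nonzero
    for D2 SPNs, whose enhanced excitability supports action suppression.
    """

    tau_m: float = 10.0
    threshold: float = 1.0
    reset: float = 0.0
    resting: float = 0.0
    refractory: float = 2.0
    excitability_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ConfigurationError("membrane time constant must be positive")
        if self.effective_threshold <= self.reset:
            raise ConfigurationError("threshold must exceed reset potential")

    @property
    def effective_threshold(self) -> float:
        return self.threshold - self.excitability_offset


@dataclass(frozen=True)
class ChannelWiring:
    """Static (non-plastic) connectivity of the action-selection circuit."""

    n_channels: int = 2
    n_d1: int = 20
    n_d2: int = 20
    w_d1_act: float = 0.3     # D1 -> own action neuron, excitatory
    w_d2_act: float = 0.4     # D2 -> own action neuron, inhibitory
    w_d2_d1: float = 0.020    # lateral D2 -> D1, within and across channels
    w_d1_d2: float = 0.008    # lateral D1 -> D2, weaker by design
    w_act_act: float = 3.0    # mutual inhibition between action neurons
    #                           (competitive winner-take-all output stage)
    lat_cross_factor: float = 0.25  # cross-channel scaling of SPN lateral inhibition
    action_hold: float = 250.0      # ms other channels' action neurons are held
    #                                 refractory after an executed action

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_d1 < 1 or self.n_d2 < 1:
            raise ConfigurationError("channel and population sizes must be >= 1")
        if any(w < 0 for w in (self.w_d1_act, self.w_d2_act, self.w_d2_d1, self.w_d1_d2)):
            raise ConfigurationError("wiring magnitudes are given as positive numbers")
        if not self.w_d2_d1 > self.w_d1_d2:
            raise ConfigurationError(
                "lateral inhibition must be asymmetric: D2->D1 stronger than D1->D2"
            )


@dataclass(frozen=True)
class DAPulse:
    """A global dopamine transient tagged with its outcome valence."""

    onset: float
    duration: float
    amplitude: float
    valence: str


@dataclass
class ModulatorState:
    """Global dopamine pulses + per-channel ACh gate expiry times (ms)."""

    ach_window: float
    gate_until: np.ndarray
    pulses: list[DAPulse] = field(default_factory=list)

    @classmethod
    def closed(cls, n_channels: int, ach_window: float) -> "ModulatorState":
        return cls(ach_window=ach_window, gate_until=np.full(n_channels, -np.inf))

    def gate_open(self, t: float) -> np.ndarray:
        return t <= self.gate_until

    def reset(self) -> None:
        self.gate_until[:] = -np.inf
        self.pulses.clear()


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameterization of the spiking circuit and its learning rule."""

    wiring: ChannelWiring = ChannelWiring()
    d1_params: NeuronParams = NeuronParams()
    d2_params: NeuronParams = NeuronParams(excitability_offset=0.1)  # Vth -10%
    action_params: NeuronParams = NeuronParams(refractory=20.0)
    dt: float = 1.0
    w_max: float = 1.0
    w_init: float = 0.1
    noise_spn: float = 0.20
    noise_act: float = 0.16
    ach_window: float = 150.0
    learning_rate: float = 0.008
    kernels: STDPKernelSpec = STDPKernelSpec()
    ltd: LTDParams = LTDParams()
    plasticity_mode: str = "da_ach_gated"
    da_amplitude: float = 1.0
    da_duration: float = 50.0

    def __post_init__(self) -> None:
        resolve_mode(self.plasticity_mode)
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not (0 <= self.w_init <= self.w_max):
            raise ConfigurationError("w_init must lie in [0, w_max]")


@dataclass
class NetworkState:
    """Mutable simulation state: membranes, refractoriness, weights, gates."""

    config: NetworkConfig
    n_input: int
    w_d1: np.ndarray   # [n_input, n_channels*n_d1], plastic, in [0, w_max]
    w_d2: np.ndarray   # [n_input, n_channels*n_d2]
    v_d1: np.ndarray
    v_d2: np.ndarray
    v_act: np.ndarray
    refr_d1: np.ndarray
    refr_d2: np.ndarray
    refr_act: np.ndarray
    modulators: ModulatorState
    rng: np.random.Generator
    t: float = 0.0
    action_events: list[tuple[int, float]] = field(default_factory=list)
    _prev_d1_per_ch: np.ndarray = field(default=None, repr=False)
    _prev_d2_per_ch: np.ndarray = field(default=None, repr=False)
    _prev_act_per_ch: np.ndarray = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.config.wiring.n_channels

    def reset_dynamic(self) -> None:
        """Between-trial reset: everything but the plastic weights."""
        for arr in (self.v_d1, self.v_d2, self.v_act):
            arr[:] = 0.0
        for arr in (self.refr_d1, self.refr_d2, self.refr_act):
            arr[:] = 0
        self._prev_d1_per_ch[:] = 0
        self._prev_d2_per_ch[:] = 0
        self._prev_act_per_ch[:] = 0
        self.modulators.reset()
        self.action_events.clear()
        self.t = 0.0


@dataclass
class TrialLogs:
    """Per-trial records returned by :func:`run_trial`."""

    action_spikes: list[tuple[int, float]]
    d1_counts: np.ndarray            # spikes per D1 neuron this trial
    d2_counts: np.ndarray
    gate_intervals: dict[int, list[tuple[float, float]]]
    da_pulse: DAPulse | None
    spike_log: SpikeEventLog | None = None
    input_log: SpikeEventLog | None = None
    eligibility: dict[str, np.ndarray] | None = None

    def d1_counts_per_channel(self, wiring: ChannelWiring) -> np.ndarray:
        return self.d1_counts.reshape(wiring.n_channels, wiring.n_d1).sum(axis=1)

    def d2_counts_per_channel(self, wiring: ChannelWiring) -> np.ndarray:
        return self.d2_counts.reshape(wiring.n_channels, wiring.n_d2).sum(axis=1)


def build_network(
    config: NetworkConfig, n_input: int, seed: int | np.random.Generator = 0
) -> NetworkState:
    """Instantiate the circuit with constant initial weights ``w_init``."""
    if n_input < 1:
        raise ConfigurationError("need at least one input neuron")
    w = config.wiring
    n1t, n2t = w.n_channels * w.n_d1, w.n_channels * w.n_d2
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return NetworkState(
        config=config,
        n_input=n_input,
        w_d1=np.full((n_input, n1t), float(config.w_init)),
        w_d2=np.full((n_input, n2t), float(config.w_init)),
        v_d1=np.zeros(n1t),
        v_d2=np.zeros(n2t),
        v_act=np.zeros(w.n_channels),
        refr_d1=np.zeros(n1t, dtype=np.int64),
        refr_d2=np.zeros(n2t, dtype=np.int64),
        refr_act=np.zeros(w.n_channels, dtype=np.int64),
        modulators=ModulatorState.closed(w.n_channels, config.ach_window),
        rng=rng,
        _prev_d1_per_ch=np.zeros(w.n_channels, dtype=np.int64),
        _prev_d2_per_ch=np.zeros(w.n_channels, dtype=np.int64),
        _prev_act_per_ch=np.zeros(w.n_channels, dtype=np.int64),
    )


def on_action_spike(state: NetworkState, channel: int, t: float) -> ModulatorState:
    """Record an action-neuron spike: the behavioral event plus a refreshed
    (extended, not stacked) ACh gate covering ``(t, t + ach_window]`` in that
    channel only."""
    if not (0 <= channel < state.n_channels):
        raise ValueError(f"unknown channel {channel}")
    state.modulators.gate_until[channel] = t + state.modulators.ach_window
    state.action_events.append((channel, t))
    return state.modulators


def deliver_outcome(
    state: NetworkState, outcome: TrialOutcome, task: TaskConfig
) -> ModulatorState:
    """Schedule the global DA pulse implied by an adjudicated outcome.

    Reward and punishment are delivered after the response period (at trial
    end); trials with no counted response get no pulse at all.
    """
    cfg = state.config
    if outcome.rewarded:
        valence = REWARD
    elif outcome.punished:
        valence = PUNISH
    else:
        return state.modulators
    state.modulators.pulses.append(
        DAPulse(
            onset=task.trial_duration,
            duration=cfg.da_duration,
            amplitude=cfg.da_amplitude,
            valence=valence,
        )
    )
    return state.modulators


def step_network(
    state: NetworkState,
    input_spikes_at_t: np.ndarray | None = None,
    ext_d1: float | np.ndarray = 0.0,
    ext_d2: float | np.ndarray = 0.0,
    ext_act: float | np.ndarray = 0.0,
    noise: bool = True,
) -> dict[str, np.ndarray]:
    """Advance the whole circuit by one ``dt`` step (pure-NumPy path).

    Returns boolean spike vectors per population. Recurrent couplings act
    with a one-step delay; feed-forward input acts within the step. Action
    spikes open their channel's ACh gate via :func:`on_action_spike`.
    """
    cfg = state.config
    w = cfg.wiring
    dt = cfg.dt
    n1t, n2t = w.n_channels * w.n_d1, w.n_channels * w.n_d2
    if input_spikes_at_t is None:
        input_spikes_at_t = np.zeros(state.n_input)
    spikes_in = np.asarray(input_spikes_at_t, dtype=float)

    d2_tot = state._prev_d2_per_ch.sum()
    d1_tot = state._prev_d1_per_ch.sum()
    lat1 = -w.w_d2_d1 * (
        state._prev_d2_per_ch + w.lat_cross_factor * (d2_tot - state._prev_d2_per_ch)
    )
    lat2 = -w.w_d1_d2 * (
        state._prev_d1_per_ch + w.lat_cross_factor * (d1_tot - state._prev_d1_per_ch)
    )
    cur1 = state.w_d1.T @ spikes_in + ext_d1 + np.repeat(lat1, w.n_d1)
    cur2 = state.w_d2.T @ spikes_in + ext_d2 + np.repeat(lat2, w.n_d2)
    if noise:
        cur1 = cur1 + cfg.noise_spn * state.rng.standard_normal(n1t)
        cur2 = cur2 + cfg.noise_spn * state.rng.standard_normal(n2t)

    out: dict[str, np.ndarray] = {}
    for key, v, refr, cur, params in (
        ("d1", state.v_d1, state.refr_d1, cur1, cfg.d1_params),
        ("d2", state.v_d2, state.refr_d2, cur2, cfg.d2_params),
    ):
        in_refr = refr > 0
        refr[in_refr] -= 1
        v[in_refr] = params.reset
        active = ~in_refr
        v[active] = v[active] * np.exp(-dt / params.tau_m) + cur[active]
        spk = active & (v >= params.effective_threshold)
        v[spk] = params.reset
        refr[spk] = int(round(params.refractory / dt))
        out[key] = spk

    ap = cfg.action_params
    drive = (
        w.w_d1_act * state._prev_d1_per_ch
        - w.w_d2_act * state._prev_d2_per_ch
        - w.w_act_act * (state._prev_act_per_ch.sum() - state._prev_act_per_ch)
    ).astype(float) + ext_act
    if noise:
        drive = drive + cfg.noise_act * state.rng.standard_normal(w.n_channels)
    in_refr = state.refr_act > 0
    state.refr_act[in_refr] -= 1
    state.v_act[in_refr] = ap.reset
    active = ~in_refr
    state.v_act[active] = state.v_act[active] * np.exp(-dt / ap.tau_m) + drive[active]
    spk_act = active & (state.v_act >= ap.effective_threshold)
    state.v_act[spk_act] = ap.reset
    state.refr_act[spk_act] = int(round(ap.refractory / dt))
    if spk_act.any():
        hold = int(round(w.action_hold / cfg.dt))
        others = ~spk_act
        state.refr_act[others] = np.maximum(state.refr_act[others], hold)
    out["action"] = spk_act

    if not (np.all(np.isfinite(state.v_d1)) and np.all(np.isfinite(state.v_d2))):
        raise SimulationError("non-finite membrane potential")

    state._prev_d1_per_ch = out["d1"].reshape(w.n_channels, w.n_d1).sum(axis=1)
    state._prev_d2_per_ch = out["d2"].reshape(w.n_channels, w.n_d2).sum(axis=1)
    state._prev_act_per_ch = spk_act.astype(np.int64)
    for c in np.nonzero(spk_act)[0]:
        on_action_spike(state, int(c), state.t)
    state.t += dt
    return out


def _gate_intervals(
    action_spikes: Sequence[tuple[int, float]],
    n_channels: int,
    window: float,
    trial_duration: float,
) -> dict[int, list[tuple[float, float]]]:
    """Merged open-gate intervals (t, t+window] implied by action spikes."""
    intervals: dict[int, list[tuple[float, float]]] = {c: [] for c in range(n_channels)}
    for c, t in sorted(action_spikes, key=lambda x: x[1]):
        end = min(t + window, trial_duration)
        if intervals[c] and t <= intervals[c][-1][1]:
            lo, _ = intervals[c][-1]
            intervals[c][-1] = (lo, end)  # refresh extends, never stacks
        else:
            intervals[c].append((t, end))
    return intervals


def run_trial(
    state: NetworkState,
    trial_spikes: SpikeEventLog,
    action_map: StimulusActionMap,
    relevant_stimulus: int,
    distractors: Sequence[int],
    episode: int,
    task: TaskConfig,
    plasticity_on: bool = True,
    record_spikes: bool = False,
    return_eligibility: bool = False,
    max_logged_spikes: int = 200_000,
) -> tuple[TrialOutcome, TrialLogs]:
    """Simulate one 2 s episode end-to-end and apply plasticity.

    Injects the stimulus spikes, runs the jitted clock-driven loop, collapses
    action-neuron spikes into behavioral responses, adjudicates the outcome,
    delivers the global DA pulse, converts gated eligibility into weight
    changes according to the configured plasticity mode, and applies the
    multiplicative LTD scaling. Dynamic state is reset afterwards; only the
    weights persist.
    """
    cfg = state.config
    w = cfg.wiring
    dt = cfg.dt
    n_steps = int(round(task.trial_duration / dt))
    n1t, n2t = w.n_channels * w.n_d1, w.n_channels * w.n_d2

    raster = trial_spikes.to_raster(n_steps, state.n_input, dt)
    noise = state.rng.standard_normal((n_steps, n1t + n2t + w.n_channels))
    noise[:, : n1t + n2t] *= cfg.noise_spn
    noise[:, n1t + n2t :] *= cfg.noise_act

    gated, da_dependent = resolve_mode(cfg.plasticity_mode)
    kern = cfg.kernels.d1_reward  # shared time constants across the table

    (
        e1r, e1p, e2r, e2p,
        d1_counts, d2_counts,
        action_t, action_c,
        log_t, log_id, log_pop,
        finite,
    ) = _core.simulate_trial(
        raster,
        noise,
        state.w_d1,
        state.w_d2,
        w.n_channels,
        w.n_d1,
        w.n_d2,
        np.exp(-dt / cfg.d1_params.tau_m),
        np.exp(-dt / cfg.action_params.tau_m),
        cfg.d1_params.effective_threshold,
        cfg.d2_params.effective_threshold,
        cfg.action_params.effective_threshold,
        cfg.d1_params.reset,
        int(round(cfg.d1_params.refractory / dt)),
        int(round(cfg.action_params.refractory / dt)),
        w.w_d1_act,
        w.w_d2_act,
        w.w_d2_d1,
        w.w_d1_d2,
        w.lat_cross_factor,
        w.w_act_act,
        int(round(w.action_hold / dt)),
        np.exp(-dt / kern.tau_plus),
        np.exp(-dt / kern.tau_minus),
        cfg.kernels.amplitude_array(),
        int(round(cfg.ach_window / dt)),
        not gated,
        record_spikes,
        max_logged_spikes,
    )
    if not finite:
        raise SimulationError("non-finite membrane potential during trial")

    action_spikes = [(int(c), float(t) * dt) for t, c in zip(action_t, action_c)]
    for c, t in action_spikes:
        on_action_spike(state, c, t)

    # collapse to one behavioral action event per channel: first spike at or
    # after the exclusion period counts; premature spikes are kept only so
    # the adjudicator can flag premature-only trials
    first_counted: dict[int, float] = {}
    first_premature: dict[int, float] = {}
    for c, t in action_spikes:
        if t >= task.exclusion_period:
            first_counted.setdefault(c, t)
        else:
            first_premature.setdefault(c, t)
    collapsed = sorted(
        [(c, t) for c, t in first_premature.items()]
        + [(c, t) for c, t in first_counted.items()],
        key=lambda x: x[1],
    )
    outcome = evaluate_response(
        collapsed, action_map, relevant_stimulus, distractors, episode, task
    )
    deliver_outcome(state, outcome, task)

    if plasticity_on:
        valence = None
        if da_dependent:
            if outcome.rewarded:
                valence = REWARD
            elif outcome.punished:
                valence = PUNISH
        else:
            valence = REWARD  # classic STDP: timing only, applied every trial
        if valence is not None:
            elig1 = e1r if valence == REWARD else e1p
            elig2 = e2r if valence == REWARD else e2p
            state.w_d1 += cfg.learning_rate * elig1
            state.w_d2 += cfg.learning_rate * elig2
            np.clip(state.w_d1, 0.0, cfg.w_max, out=state.w_d1)
            np.clip(state.w_d2, 0.0, cfg.w_max, out=state.w_d2)
        multiplicative_ltd(state.w_d1, d1_counts, cfg.ltd)
        multiplicative_ltd(state.w_d2, d2_counts, cfg.ltd)

    pulses = list(state.modulators.pulses)
    logs = TrialLogs(
        action_spikes=action_spikes,
        d1_counts=d1_counts,
        d2_counts=d2_counts,
        gate_intervals=_gate_intervals(
            action_spikes, w.n_channels, cfg.ach_window, task.trial_duration
        ),
        da_pulse=pulses[0] if pulses else None,
    )
    if record_spikes:
        tags = np.array(["d1", "d2", "action"])
        logs.spike_log = SpikeEventLog(
            times=log_t.astype(float) * dt,
            neuron_ids=log_id,
            population_tags=tags[log_pop],
        )
        logs.input_log = trial_spikes
    if return_eligibility:
        logs.eligibility = {
            "d1_reward": e1r, "d1_punish": e1p,
            "d2_reward": e2r, "d2_punish": e2p,
        }

    state.reset_dynamic()
    return outcome, logs
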