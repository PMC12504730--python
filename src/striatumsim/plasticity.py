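"""Three-factor cortico-striatal plasticity.

Weight changes require the coincidence of (1) pre/post spike-timing structure
captured by exponentially decaying traces, (2) an open channel-local
acetylcholine gate (a brief window following an action-neuron spike), and
(3) a delayed global dopamine pulse whose valence (reward vs. punishment)
selects the STDP kernel. Eligibility is accumulated per synapse and per
valence while a gate is open, then converted to a weight change when dopamine
arrives; a multiplicative postsynaptic LTD term keeps weights bounded.

The functions here are the reference (pure-NumPy) implementation of the rule;
the trial simulator in :mod:`striatumsim._core` applies the identical update
order step by step, and the two are held together by tests.

Update order within one time step of size ``dt`` (spikes at the same step do
not interact, i.e. a Δt=0 pair contributes nothing):

1. decay all traces by ``exp(-dt/τ)``;
2. each presynaptic spike at gated synapses adds ``A_post_pre · y_post``;
3. each postsynaptic spike of a gated neuron adds ``A_pre_post · x_pre``;
4. traces are incremented (+1) for this step's spikes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelParams",
    "STDPKernelSpec",
    "LTDParams",
    "TraceState",
    "PLASTICITY_MODES",
    "resolve_mode",
    "update_traces",
    "accumulate_eligibility",
    "step_plasticity",
    "apply_dopamine",
    "multiplicative_ltd",
    "pairwise_eligibility",
]

logger = logging.getLogger(__name__)

REWARD, PUNISH = "reward", "punish"

#: classic = un-gated, un-modulated STDP; reward_modulated = dopamine-dependent
#: but gate-free (global modulation); da_ach_gated = the full three-factor rule.
PLASTICITY_MODES = ("classic", "reward_modulated", "da_ach_gated")


def resolve_mode(mode: str) -> tuple[bool, bool]:
    """Return ``(gated, da_dependent)`` flags for a plasticity mode name."""
    if mode not in PLASTICITY_MODES:
        raise ValueError(f"unknown plasticity mode {mode!r}; expected one of {PLASTICITY_MODES}")
    return mode == "da_ach_gated", mode != "classic"


@dataclass(frozen=True)
class KernelParams:
    """One STDP kernel: pre-before-post branch ``a_plus`` with decay
    ``tau_plus`` (ms), post-before-pre branch ``a_minus`` with ``tau_minus``.
    Amplitudes are signed and dimensionless."""

    a_plus: float
    a_minus: float
    tau_plus: float = 20.0
    tau_minus: float = 20.0

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")


@dataclass(frozen=True)
class STDPKernelSpec:
    """Kernel table per SPN type x outcome valence.

    Sign conventions: D1 potentiates under reward (consolidating rewarded
    stimulus-action pairs) and depresses under punishment; D2 shows the
    mirrored pattern, potentiating under punishment so the indirect pathway
    learns to suppress actions that led to bad outcomes.
    """

    d1_reward: KernelParams = KernelParams(+1.0, -0.5)
    d1_punish: KernelParams = KernelParams(-1.0, +0.5)
    d2_reward: KernelParams = KernelParams(-1.0, +0.5)
    d2_punish: KernelParams = KernelParams(+1.0, -0.5)

    def __post_init__(self) -> None:
        if self.d1_reward.a_plus <= 0:
            raise ValueError("D1 reward pre->post branch must be potentiating")

    def for_type(self, spn_type: str, valence: str) -> KernelParams:
        try:
            return getattr(self, f"{spn_type}_{valence}")
        except AttributeError:
            raise ValueError(f"unknown kernel selector ({spn_type!r}, {valence!r})") from None

    def amplitude_array(self) -> np.ndarray:
        """[type(d1,d2), valence(reward,punish), branch(plus,minus)] floats."""
        out = np.empty((2, 2, 2))
        for i, t in enumerate(("d1", "d2")):
            for j, v in enumerate((REWARD, PUNISH)):
                k = self.for_type(t, v)
                out[i, j] = (k.a_plus, k.a_minus)
        return out


@dataclass(frozen=True)
class LTDParams:
    """Multiplicative LTD: each weight is scaled by ``1 - lam * activity`` of
    its postsynaptic neuron once per trial (``lam`` in 1/spike)."""

    lam: float = 2e-4

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("LTD coefficient must be >= 0")


@dataclass
class TraceState:
    """Pre/post traces and per-valence eligibility for one SPN population."""

    x_pre: np.ndarray
    y_post: np.ndarray
    eligibility: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(
            x_pre=np.zeros(n_pre),
            y_post=np.zeros(n_post),
            eligibility={
                REWARD: np.zeros((n_pre, n_post)),
                PUNISH: np.zeros((n_pre, n_post)),
            },
        )

    def reset(self) -> None:
        self.x_pre[:] = 0.0
        self.y_post[:] = 0.0
        for e in self.eligibility.values():
            e[:] = 0.0


def update_traces(
    traces: TraceState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    dt: float,
    kernel: KernelParams,
) -> TraceState:
    """Advance spike traces one step: exponential decay plus unit increments.

    ``pre_spikes`` / ``post_spikes`` are 0/1 (or count) vectors for this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    traces.x_pre *= np.exp(-dt / kernel.tau_plus)
    traces.y_post *= np.exp(-dt / kernel.tau_minus)
    traces.x_pre += pre_spikes
    traces.y_post += post_spikes
    return traces


def accumulate_eligibility(
    traces: TraceState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    gate_open: np.ndarray,
    kernels: dict[str, KernelParams],
) -> TraceState:
    """Add this step's spike-pairing contributions to gated eligibility.

    Must be called after trace decay but *before* the trace increments for
    this step's spikes (see module docstring); ``gate_open`` is a boolean
    mask over postsynaptic neurons (True where the neuron's channel has an
    open ACh gate). Ungated neurons accumulate nothing.
    """
    gate = np.asarray(gate_open, dtype=bool)
    pre_idx = np.nonzero(pre_spikes)[0]
    post_idx = np.nonzero(np.asarray(post_spikes, dtype=bool) & gate)[0]
    for valence, kern in kernels.items():
        elig = traces.eligibility[valence]
        if pre_idx.size:
            elig[np.ix_(pre_idx, np.nonzero(gate)[0])] += (
                kern.a_minus * traces.y_post[gate]
            )
        if post_idx.size:
            elig[:, post_idx] += kern.a_plus * traces.x_pre[:, None]
    return traces


def apply_dopamine(
    weights: np.ndarray,
    traces: TraceState,
    valence: str,
    learning_rate: float,
    w_max: float,
) -> np.ndarray:
    """Convert accumulated eligibility into a weight change.

    ``Δw = η · e_valence`` (kernel signs already live in the eligibility),
    clipped to ``[0, w_max]``. The consumed eligibility is zeroed.
    """
    if valence not in traces.eligibility:
        raise ValueError(f"unknown dopamine valence {valence!r}")
    weights += learning_rate * traces.eligibility[valence]
    np.clip(weights, 0.0, w_max, out=weights)
    for e in traces.eligibility.values():
        e[:] = 0.0
    return weights


def multiplicative_ltd(
    weights: np.ndarray, post_activity: np.ndarray, ltd: LTDParams
) -> np.ndarray:
    """Scale each column by ``1 - lam * activity`` of its postsynaptic neuron.

    Homeostatic depression proportional to the current weight; factors that
    would go negative are clamped at zero (with a warning) so weights stay in
    ``[0, w_max]``.
    """
    activity = np.asarray(post_activity, dtype=float)
    if np.any(activity < 0):
        raise ValueError("postsynaptic activity must be >= 0")
    factor = 1.0 - ltd.lam * activity
    if np.any(factor < 0):
        logger.warning("multiplicative LTD factor clamped at 0 (lam*activity > 1)")
        factor = np.maximum(factor, 0.0)
    weights *= factor[None, :]
    return weights


def step_plasticity(
    traces: TraceState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    gate_open: np.ndarray,
    kernels: dict[str, KernelParams],
    dt: float,
) -> TraceState:
    """One full plasticity step in the documented order.

    Decays traces, accumulates gated eligibility from this step's spikes
    against the decayed-but-not-yet-incremented traces, then increments the
    traces. All kernels are assumed to share their time constants (the trace
    pair is common to the valence-specific amplitude tables).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    kern0 = next(iter(kernels.values()))
    traces.x_pre *= np.exp(-dt / kern0.tau_plus)
    traces.y_post *= np.exp(-dt / kern0.tau_minus)
    accumulate_eligibility(traces, pre_spikes, post_spikes, gate_open, kernels)
    traces.x_pre += pre_spikes
    traces.y_post += post_spikes
    return traces


def pairwise_eligibility(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    kernel: KernelParams,
) -> float:
    """Brute-force pairwise STDP sum for one synapse (independent oracle).

    Sums ``a_plus·exp(-Δt/τ_plus)`` over every (pre, post) pair with the post
    spike strictly later, and ``a_minus·exp(-Δt/τ_minus)`` over pairs with
    the pre spike strictly later. Coincident spikes contribute nothing,
    matching the step convention of :func:`accumulate_eligibility`.
    """
    pre = np.asarray(pre_times, dtype=float)[:, None]
    post = np.asarray(post_times, dtype=float)[None, :]
    dt = post - pre
    total = kernel.a_plus * np.exp(-dt[dt > 0] / kernel.tau_plus).sum()
    total += kernel.a_minus * np.exp(dt[dt < 0] / kernel.tau_minus).sum()
    return float(total)
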