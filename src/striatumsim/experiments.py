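"""Experiment presets, seed management, and artifact plumbing.

Named presets cover the model's experimental settings:

``baseline``
    two stimuli mapped to two action channels, no distractors or reversals,
    10,000 episodes;
``credit_assignment``
    relevant stimuli plus 0-8 always-on distractors, 2 channels, 100 seeds;
``reversal_single``
    a single contingency reversal at episode 500, 8 distractors, 50 seeds;
``reversal_repeated``
    reversals every 2,000 episodes over 10,000;
``scaling``
    N relevant stimuli / N channels for N in {4, 8, 16, 32}, no distractors,
    run with either the spiking agent or the tabular Q-learning baseline.

Full-scale presets carry the full experiment sizes; :func:`scale_preset` derives
smaller copies for quick runs. Randomness is split per (seed, component)
with ``numpy.random.SeedSequence`` spawn keys so the environment and the
network noise are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from . import analysis
from .network import NetworkConfig, build_network, run_trial
from .plasticity import KernelParams, LTDParams, STDPKernelSpec
from .qlearning import QLConfig, run_ql_experiment
from .task import (
    ConfigurationError,
    TaskConfig,
    apply_reversal,
    generate_trial_spikes,
    initial_action_map,
    make_stimulus_patterns,
    schedule_trials,
)

__all__ = [
    "ExperimentPreset",
    "SimRun",
    "PRESETS",
    "get_preset",
    "scale_preset",
    "scaling_preset",
    "load_config",
    "dump_config",
    "run_snn_run",
    "run_experiment",
    "report",
]

PRESET_NAMES = (
    "baseline",
    "credit_assignment",
    "reversal_single",
    "reversal_repeated",
    "scaling",
)


@dataclass(frozen=True)
class ExperimentPreset:
    """A named, fully resolved experiment configuration."""

    name: str
    task: TaskConfig
    network: NetworkConfig = NetworkConfig()
    ql: QLConfig = QLConfig()
    agent: str = "snn"
    plasticity_mode: str = "da_ach_gated"
    n_seeds: int = 1
    snapshot_every: int = 10

    def __post_init__(self) -> None:
        if self.agent not in ("snn", "ql"):
            raise ConfigurationError("agent must be 'snn' or 'ql'")
        if self.n_seeds < 1:
            raise ConfigurationError("n_seeds must be >= 1")
        if self.plasticity_mode != self.network.plasticity_mode:
            object.__setattr__(
                self, "network", replace(self.network, plasticity_mode=self.plasticity_mode)
            )


def _base_presets() -> dict[str, ExperimentPreset]:
    two_ch = dict(n_channels=2, n_relevant_stimuli=2)
    return {
        "baseline": ExperimentPreset(
            name="baseline",
            task=TaskConfig(**two_ch, n_distractors=0, n_episodes=10_000),
            n_seeds=1,
        ),
        "credit_assignment": ExperimentPreset(
            name="credit_assignment",
            task=TaskConfig(**two_ch, n_distractors=8, n_episodes=10_000),
            n_seeds=100,
        ),
        "reversal_single": ExperimentPreset(
            name="reversal_single",
            task=TaskConfig(
                **two_ch, n_distractors=8, n_episodes=2_000, reversal_episodes=(500,)
            ),
            n_seeds=50,
        ),
        "reversal_repeated": ExperimentPreset(
            name="reversal_repeated",
            task=TaskConfig(
                **two_ch,
                n_distractors=8,
                n_episodes=10_000,
                reversal_episodes=(2_000, 4_000, 6_000, 8_000),
            ),
            n_seeds=1,
        ),
        "scaling": scaling_preset(4),
    }


def scaling_preset(n_actions: int, agent: str = "ql", n_episodes: int = 5_000) -> ExperimentPreset:
    """N actions <-> N relevant stimuli <-> N channels, no distractors."""
    return ExperimentPreset(
        name="scaling",
        task=TaskConfig(
            n_channels=n_actions,
            n_relevant_stimuli=n_actions,
            n_distractors=0,
            n_episodes=n_episodes,
        ),
        agent=agent,
        n_seeds=10,
    )


PRESETS: dict[str, ExperimentPreset] = _base_presets()


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
        ) from None


def scale_preset(
    preset: ExperimentPreset,
    n_episodes: int | None = None,
    n_seeds: int | None = None,
    reversal_episodes: tuple[int, ...] | None = None,
    n_distractors: int | None = None,
) -> ExperimentPreset:
    """Derive a reduced copy of a preset (fewer episodes/seeds) for quick runs."""
    task_kw: dict[str, Any] = {}
    if n_episodes is not None:
        task_kw["n_episodes"] = n_episodes
        if reversal_episodes is None:
            task_kw["reversal_episodes"] = tuple(
                e for e in preset.task.reversal_episodes if e < n_episodes
            )
    if reversal_episodes is not None:
        task_kw["reversal_episodes"] = reversal_episodes
    if n_distractors is not None:
        task_kw["n_distractors"] = n_distractors
    return replace(
        preset,
        task=replace(preset.task, **task_kw) if task_kw else preset.task,
        n_seeds=preset.n_seeds if n_seeds is None else n_seeds,
    )


# --------------------------------------------------------------------------
# config file round-trip

def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(x) for x in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _from_dict(cls: type, data: dict[str, Any], path: str = "") -> Any:
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in field_map:
            raise ConfigurationError(f"unknown config key {path + key!r} for {cls.__name__}")
        target = _NESTED.get((cls.__name__, key))
        if target is not None and isinstance(value, dict):
            kwargs[key] = _from_dict(target, value, path=f"{path}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


from .network import ChannelWiring, NeuronParams  # noqa: E402  (config schema)

_NESTED: dict[tuple[str, str], type] = {
    ("ExperimentPreset", "task"): TaskConfig,
    ("ExperimentPreset", "network"): NetworkConfig,
    ("ExperimentPreset", "ql"): QLConfig,
    ("NetworkConfig", "wiring"): ChannelWiring,
    ("NetworkConfig", "d1_params"): NeuronParams,
    ("NetworkConfig", "d2_params"): NeuronParams,
    ("NetworkConfig", "action_params"): NeuronParams,
    ("NetworkConfig", "kernels"): STDPKernelSpec,
    ("NetworkConfig", "ltd"): LTDParams,
    ("STDPKernelSpec", "d1_reward"): KernelParams,
    ("STDPKernelSpec", "d1_punish"): KernelParams,
    ("STDPKernelSpec", "d2_reward"): KernelParams,
    ("STDPKernelSpec", "d2_punish"): KernelParams,
}


def load_config(path: str | Path) -> ExperimentPreset:
    """Load an experiment preset from a YAML file.

    The file names a preset and may override any nested field; unknown keys
    are rejected with a descriptive error.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict) or "preset" not in raw:
        raise ConfigurationError("config file must be a mapping with a 'preset' key")
    base = _to_dict(get_preset(raw.pop("preset")))

    def merge(dst: dict, src: dict, path: str = "") -> dict:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v, path=f"{path}{k}.")
            else:
                dst[k] = v
        return dst

    merge(base, raw)
    return _from_dict(ExperimentPreset, base)


def dump_config(preset: ExperimentPreset, path: str | Path) -> None:
    data = _to_dict(preset)
    data["preset"] = data.pop("name")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(preset: ExperimentPreset) -> str:
    return hashlib.sha256(
        json.dumps(_to_dict(preset), sort_keys=True).encode()
    ).hexdigest()[:16]


# --------------------------------------------------------------------------
# simulation drivers

@dataclass
class SimRun:
    """In-memory result of one seeded spiking-network run."""

    outcomes: pd.DataFrame
    snapshot_episodes: np.ndarray
    snapshot_d1: np.ndarray        # [n_snap, n_stimuli, n_channels] block means
    snapshot_d2: np.ndarray
    final_w_d1: np.ndarray         # full plastic matrices at end of run
    final_w_d2: np.ndarray
    d1_counts: np.ndarray          # [n_episodes, n_channels] spikes per trial
    d2_counts: np.ndarray
    mapping_history: list[tuple[int, dict[int, int]]]

    @property
    def accuracy(self) -> np.ndarray:
        return self.outcomes["rewarded"].to_numpy(dtype=float)


def component_rngs(base_seed: int, seed_index: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent (environment, network) RNG streams for one run."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(seed_index,))
    env_ss, net_ss = ss.spawn(2)
    return np.random.default_rng(env_ss), np.random.default_rng(net_ss)


def run_snn_run(
    task: TaskConfig,
    network: NetworkConfig,
    seed: int,
    seed_index: int = 0,
    snapshot_every: int = 10,
) -> SimRun:
    """Run the spiking agent for one seed over the full episode schedule."""
    rng_env, rng_net = component_rngs(seed, seed_index)
    patterns = make_stimulus_patterns(task)
    schedule = schedule_trials(task, rng_env)
    amap = initial_action_map(task)
    state = build_network(network, task.n_input_neurons, rng_net)
    wiring = network.wiring

    rows = []
    snap_eps, snap_d1, snap_d2 = [], [], []
    d1_counts = np.zeros((task.n_episodes, wiring.n_channels), dtype=np.int64)
    d2_counts = np.zeros((task.n_episodes, wiring.n_channels), dtype=np.int64)
    mapping_history = [(0, dict(amap.mapping))]

    for ep, (stim, distractors) in enumerate(schedule):
        new_map = apply_reversal(amap, ep, task)
        if new_map.epoch != amap.epoch:
            mapping_history.append((ep, dict(new_map.mapping)))
        amap = new_map
        active = [patterns[stim]] + [patterns[d] for d in distractors]
        spikes = generate_trial_spikes(active, task.trial_duration, rng_env, network.dt)
        outcome, logs = run_trial(
            state, spikes, amap, stim, distractors, ep, task
        )
        counted = [(c, t) for c, t in outcome.actions_taken if t >= task.exclusion_period]
        rows.append(
            {
                "episode": ep,
                "relevant_stimulus": stim,
                "action": counted[0][0] if counted else -1,
                "latency_ms": outcome.latency_ms,
                "rewarded": outcome.rewarded,
                "punished": outcome.punished,
                "correct_action": amap.correct_action(stim),
                "epoch": amap.epoch,
            }
        )
        d1_counts[ep] = logs.d1_counts_per_channel(wiring)
        d2_counts[ep] = logs.d2_counts_per_channel(wiring)
        if ep % snapshot_every == 0 or ep == task.n_episodes - 1:
            summ = analysis.weight_summary(
                state.w_d1, state.w_d2,
                task.input_pop_size_per_stimulus, wiring.n_d1, wiring.n_d2,
            )
            snap_eps.append(ep)
            snap_d1.append(summ.d1)
            snap_d2.append(summ.d2)

    return SimRun(
        outcomes=pd.DataFrame(rows),
        snapshot_episodes=np.array(snap_eps),
        snapshot_d1=np.stack(snap_d1),
        snapshot_d2=np.stack(snap_d2),
        final_w_d1=state.w_d1.copy(),
        final_w_d2=state.w_d2.copy(),
        d1_counts=d1_counts,
        d2_counts=d2_counts,
        mapping_history=mapping_history,
    )


def run_experiment(
    preset: ExperimentPreset,
    out_dir: str | Path,
    base_seed: int = 0,
    resume: bool = True,
) -> Path:
    """Run every seed of a preset, writing one artifact set per seed.

    Artifacts per seed: ``outcomes_seed{k}.csv`` (one row per episode) and,
    for the spiking agent, ``weights_seed{k}.h5`` (block-mean snapshots plus
    final matrices) and ``counts_seed{k}.csv`` (per-trial D1/D2 spike counts
    per channel). A ``manifest.json`` records the resolved config, its hash,
    and the seed list. Existing per-seed outputs are skipped when resuming.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = list(range(base_seed, base_seed + preset.n_seeds))
    for idx, seed in enumerate(seeds):
        csv_path = out / f"outcomes_seed{seed}.csv"
        if resume and csv_path.exists():
            continue
        if preset.agent == "ql":
            correct = run_ql_experiment(preset.task, preset.ql, 1, base_seed=seed)[0]
            pd.DataFrame(
                {"episode": np.arange(preset.task.n_episodes), "rewarded": correct.astype(bool)}
            ).to_csv(csv_path, index=False)
            continue
        run = run_snn_run(
            preset.task, preset.network, seed,
            snapshot_every=preset.snapshot_every,
        )
        run.outcomes.to_csv(csv_path, index=False)
        counts = pd.DataFrame(
            np.hstack([run.d1_counts, run.d2_counts]),
            columns=[f"d1_ch{c}" for c in range(run.d1_counts.shape[1])]
            + [f"d2_ch{c}" for c in range(run.d2_counts.shape[1])],
        )
        counts.insert(0, "episode", np.arange(preset.task.n_episodes))
        counts.to_csv(out / f"counts_seed{seed}.csv", index=False)
        with h5py.File(out / f"weights_seed{seed}.h5", "w") as h5:
            h5.create_dataset("snapshot_episodes", data=run.snapshot_episodes)
            h5.create_dataset("snapshot_d1", data=run.snapshot_d1)
            h5.create_dataset("snapshot_d2", data=run.snapshot_d2)
            h5.create_dataset("final_w_d1", data=run.final_w_d1)
            h5.create_dataset("final_w_d2", data=run.final_w_d2)
    manifest = {
        "preset": _to_dict(preset),
        "config_hash": config_hash(preset),
        "seeds": seeds,
        "n_episodes": preset.task.n_episodes,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def report(bundle_dir: str | Path) -> dict[str, Any]:
    """Summarize an experiment bundle into headline statistics.

    Reads the manifest and per-seed artifacts, computes seed-averaged
    smoothed accuracy, final weight-summary contrasts and, when the preset
    includes reversals, the reversal statistics (paired t, Cohen's d, remap
    time, D2/D1 ratio change). Writes and returns ``summary.json``.
    """
    out = Path(bundle_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    preset = _from_dict(ExperimentPreset, manifest["preset"])
    seeds = manifest["seeds"]
    missing = [
        s for s in seeds if not (out / f"outcomes_seed{s}.csv").exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing outcome files for seeds {missing}")

    curves = np.stack(
        [
            pd.read_csv(out / f"outcomes_seed{s}.csv")["rewarded"]
            .to_numpy(dtype=float)
            for s in seeds
        ]
    )
    mean_curve = analysis.smooth_accuracy(curves.mean(axis=0) * 100.0)
    summary: dict[str, Any] = {
        "preset": preset.name,
        "agent": preset.agent,
        "n_seeds": len(seeds),
        "final_accuracy_pct": float(mean_curve[-1]),
        "mean_accuracy_pct": float(mean_curve.mean()),
    }

    if preset.agent == "snn":
        diag, offdiag = [], []
        for s in seeds:
            with h5py.File(out / f"weights_seed{s}.h5", "r") as h5:
                d1 = h5["snapshot_d1"][-1]
            n_rel = preset.task.n_relevant_stimuli
            eye = np.eye(n_rel, dtype=bool)
            diag.append(d1[:n_rel, :][eye].mean())
            offdiag.append(d1[:n_rel, :][~eye].mean())
        summary["d1_diagonal_mean"] = float(np.mean(diag))
        summary["d1_offdiagonal_mean"] = float(np.mean(offdiag))

    if preset.task.reversal_episodes and preset.agent == "snn":
        summary["reversal"] = _reversal_stats(out, preset, seeds)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _reversal_stats(out: Path, preset: ExperimentPreset, seeds: list[int]) -> dict[str, Any]:
    """Per-seed reversal measures aggregated with paired statistics."""
    task = preset.task
    rev = task.reversal_episodes[0]
    window = min(100, rev, max(task.n_episodes - rev - 1, 1))
    pre_correct, pre_distr, new_final, old_final = [], [], [], []
    ratio_pre, ratio_post, remap = [], [], []
    n_rel = task.n_relevant_stimuli
    for s in seeds:
        with h5py.File(out / f"weights_seed{s}.h5", "r") as h5:
            eps = h5["snapshot_episodes"][:]
            d1 = h5["snapshot_d1"][:]
            d2 = h5["snapshot_d2"][:]
        diff = d1 - d2
        pre_idx = int(np.searchsorted(eps, rev) - 1)
        eye = np.eye(n_rel, dtype=bool)
        pre_correct.append(diff[pre_idx, :n_rel, :][eye].mean())
        pre_distr.append(
            diff[pre_idx, n_rel:, :].mean() if task.n_distractors else float("nan")
        )
        # after a two-stimulus swap the new correct pairs are the off-diagonal
        new_final.append(diff[-1, :n_rel, :][~eye].mean())
        old_final.append(diff[-1, :n_rel, :][eye].mean())

        counts = pd.read_csv(out / f"counts_seed{s}.csv")
        d1c = counts[[c for c in counts if c.startswith("d1_")]].to_numpy().sum(axis=1)
        d2c = counts[[c for c in counts if c.startswith("d2_")]].to_numpy().sum(axis=1)
        ratio_pre.append(analysis.d2_d1_ratio(d2c[rev - window : rev], d1c[rev - window : rev]))
        ratio_post.append(
            analysis.d2_d1_ratio(d2c[rev + 1 : rev + 1 + window], d1c[rev + 1 : rev + 1 + window])
        )

        acc = pd.read_csv(out / f"outcomes_seed{s}.csv")["rewarded"].to_numpy(dtype=float)
        remap.append(analysis.remap_time(analysis.smooth_accuracy(acc * 100.0), rev))

    weights_test = analysis.paired_stats(np.array(pre_correct), np.array(pre_distr))
    ratio_test = analysis.paired_stats(np.array(ratio_pre), np.array(ratio_post))
    final_test = analysis.paired_stats(np.array(new_final), np.array(old_final))
    remap_arr = np.array(remap)
    return {
        "pre_correct_mean": float(np.mean(pre_correct)),
        "pre_distractor_mean": float(np.mean(pre_distr)),
        "pre_weights_t": weights_test.t,
        "pre_weights_p": weights_test.p,
        "pre_weights_d": weights_test.d,
        "d2d1_ratio_pre": float(np.mean(ratio_pre)),
        "d2d1_ratio_post": float(np.mean(ratio_post)),
        "d2d1_ratio_t": ratio_test.t,
        "d2d1_ratio_p": ratio_test.p,
        "new_correct_final": float(np.mean(new_final)),
        "old_correct_final": float(np.mean(old_final)),
        "final_weights_t": final_test.t,
        "final_weights_p": final_test.p,
        "remap_time_mean": float(np.nanmean(remap_arr)),
        "remap_time_sd": float(np.nanstd(remap_arr, ddof=1)) if len(remap_arr) > 1 else float("nan"),
        "remap_undefined": int(np.isnan(remap_arr).sum()),
    }
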