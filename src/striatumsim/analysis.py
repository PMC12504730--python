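"""Quantitative analyses of simulated behavior and synaptic state.

Covers the evaluation statistics for this model family: Gaussian-smoothed
accuracy curves (sigma = 10 episodes), per-block weight-matrix summaries
(stimulus population x action channel, D1, D2 and D1-D2), power-law fits of
the low-accuracy regime of learning curves (accuracy < 79%, i.e.
log10(accuracy) < -0.1), paired t-tests with the paired Cohen's d
(d_z = mean(diff)/sd(diff) = t/sqrt(n)), post-reversal remapping times, and
D2/D1 activity ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "WeightSummary",
    "PowerLawFit",
    "PairedStats",
    "smooth_accuracy",
    "weight_summary",
    "powerlaw_fit",
    "paired_stats",
    "remap_time",
    "d2_d1_ratio",
]


def smooth_accuracy(series: np.ndarray, sigma: float = 10.0) -> np.ndarray:
    """Gaussian-filter a per-episode series (sigma in episode units).

    Reflective boundary handling preserves the series length and keeps a
    constant series exactly constant.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 1:
        raise ValueError("series must be a non-empty 1-D array")
    return ndimage.gaussian_filter1d(series, sigma=sigma, mode="reflect")


@dataclass(frozen=True)
class WeightSummary:
    """Block means per (stimulus population x action channel)."""

    d1: np.ndarray
    d2: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        """Net pathway selectivity D1 - D2, computed on the block means."""
        return self.d1 - self.d2


def weight_summary(
    w_d1: np.ndarray,
    w_d2: np.ndarray,
    pop_size: int,
    n_d1: int,
    n_d2: int,
) -> WeightSummary:
    """Average the full weight matrices into stimulus x channel blocks.

    Row blocks are consecutive stimulus input populations of ``pop_size``
    neurons; column blocks are consecutive per-channel SPN populations.
    """
    def block_means(w: np.ndarray, cols_per_ch: int) -> np.ndarray:
        n_in, n_post = w.shape
        if n_in % pop_size or n_post % cols_per_ch:
            raise ValueError("matrix shape does not tile into the given blocks")
        n_stim, n_ch = n_in // pop_size, n_post // cols_per_ch
        if n_stim == 0 or n_ch == 0 or pop_size == 0 or cols_per_ch == 0:
            raise ValueError("empty blocks in weight summary")
        return w.reshape(n_stim, pop_size, n_ch, cols_per_ch).mean(axis=(1, 3))

    return WeightSummary(d1=block_means(w_d1, n_d1), d2=block_means(w_d2, n_d2))


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    threshold: float


def powerlaw_fit(
    accuracy: np.ndarray,
    episodes: np.ndarray | None = None,
    threshold: float = 0.79,
    min_episode: float = 0.0,
) -> PowerLawFit:
    """OLS fit of log10(accuracy) on log10(episode) in the low-accuracy regime.

    ``accuracy`` is a smoothed curve as a fraction in (0, 1]; only points
    strictly below ``threshold`` (the early, power-law portion of learning)
    enter the fit. Episode indices default to 1..len(accuracy).

    ``min_episode`` additionally excludes the earliest episodes: with a
    reflective Gaussian filter the first ~3 sigma samples average in later
    (higher-accuracy) episodes, flattening the log-log curve, so scaling
    analyses fit from 3 sigma onward.
    """
    accuracy = np.asarray(accuracy, dtype=float)
    if episodes is None:
        episodes = np.arange(1, accuracy.size + 1, dtype=float)
    episodes = np.asarray(episodes, dtype=float)
    mask = (accuracy > 0) & (accuracy < threshold) & (episodes >= max(min_episode, 1e-300)) & (episodes > 0)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points below the accuracy threshold")
    res = stats.linregress(np.log10(episodes[mask]), np.log10(accuracy[mask]))
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(mask.sum()),
        threshold=threshold,
    )


@dataclass(frozen=True)
class PairedStats:
    t: float
    dof: int
    p: float
    d: float
    mean_a: float
    mean_b: float


def paired_stats(sample_a: np.ndarray, sample_b: np.ndarray) -> PairedStats:
    """Two-sided paired t-test plus the paired Cohen's d.

    ``d_z = mean(diff) / sd(diff)``, so ``d_z * sqrt(n) == t`` identically.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("samples must be equal-length 1-D arrays with n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return PairedStats(
        t=float(res.statistic),
        dof=a.size - 1,
        p=float(res.pvalue),
        d=float(diff.mean() / sd),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def remap_time(
    smoothed_accuracy: np.ndarray,
    reversal_episode: int,
    criterion: float | None = None,
    baseline_window: int = 100,
    criterion_drop: float = 5.0,
) -> float:
    """Episodes from a reversal until accuracy recovers to criterion.

    With no explicit ``criterion`` (percentage points), it defaults to the
    mean smoothed accuracy over the ``baseline_window`` episodes preceding
    the reversal minus ``criterion_drop`` points. Returns NaN when the curve
    never re-reaches the criterion (recovery undefined).
    """
    acc = np.asarray(smoothed_accuracy, dtype=float)
    if not (0 <= reversal_episode < acc.size):
        raise ValueError("reversal episode outside the curve")
    if criterion is None:
        lo = max(0, reversal_episode - baseline_window)
        criterion = acc[lo:reversal_episode].mean() - criterion_drop
    post = acc[reversal_episode:]
    below = np.nonzero(post < criterion)[0]
    if below.size == 0:
        return 0.0  # performance never dropped below criterion
    hits = np.nonzero(post[below[0]:] >= criterion)[0]
    return float(below[0] + hits[0]) if hits.size else float("nan")


def d2_d1_ratio(d2_counts: np.ndarray, d1_counts: np.ndarray) -> float:
    """Total D2 spikes over total D1 spikes in a window; NaN if no D1 spikes."""
    d1 = float(np.sum(d1_counts))
    d2 = float(np.sum(d2_counts))
    if d1 == 0:
        return float("nan")
    return d2 / d1
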