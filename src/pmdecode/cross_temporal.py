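"""Time-resolved decoding and temporal-stability analysis.

A 4-direction classifier is trained on the population rates of one 40-ms
time window and tested on the same or any other window (leave-one-out over
pseudotrials, preprocessing refit per fold), yielding a train x test
accuracy map over the sample period and the first 1,200 ms of the delay.
A testing window counts as *stable* for a given training window when its
accuracy is above chance (label-shuffle surrogates, percentile rule) and
not significantly below the same-window accuracy (bootstrap
accuracy-difference test).  The percentage of stable delay windows — and
its millisecond equivalent — quantifies how temporally consistent the
population code is; a dynamic code shows a high diagonal with decaying
off-diagonal generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stats import perm_pvalue
from .classifier import loo_fold_models
from .data_model import Dataset, Task
from .population_decoding import (
    accuracy_difference_test,
    build_pseudopopulation,
    Pseudopopulation,
)

__all__ = ["CrossTemporalMap", "cross_temporal_decode", "stability_stats"]


@dataclass
class CrossTemporalMap:
    """Train-window x test-window direction-decoding accuracies (percent)."""

    accuracy: np.ndarray            # (W, W) real map
    boot_accuracy: np.ndarray       # (n_boot, W, W)
    null_accuracy: np.ndarray       # (n_null, W, W) label-shuffle surrogates
    window_start_ms: np.ndarray     # (W,) absolute start of each window
    bin_ms: int
    sample_ms: int
    task: str
    delay_span_ms: tuple[int, int] = (240, 1200)  # analysed delay, rel. delay onset

    @property
    def n_windows(self) -> int:
        return self.accuracy.shape[0]

    def delay_window_mask(self) -> np.ndarray:
        """Windows inside the analysed delay span (stability denominator)."""
        start = self.sample_ms + self.delay_span_ms[0]
        end = self.sample_ms + self.delay_span_ms[1]
        return (self.window_start_ms >= start) & (self.window_start_ms < end)

    def chance_mask(self, percentile: float = 99.0) -> np.ndarray:
        """Cells whose real accuracy reaches the given surrogate percentile."""
        thresh = np.percentile(self.null_accuracy, percentile, axis=0)
        return self.accuracy >= thresh


def _window_tensor(pp: Pseudopopulation) -> np.ndarray:
    """(n_pseudo, n_columns, n_bins) rates read through the pseudotrial mapping."""
    stack = pp.dataset.rate_stack()           # (n_neurons, n_trials, n_bins)
    cols = stack[pp.neuron_indices]           # (n_cols, n_trials, n_bins)
    return cols[np.arange(pp.n_columns)[None, :], pp.source_trial_idx, :]


def _accuracy_map(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """LOO accuracy for every (train window, test window) pair."""
    n_windows = X.shape[2]
    acc = np.empty((n_windows, n_windows))
    for wt in range(n_windows):
        models = loo_fold_models(X[:, :, wt], y, n_classes=4, alpha=alpha)
        for wv in range(n_windows):
            pred = models.predict_heldout(X[:, :, wv])
            acc[wt, wv] = 100.0 * np.mean(pred == y)
    return acc


def cross_temporal_decode(
    dataset: Dataset,
    task: Task,
    rng: np.random.Generator | int | None = None,
    n_per_condition: int = 30,
    alpha: float = 0.01,
    n_boot: int = 20,
    n_null: int = 40,
    windows: np.ndarray | None = None,
) -> CrossTemporalMap:
    """Cross-temporal 4-direction decoding within one task.

    The pseudotrial-to-source-trial mapping is fixed across windows, so
    every cell decodes the same trials from different time slices.
    ``windows`` restricts the bin grid (default: all stored bins).
    Bootstrap and surrogate counts are configurable; the protocol is
    preserved at reduced n for desk-scale runs.
    """
    rng = np.random.default_rng(rng)
    task = Task(task)
    pp = build_pseudopopulation(dataset, n_per_condition, rng).task_subset(task)
    y = pp.dir_idx
    tensor = _window_tensor(pp)
    if windows is None:
        windows = np.arange(tensor.shape[2])
    windows = np.asarray(windows, dtype=int)
    X = tensor[:, :, windows]

    accuracy = _accuracy_map(X, y, alpha)

    boot = np.empty((n_boot, len(windows), len(windows)))
    for b in range(n_boot):
        cols = rng.choice(dataset.n_neurons, size=dataset.n_neurons, replace=True)
        pp_b = build_pseudopopulation(dataset, n_per_condition, rng, neuron_indices=cols).task_subset(task)
        Xb = _window_tensor(pp_b)[:, :, windows]
        boot[b] = _accuracy_map(Xb, pp_b.dir_idx, alpha)

    null = np.empty((n_null, len(windows), len(windows)))
    for k in range(n_null):
        y_shuf = rng.permutation(y)
        null[k] = _accuracy_map(X, y_shuf, alpha)

    return CrossTemporalMap(
        accuracy=accuracy,
        boot_accuracy=boot,
        null_accuracy=null,
        window_start_ms=dataset.t0_ms + windows * dataset.bin_ms,
        bin_ms=dataset.bin_ms,
        sample_ms=dataset.sample_ms,
        task=task.value,
    )


def stability_stats(
    ct_map: CrossTemporalMap,
    alpha: float = 0.01,
    percentile: float = 99.0,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Temporal-stability summary of a cross-temporal map.

    For each training window, the stable fraction is the share of analysed
    delay testing windows that are (a) above chance and (b) not
    significantly below the same-window accuracy at level ``alpha``
    (one-sided bootstrap accuracy-difference test).  The millisecond
    equivalent scales the fraction by the analysed delay span.  Delay-mean
    values average over training windows inside the delay span.
    """
    rng = np.random.default_rng(rng)
    chance = ct_map.chance_mask(percentile)
    delay_cols = np.flatnonzero(ct_map.delay_window_mask())
    if delay_cols.size == 0:
        raise ValueError("no testing windows fall inside the analysed delay span")
    span_ms = delay_cols.size * ct_map.bin_ms

    W = ct_map.n_windows
    stable = np.zeros((W, delay_cols.size), dtype=bool)
    for wt in range(W):
        same = ct_map.boot_accuracy[:, wt, wt]
        for k, wv in enumerate(delay_cols):
            if not chance[wt, wv]:
                continue
            if wv == wt:
                stable[wt, k] = True  # same-window vs itself: no deficit possible
                continue
            p = accuracy_difference_test(same, ct_map.boot_accuracy[:, wt, wv], n_perm, rng)
            stable[wt, k] = p >= alpha
    percent = 100.0 * stable.mean(axis=1)
    delay_rows = ct_map.delay_window_mask()
    return {
        "percent_stable_per_train_window": percent,
        "ms_stable_per_train_window": percent / 100.0 * span_ms,
        "delay_mean_percent_stable": float(percent[delay_rows].mean()),
        "delay_mean_ms_stable": float((percent[delay_rows] / 100.0 * span_ms).mean()),
        "analysed_delay_span_ms": int(span_ms),
        "stable_mask": stable,
        "delay_test_windows": delay_cols,
    }
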