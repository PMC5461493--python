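"""Per-neuron direction discriminability, significance and classification.

For each neuron and each task the direction discriminability is the highest
rectified auROC between the delay-period rate distributions of any pair of
sample directions, and the preferred direction is the direction with the
highest mean delay rate.  Significance comes from a label-permutation test
(default 500 shuffles, 99th-percentile rule), and neurons are classed as
perceptual (P), mnemonic (M), perceptual-mnemonic (PM, significant in both
tasks) or non-discriminating (X).  All discriminability analyses use
correctly performed trials only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import auroc, max_pair_auroc_batch, perm_pvalue, rectify
from .data_model import (
    AnalysisWindow,
    Dataset,
    Outcome,
    Task,
    window_mean_matrix,
)

__all__ = [
    "auroc",
    "rectify",
    "NeuronClassification",
    "direction_discriminability",
    "permutation_significance",
    "classify_neurons",
    "classification_frame",
    "pm_excess_test",
    "discriminability_correlation",
    "explained_variance",
    "compare_task_tuning",
]


@dataclass(frozen=True)
class NeuronClassification:
    neuron_id: str
    auroc_perceptual: float
    auroc_mnemonic: float
    pref_perceptual: float
    pref_mnemonic: float
    p_perceptual: float
    p_mnemonic: float
    sig_perceptual: bool
    sig_mnemonic: bool
    eta2_perceptual: float
    eta2_mnemonic: float

    @property
    def neuron_class(self) -> str:
        if self.sig_perceptual and self.sig_mnemonic:
            return "PM"
        if self.sig_perceptual:
            return "P"
        if self.sig_mnemonic:
            return "M"
        return "X"


def _task_rates_by_direction(
    dataset: Dataset,
    neuron_index: int,
    task: Task,
    window: AnalysisWindow | None,
    correct_only: bool = True,
):
    """Delay-mean rates of one neuron on one task, grouped by direction.

    Returns (concatenated rates ordered by direction, per-direction counts,
    sorted direction angles).
    """
    means = window_mean_matrix(dataset, window)[:, neuron_index]
    task = Task(task)
    sel = np.array(
        [
            t.task is task and (not correct_only or t.outcome is Outcome.CORRECT)
            for t in dataset.trials
        ]
    )
    dirs = np.array([t.direction for t in dataset.trials])[sel]
    rates = means[sel]
    angles = np.asarray(dataset.direction_set, dtype=float)  # sorted ascending
    grouped, counts = [], []
    for ang in angles:
        g = rates[dirs == ang]
        grouped.append(g)
        counts.append(g.size)
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 2):
        missing = angles[counts < 2]
        raise ValueError(
            f"neuron {dataset.neurons[neuron_index].neuron_id}, task {task.value}: "
            f"fewer than 2 trials for direction(s) {missing.tolist()}"
        )
    return np.concatenate(grouped), counts, angles


def direction_discriminability(
    dataset: Dataset,
    neuron_id: str,
    task: Task,
    window: AnalysisWindow | None = None,
    correct_only: bool = True,
) -> tuple[float, float]:
    """(rectified max-pair auROC, preferred direction) for one neuron/task.

    Ties in the per-direction mean rate break toward the lowest angle.
    """
    idx = dataset.neuron_index(neuron_id)
    rates, counts, angles = _task_rates_by_direction(dataset, idx, task, window, correct_only)
    value = float(max_pair_auroc_batch(rates[None, :], counts)[0])
    offs = np.concatenate([[0], np.cumsum(counts)])
    dir_means = np.array([rates[offs[g] : offs[g + 1]].mean() for g in range(4)])
    preferred = float(angles[int(np.argmax(dir_means))])  # argmax -> lowest angle on ties
    return value, preferred


def permutation_significance(
    dataset: Dataset,
    neuron_id: str,
    task: Task,
    n_shuffles: int = 500,
    percentile: float = 99.0,
    rng: np.random.Generator | int | None = None,
    window: AnalysisWindow | None = None,
    correct_only: bool = True,
) -> tuple[float, bool]:
    """Label-permutation test of direction discriminability.

    Each surrogate reassigns the direction labels of all trials (within the
    task, preserving per-direction trial counts) and recomputes the full
    max-pair statistic.  The real value is significant when it reaches or
    exceeds the given percentile of the surrogate distribution; the p-value
    uses the add-one estimator (1 + k) / (1 + n).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if n_shuffles < 100:
        warnings.warn(
            f"n_shuffles={n_shuffles} gives a coarse surrogate distribution",
            stacklevel=2,
        )
    rng = np.random.default_rng(rng)
    idx = dataset.neuron_index(neuron_id)
    rates, counts, _ = _task_rates_by_direction(dataset, idx, task, window, correct_only)
    real = float(max_pair_auroc_batch(rates[None, :], counts)[0])
    perms = np.argsort(rng.random((n_shuffles, rates.size)), axis=1)
    surrogates = max_pair_auroc_batch(rates[perms], counts)
    p = perm_pvalue(real, surrogates)
    significant = bool(real >= np.percentile(surrogates, percentile))
    return p, significant


def explained_variance(
    dataset: Dataset,
    neuron_id: str,
    task: Task,
    window: AnalysisWindow | None = None,
    correct_only: bool = True,
) -> float:
    """One-way ANOVA effect size eta^2 = SS_between / SS_total over directions."""
    idx = dataset.neuron_index(neuron_id)
    rates, counts, _ = _task_rates_by_direction(dataset, idx, task, window, correct_only)
    offs = np.concatenate([[0], np.cumsum(counts)])
    grand = rates.mean()
    ss_total = float(np.sum((rates - grand) ** 2))
    if ss_total == 0.0:
        return 0.0
    ss_between = float(
        sum(
            counts[g] * (rates[offs[g] : offs[g + 1]].mean() - grand) ** 2
            for g in range(counts.size)
        )
    )
    return ss_between / ss_total


def classify_neurons(
    dataset: Dataset,
    window: AnalysisWindow | None = None,
    n_shuffles: int = 500,
    percentile: float = 99.0,
    seed: int | np.random.Generator = 0,
    fdr_alpha: float | None = None,
) -> list[NeuronClassification]:
    """Run discriminability + permutation tests for every neuron and task.

    ``fdr_alpha``, if given, replaces the per-neuron percentile rule with
    Benjamini-Hochberg control on the permutation p-values (pooled over the
    two tasks).
    """
    if isinstance(seed, np.random.Generator):
        child_seeds = seed.integers(0, 2**31 - 1, size=dataset.n_neurons)
        rngs = [np.random.default_rng(int(s)) for s in child_seeds]
    else:
        rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(dataset.n_neurons)]
    records = []
    for nr, rng in zip(dataset.neurons, rngs):
        per_task: dict[Task, tuple[float, float, float, bool, float]] = {}
        for task in (Task.PERCEPTUAL, Task.MEMORY):
            value, pref = direction_discriminability(dataset, nr.neuron_id, task, window)
            p, sig = permutation_significance(
                dataset, nr.neuron_id, task, n_shuffles, percentile, rng, window
            )
            eta2 = explained_variance(dataset, nr.neuron_id, task, window)
            per_task[task] = (value, pref, p, sig, eta2)
        records.append(per_task)

    if fdr_alpha is not None:
        pvals = np.array(
            [r[t][2] for r in records for t in (Task.PERCEPTUAL, Task.MEMORY)]
        )
        reject, *_ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
        reject = reject.reshape(len(records), 2)
    else:
        reject = None

    out = []
    for i, (nr, r) in enumerate(zip(dataset.neurons, records)):
        vp, pp, p_p, sig_p, e_p = r[Task.PERCEPTUAL]
        vm, pm, p_m, sig_m, e_m = r[Task.MEMORY]
        if reject is not None:
            sig_p, sig_m = bool(reject[i, 0]), bool(reject[i, 1])
        out.append(
            NeuronClassification(
                neuron_id=nr.neuron_id,
                auroc_perceptual=vp,
                auroc_mnemonic=vm,
                pref_perceptual=pp,
                pref_mnemonic=pm,
                p_perceptual=p_p,
                p_mnemonic=p_m,
                sig_perceptual=bool(sig_p),
                sig_mnemonic=bool(sig_m),
                eta2_perceptual=e_p,
                eta2_mnemonic=e_m,
            )
        )
    return out


def classification_frame(classifications: list[NeuronClassification]) -> pd.DataFrame:
    df = pd.DataFrame([vars(c) | {"neuron_class": c.neuron_class} for c in classifications])
    return df


def pm_excess_test(
    classifications: list[NeuronClassification],
    n_shuffles: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Is the share of PM neurons larger than expected under independence?

    The perceptual and mnemonic significance flags are shuffled
    independently across the recorded population; each surrogate is the
    resulting percentage of neurons carrying both flags.  (Shuffling within
    the significant subset alone is degenerate: conditioned on every neuron
    holding at least one flag, the observed overlap is the smallest any
    rearrangement can produce, so the test must randomize over all neurons
    for an excess to be detectable.)
    """
    rng = np.random.default_rng(rng)
    if not any(c.neuron_class != "X" for c in classifications):
        raise ValueError("pm_excess_test needs at least one P/M/PM neuron")
    flags_p = np.array([c.sig_perceptual for c in classifications])
    flags_m = np.array([c.sig_mnemonic for c in classifications])
    real = 100.0 * np.mean(flags_p & flags_m)
    surrogates = np.empty(n_shuffles)
    for k in range(n_shuffles):
        sp = rng.permutation(flags_p)
        sm = rng.permutation(flags_m)
        surrogates[k] = 100.0 * np.mean(sp & sm)
    return perm_pvalue(real, surrogates)


def discriminability_correlation(
    classifications: list[NeuronClassification],
    subset: str = "all",
    n_shuffles: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Pearson r between perceptual and mnemonic discriminability.

    The p-value is a one-sided shuffle null (discriminability values permuted
    between neurons), matching how the chance level is defined.
    """
    if subset == "all":
        sel = classifications
    elif subset == "PM":
        sel = [c for c in classifications if c.neuron_class == "PM"]
    else:
        raise ValueError("subset must be 'all' or 'PM'")
    if len(sel) < 3:
        raise ValueError(f"subset {subset!r} has {len(sel)} neurons; need >= 3")
    x = np.array([c.auroc_perceptual for c in sel])
    y = np.array([c.auroc_mnemonic for c in sel])
    if x.std() == 0 or y.std() == 0:
        # a saturated (constant) discriminability vector carries no rank info
        return float("nan"), 1.0
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(rng)
    surrogates = np.empty(n_shuffles)
    for k in range(n_shuffles):
        surrogates[k] = stats.pearsonr(x, rng.permutation(y)).statistic
    return r, perm_pvalue(r, surrogates)


def _fold_circular_shift(a: float, b: float) -> int:
    """Circular difference between two angles folded to {0, 90, 180}."""
    d = abs(((a - b + 180.0) % 360.0) - 180.0)
    return int(round(d))


def compare_task_tuning(
    classifications: list[NeuronClassification],
    dataset: Dataset,
    window: AnalysisWindow | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-task tuning comparison per neuron.

    ``pref_shift`` (PM neurons only): circular difference between the
    task-wise preferred directions folded to {0, 90, 180}.  ``rate_diff_p``
    (all neurons): two-sample t-test on overall delay rates between tasks,
    Benjamini-Hochberg corrected across neurons.
    """
    from .data_model import window_mean_matrix as _wmm

    means = _wmm(dataset, window)
    task_is_p = np.array(
        [t.task is Task.PERCEPTUAL and t.outcome is Outcome.CORRECT for t in dataset.trials]
    )
    task_is_m = np.array(
        [t.task is Task.MEMORY and t.outcome is Outcome.CORRECT for t in dataset.trials]
    )
    rows = []
    for j, c in enumerate(classifications):
        shift = (
            _fold_circular_shift(c.pref_perceptual, c.pref_mnemonic)
            if c.neuron_class == "PM"
            else None
        )
        t_stat, p = stats.ttest_ind(means[task_is_p, j], means[task_is_m, j])
        rows.append(
            {
                "neuron_id": c.neuron_id,
                "neuron_class": c.neuron_class,
                "pref_shift": shift,
                "rate_diff_t": float(t_stat),
                "rate_diff_p": float(p),
            }
        )
    df = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(df["rate_diff_p"], alpha=fdr_alpha, method="fdr_bh")
    df["rate_diff_p_fdr"] = p_adj
    df["rate_diff_significant"] = reject
    return df
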