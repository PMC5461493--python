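"""Pseudopopulation construction and condition-decoding analyses.

Neurons recorded in different sessions are pooled into a pseudopopulation:
for every neuron, 30 correct trials per condition are drawn and trial
"simultaneity" is assigned at random within condition, independently per
neuron.  A diagonal linear discriminant classifier, with fold-wise
z-scoring and 8-level-ANOVA feature pre-selection, decodes the eight
conditions (2 tasks x 4 directions) under leave-one-out cross-validation.
Variability comes from 100 neuron bootstraps; chance levels from
randomized-trial-label re-runs of the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from ._stats import perm_pvalue
from .classifier import DiagLDA, loo_fold_models, loo_predict, preprocess_fit
from .data_model import (
    AnalysisWindow,
    Dataset,
    Outcome,
    Task,
    Trial,
    group_trials,
    window_mean_matrix,
)
from .discriminability import NeuronClassification

__all__ = [
    "Pseudopopulation",
    "ConfusionMatrix",
    "DecodeResult",
    "rotate_direction_labels",
    "build_pseudopopulation",
    "loo_decode",
    "summarize",
    "bootstrap_neurons",
    "accuracy_difference_test",
    "randomized_label_null",
    "cross_task_decode",
    "class_removal_analysis",
    "region_subset_decode",
]

TASK_ORDER = (Task.PERCEPTUAL, Task.MEMORY)


def rotate_direction_labels(dataset: Dataset) -> Dataset:
    """Rotate the direction reference frame to the canonical {0, 90, 180, 270}.

    All session directions are 90 degrees apart, so subtracting the common
    residue maps them onto the canonical set; the same rotation applies to
    both tasks.  Decoding is invariant to this relabelling.
    """
    residue = min(d % 90.0 for d in dataset.direction_set)
    if residue == 0.0 and set(dataset.direction_set) == {0.0, 90.0, 180.0, 270.0}:
        return dataset
    trials = [replace(t, direction=(t.direction - residue) % 360.0) for t in dataset.trials]
    return Dataset(
        neurons=dataset.neurons,
        trials=trials,
        direction_set=tuple(sorted((d - residue) % 360.0 for d in dataset.direction_set)),
        sample_ms=dataset.sample_ms,
        provenance={**dataset.provenance, "rotated_by_deg": residue},
    )


@dataclass
class Pseudopopulation:
    """Pseudotrial x neuron assembly with its source-trial provenance.

    ``source_trial_idx[i, j]`` is the dataset trial row feeding pseudotrial
    i of neuron column j, so the same trial mapping can be re-read at any
    time window (cross-temporal decoding).  Condition index = task * 4 +
    direction rank, tasks ordered (perceptual, memory), directions ascending.
    """

    dataset: Dataset
    neuron_indices: np.ndarray          # columns -> dataset neuron rows (repeats allowed)
    source_trial_idx: np.ndarray        # (n_pseudo, n_columns)
    condition: np.ndarray               # (n_pseudo,) in 0..7
    task_idx: np.ndarray                # (n_pseudo,) 0=perceptual, 1=memory
    dir_idx: np.ndarray                 # (n_pseudo,) 0..3
    n_per_condition: int
    seed_info: dict = field(default_factory=dict)

    @property
    def n_pseudotrials(self) -> int:
        return self.source_trial_idx.shape[0]

    @property
    def n_columns(self) -> int:
        return self.source_trial_idx.shape[1]

    def rates(self, window: AnalysisWindow | None = None) -> np.ndarray:
        """(n_pseudo, n_columns) window-mean rate matrix."""
        means = window_mean_matrix(self.dataset, window)  # (n_trials, n_neurons)
        cols = means[:, self.neuron_indices]              # (n_trials, n_columns)
        return np.take_along_axis(cols, self.source_trial_idx, axis=0)

    def task_subset(self, task: Task) -> "Pseudopopulation":
        """Rows of one task only (labels become the 4 direction classes)."""
        t = TASK_ORDER.index(Task(task))
        rows = self.task_idx == t
        return Pseudopopulation(
            dataset=self.dataset,
            neuron_indices=self.neuron_indices,
            source_trial_idx=self.source_trial_idx[rows],
            condition=self.condition[rows],
            task_idx=self.task_idx[rows],
            dir_idx=self.dir_idx[rows],
            n_per_condition=self.n_per_condition,
            seed_info=self.seed_info,
        )


def build_pseudopopulation(
    dataset: Dataset,
    n_per_condition: int = 30,
    rng: np.random.Generator | int | None = None,
    neuron_indices: Sequence[int] | None = None,
    correct_only: bool = True,
) -> Pseudopopulation:
    """Assemble a pseudopopulation of ``8 * n_per_condition`` pseudotrials.

    Each neuron column independently samples ``n_per_condition`` (correct)
    trials per condition and shuffles their within-condition order, which
    destroys any cross-neuron trial correlation.  A condition with fewer
    available trials than requested makes the dataset ineligible.
    """
    rng = np.random.default_rng(rng)
    if neuron_indices is None:
        neuron_indices = np.arange(dataset.n_neurons)
    neuron_indices = np.asarray(neuron_indices, dtype=int)
    if neuron_indices.size == 0:
        raise ValueError("no neurons to build a pseudopopulation from")

    groups = group_trials(dataset, by=("task", "direction", "outcome") if correct_only else ("task", "direction"))
    dirs = sorted(dataset.direction_set)
    pools = []
    for task in TASK_ORDER:
        for d in dirs:
            key = (task.value, d, Outcome.CORRECT.value) if correct_only else (task.value, d)
            pool = groups.get(key, np.empty(0, dtype=int))
            if pool.size < n_per_condition:
                raise ValueError(
                    f"condition (task={task.value}, direction={d}) has only "
                    f"{pool.size} usable trials; {n_per_condition} required"
                )
            pools.append(pool)

    n_cond = len(pools)
    n_rows = n_cond * n_per_condition
    source = np.empty((n_rows, neuron_indices.size), dtype=int)
    for j in range(neuron_indices.size):
        for c, pool in enumerate(pools):
            picked = rng.choice(pool, size=n_per_condition, replace=False)
            source[c * n_per_condition : (c + 1) * n_per_condition, j] = picked

    condition = np.repeat(np.arange(n_cond), n_per_condition)
    return Pseudopopulation(
        dataset=dataset,
        neuron_indices=neuron_indices,
        source_trial_idx=source,
        condition=condition,
        task_idx=condition // 4,
        dir_idx=condition % 4,
        n_per_condition=n_per_condition,
    )


@dataclass
class ConfusionMatrix:
    """Decoded-vs-true incidence counts; rows sum to tested-trial counts."""

    counts: np.ndarray  # (K, K), rows = true class, columns = decoded class
    n_classes: int

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> "ConfusionMatrix":
        counts = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts=counts, n_classes=n_classes)

    def row_percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, np.nan)


@dataclass
class DecodeResult:
    """Point accuracies (percent) from one 8-condition decoding run."""

    task_accuracy: float
    dir_given_task_correct: dict[str, float | None]
    dir_given_task_error: dict[str, float | None]
    condition_accuracy: float


def loo_decode(
    pseudopop: Pseudopopulation,
    window: AnalysisWindow | None = None,
    alpha: float = 0.01,
    labels: np.ndarray | None = None,
) -> ConfusionMatrix:
    """8-condition leave-one-out decoding (fold-wise preprocessing refit).

    ``labels`` overrides the condition labels (randomized-label nulls).
    """
    X = pseudopop.rates(window)
    y = pseudopop.condition if labels is None else np.asarray(labels, dtype=int)
    pred = loo_predict(X, y, n_classes=8, alpha=alpha)
    return ConfusionMatrix.from_predictions(y, pred, 8)


def summarize(conf: ConfusionMatrix) -> DecodeResult:
    """Task accuracy and direction accuracy within task-correct / task-error trials."""
    counts = conf.counts.astype(float)
    if conf.n_classes != 8:
        raise ValueError("summarize expects an 8-condition confusion matrix")
    total = counts.sum()
    task_of = np.arange(8) // 4
    dir_of = np.arange(8) % 4
    same_task = task_of[:, None] == task_of[None, :]
    task_correct_mass = counts[same_task].sum()
    task_accuracy = 100.0 * task_correct_mass / total

    dir_ok: dict[str, float | None] = {}
    dir_err: dict[str, float | None] = {}
    for t, name in enumerate(("perceptual", "memory")):
        rows = task_of == t
        ct = counts[rows]  # (4, 8) true conditions of this task
        in_task = ct[:, task_of == t]      # decoded into same task (4x4, dir order)
        out_task = ct[:, task_of != t]     # decoded into the other task (4x4)
        denom_in = in_task.sum()
        denom_out = out_task.sum()
        dir_ok[name] = 100.0 * np.trace(in_task) / denom_in if denom_in else None
        dir_err[name] = 100.0 * np.trace(out_task) / denom_out if denom_out else None

    condition_accuracy = 100.0 * np.trace(counts) / total
    return DecodeResult(
        task_accuracy=float(task_accuracy),
        dir_given_task_correct=dir_ok,
        dir_given_task_error=dir_err,
        condition_accuracy=float(condition_accuracy),
    )


def bootstrap_neurons(
    dataset: Dataset,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
    n_per_condition: int = 30,
    alpha: float = 0.01,
    window: AnalysisWindow | None = None,
    neuron_indices: Sequence[int] | None = None,
    resample: bool = True,
) -> tuple[list[DecodeResult], list[ConfusionMatrix]]:
    """Decoding variability over neuron bootstraps.

    Each bootstrap samples neurons with replacement (same count as the base
    population); duplicates are harmless because every column re-draws and
    re-shuffles its trials.  ``resample=False`` reuses the base population
    (n_boot=1 then reproduces the point estimate up to trial assignment).
    """
    rng = np.random.default_rng(rng)
    base = (
        np.arange(dataset.n_neurons)
        if neuron_indices is None
        else np.asarray(neuron_indices, dtype=int)
    )
    results, confs = [], []
    for _ in range(n_boot):
        cols = rng.choice(base, size=base.size, replace=True) if resample else base
        pp = build_pseudopopulation(dataset, n_per_condition, rng, neuron_indices=cols)
        conf = loo_decode(pp, window=window, alpha=alpha)
        confs.append(conf)
        results.append(summarize(conf))
    return results, confs


def accuracy_difference_test(
    boot_a: Sequence[float],
    boot_b: Sequence[float],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """One-sided test of mean(boot_a) > mean(boot_b) by pooling-and-reassigning
    the bootstrap accuracy values (add-one permutation p-value)."""
    rng = np.random.default_rng(rng)
    a = np.asarray(boot_a, dtype=float)
    b = np.asarray(boot_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("accuracy_difference_test needs non-empty bootstrap sets")
    real = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    shuffled = pooled[order]
    surrogates = shuffled[:, : a.size].mean(axis=1) - shuffled[:, a.size :].mean(axis=1)
    return perm_pvalue(real, surrogates)


def randomized_label_null(
    pseudopop: Pseudopopulation,
    n: int = 1000,
    rng: np.random.Generator | int | None = None,
    window: AnalysisWindow | None = None,
    alpha: float = 0.01,
) -> list[DecodeResult]:
    """Chance distribution: full LOO pipeline re-run on shuffled condition labels."""
    rng = np.random.default_rng(rng)
    X = pseudopop.rates(window)
    out = []
    for _ in range(n):
        y = rng.permutation(pseudopop.condition)
        pred = loo_predict(X, y, n_classes=8, alpha=alpha)
        out.append(summarize(ConfusionMatrix.from_predictions(y, pred, 8)))
    return out


def null_pvalue(real: float, null_values: Sequence[float]) -> float:
    """p for a real accuracy against its randomized-label null (one-sided)."""
    return perm_pvalue(real, np.asarray(null_values, dtype=float))


def _two_fold_split(
    dir_idx: np.ndarray, n_per_condition: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split one task's rows into two folds, balanced per direction."""
    fold0, fold1 = [], []
    for d in range(4):
        rows = np.flatnonzero(dir_idx == d)
        rows = rng.permutation(rows)
        half = rows.size // 2
        fold0.append(rows[:half])
        fold1.append(rows[half:])
    return np.concatenate(fold0), np.concatenate(fold1)


def cross_task_decode(
    pseudopop: Pseudopopulation,
    rng: np.random.Generator | int | None = None,
    window: AnalysisWindow | None = None,
    alpha: float = 0.01,
) -> dict[tuple[str, str], float]:
    """Direction decoding trained/tested within or across tasks (2-fold).

    Each task's 120 trials are split 60/60 (balanced per direction); for a
    (train_task, test_task) combination the classifier trains on one fold of
    the training task and is tested on the non-overlapping fold of the
    testing task, averaging over the two folds.  Keys are
    (train, test) task-name pairs; values are accuracies in percent.
    """
    rng = np.random.default_rng(rng)
    X = pseudopop.rates(window)
    subsets = {}
    for t, task in enumerate(TASK_ORDER):
        rows = np.flatnonzero(pseudopop.task_idx == t)
        f0, f1 = _two_fold_split(pseudopop.dir_idx[rows], pseudopop.n_per_condition, rng)
        subsets[task.value] = (rows, (rows[f0], rows[f1]))

    out: dict[tuple[str, str], float] = {}
    for train_name, (_, train_folds) in subsets.items():
        for test_name, (_, test_folds) in subsets.items():
            accs = []
            for k in (0, 1):
                train_rows = train_folds[k]
                test_rows = test_folds[1 - k]
                ytr = pseudopop.dir_idx[train_rows]
                yte = pseudopop.dir_idx[test_rows]
                pre = preprocess_fit(X[train_rows], ytr, n_classes=4, alpha=alpha)
                clf = DiagLDA().fit(pre.apply(X[train_rows]), ytr, n_classes=4)
                pred = clf.predict(pre.apply(X[test_rows]))
                accs.append(100.0 * np.mean(pred == yte))
            out[(train_name, test_name)] = float(np.mean(accs))
    return out


def class_removal_analysis(
    dataset: Dataset,
    classifications: Sequence[NeuronClassification],
    rng: np.random.Generator | int | None = None,
    n_boot: int = 20,
    n_perm: int = 1000,
    n_per_condition: int = 30,
    alpha: float = 0.01,
    window: AnalysisWindow | None = None,
) -> dict[str, dict]:
    """Contribution of each functional class to population decoding.

    For each class in {P, PM, M}: decode without that class's neurons and
    compare (bootstrap accuracy-difference test) against a size-matched
    population randomly downsampled, without replacement, from the full
    population.  Reported deltas are control minus removed (positive =
    accuracy drop caused by the removal), for task accuracy and for
    perceived/memorized direction accuracy (given correct task decoding).
    """
    rng = np.random.default_rng(rng)
    classes = np.array([c.neuron_class for c in classifications])
    if len(classes) != dataset.n_neurons:
        raise ValueError("classifications must cover every neuron in the dataset")
    out: dict[str, dict] = {}
    for cls in ("P", "PM", "M"):
        keep = np.flatnonzero(classes != cls)
        control = rng.choice(dataset.n_neurons, size=keep.size, replace=False)
        removed_boot, _ = bootstrap_neurons(
            dataset, n_boot, rng, n_per_condition, alpha, window, neuron_indices=keep
        )
        control_boot, _ = bootstrap_neurons(
            dataset, n_boot, rng, n_per_condition, alpha, window, neuron_indices=control
        )
        entry: dict = {"n_removed": int(dataset.n_neurons - keep.size), "n_kept": int(keep.size)}
        for metric, getter in (
            ("task", lambda r: r.task_accuracy),
            ("condition", lambda r: r.condition_accuracy),
            ("direction_perceptual", lambda r: r.dir_given_task_correct["perceptual"]),
            ("direction_memory", lambda r: r.dir_given_task_correct["memory"]),
        ):
            a = np.array([np.nan if getter(r) is None else getter(r) for r in control_boot], dtype=float)
            b = np.array([np.nan if getter(r) is None else getter(r) for r in removed_boot], dtype=float)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if a.size == 0 or b.size == 0:
                # degenerate: the metric was undefined on every bootstrap
                entry[f"delta_{metric}"] = None
                entry[f"p_{metric}"] = None
                continue
            entry[f"delta_{metric}"] = float(a.mean() - b.mean())
            entry[f"p_{metric}"] = accuracy_difference_test(a, b, n_perm, rng)
        out[cls] = entry
    return out


def region_subset_decode(
    dataset: Dataset,
    region: Callable[[np.ndarray], bool],
    rng: np.random.Generator | int | None = None,
    n_boot: int = 20,
    n_per_condition: int = 30,
    alpha: float = 0.01,
    window: AnalysisWindow | None = None,
) -> dict[str, object]:
    """Decoding with neurons inside vs outside a cortical sub-region.

    ``region`` is a predicate on the (x, y) position in mm.  The outside
    population is additionally downsampled to the inside neuron count so the
    comparison is size-matched.
    """
    rng = np.random.default_rng(rng)
    inside = np.array([region(nr.position_mm) for nr in dataset.neurons], dtype=bool)
    inside_idx = np.flatnonzero(inside)
    outside_idx = np.flatnonzero(~inside)
    if inside_idx.size == 0:
        raise ValueError("the region contains no neurons; cannot decode an empty subset")
    if outside_idx.size > inside_idx.size:
        outside_idx = rng.choice(outside_idx, size=inside_idx.size, replace=False)
    inside_boot, _ = bootstrap_neurons(
        dataset, n_boot, rng, n_per_condition, alpha, window, neuron_indices=inside_idx
    )
    outside_boot, _ = (
        bootstrap_neurons(
            dataset, n_boot, rng, n_per_condition, alpha, window, neuron_indices=outside_idx
        )
        if outside_idx.size
        else ([], [])
    )
    return {
        "n_inside": int(inside_idx.size),
        "n_outside": int(outside_idx.size),
        "inside_boot": inside_boot,
        "outside_boot": outside_boot,
    }
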