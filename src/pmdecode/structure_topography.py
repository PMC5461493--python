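"""Feature-proximity error structure and anatomical clustering.

If population activity patterns vary smoothly along the direction circle,
a decoder's errors should fall preferentially on directions 90 degrees away
from the truth rather than 180 degrees away, and single-neuron rates at the
two orthogonal directions should sit between the preferred and
anti-preferred rates.  A whole-condition label-swap control destroys the
circular relationships while preserving decodability, and a position-
shuffle permutation test asks whether strongly discriminating neurons
cluster anatomically.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from ._stats import perm_pvalue
from .classifier import loo_predict
from .data_model import AnalysisWindow, Dataset, Outcome, Task, window_mean_matrix
from .discriminability import NeuronClassification
from .population_decoding import ConfusionMatrix, build_pseudopopulation

__all__ = [
    "OFFSETS",
    "error_incidence_profile",
    "proximity_test",
    "swap_direction_labels",
    "proximity_analysis",
    "tuning_profile",
    "topography_cluster_test",
]

#: circular offsets (decoded minus true direction), folded so -180 == 180
OFFSETS = (0, 90, -90, 180)


def _fold_offset(delta_deg: float) -> int:
    return int(round(((delta_deg + 180.0) % 360.0) - 180.0))


def error_incidence_profile(confusion, direction_angles: Sequence[float] = (0, 90, 180, 270)) -> dict[int, float]:
    """Mean incidence (percent) of decoding at each circular offset.

    ``confusion`` is a 4x4 direction confusion (counts; rows = true).  The
    incidence at each offset is computed per true-direction condition, then
    averaged over the four conditions; the four values sum to 100.
    """
    counts = confusion.counts if isinstance(confusion, ConfusionMatrix) else np.asarray(confusion, dtype=float)
    if counts.shape != (4, 4):
        raise ValueError("error_incidence_profile expects a 4x4 direction confusion")
    angles = np.asarray(direction_angles, dtype=float)
    pct = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    profile = {o: 0.0 for o in OFFSETS}
    for i in range(4):
        for j in range(4):
            off = _fold_offset(angles[j] - angles[i])
            off = 180 if off == -180 else off
            profile[off] += pct[i, j] / 4.0
    return profile


def proximity_test(profiles: np.ndarray) -> tuple[float, float]:
    """Paired t-test of (mean +/-90 incidence) > (180 incidence) across repetitions.

    ``profiles`` is (n_rep, 4) with columns ordered as :data:`OFFSETS`.
    Returns (mean difference, one-sided p).  A degenerate zero-variance
    difference is resolved by its sign.
    """
    profiles = np.asarray(profiles, dtype=float)
    near = 0.5 * (profiles[:, 1] + profiles[:, 2])
    far = profiles[:, 3]
    diff = near - far
    if np.allclose(diff.std(), 0.0):
        mean = float(diff.mean())
        return mean, 0.0 if mean > 0 else 1.0
    res = stats.ttest_rel(near, far, alternative="greater")
    return float(diff.mean()), float(res.pvalue)


def swap_direction_labels(
    dir_idx: np.ndarray, task_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute direction labels between whole conditions, within each task.

    Trials stay grouped within condition, so overall decodability is
    preserved while the circular relationships between labels are destroyed.
    """
    out = dir_idx.copy()
    for t in np.unique(task_idx):
        perm = rng.permutation(4)
        rows = task_idx == t
        out[rows] = perm[dir_idx[rows]]
    return out


def proximity_analysis(
    dataset: Dataset,
    rng: np.random.Generator | int | None = None,
    n_rep: int = 50,
    n_per_condition: int = 30,
    alpha: float = 0.01,
    swap_labels: bool = False,
    window: AnalysisWindow | None = None,
) -> dict[str, dict]:
    """Error-incidence profiles over decoding repetitions, per task.

    Each repetition bootstraps neurons (with replacement), rebuilds the
    pseudopopulation and runs within-task 4-direction leave-one-out
    decoding.  With ``swap_labels`` the whole-condition label swap is
    applied per repetition (the control that abolishes feature proximity).
    """
    rng = np.random.default_rng(rng)
    canonical = sorted(dataset.direction_set)
    out: dict[str, dict] = {}
    profiles = {t.value: [] for t in (Task.PERCEPTUAL, Task.MEMORY)}
    for _ in range(n_rep):
        cols = rng.choice(dataset.n_neurons, size=dataset.n_neurons, replace=True)
        pp = build_pseudopopulation(dataset, n_per_condition, rng, neuron_indices=cols)
        for task in (Task.PERCEPTUAL, Task.MEMORY):
            sub = pp.task_subset(task)
            y = sub.dir_idx
            if swap_labels:
                y = swap_direction_labels(y, np.zeros_like(y), rng)
            pred = loo_predict(sub.rates(window), y, n_classes=4, alpha=alpha)
            conf = ConfusionMatrix.from_predictions(y, pred, 4)
            prof = error_incidence_profile(conf, canonical)
            profiles[task.value].append([prof[o] for o in OFFSETS])
    for task_name, rows in profiles.items():
        arr = np.asarray(rows)
        diff, p = proximity_test(arr)
        out[task_name] = {
            "profiles": arr,
            "mean_profile": dict(zip(OFFSETS, arr.mean(axis=0))),
            "near_minus_far": diff,
            "p_90_vs_180": p,
        }
    return out


def tuning_profile(
    dataset: Dataset,
    classifications: Sequence[NeuronClassification],
    task: Task,
    window: AnalysisWindow | None = None,
) -> dict:
    """Preferred-direction-aligned rate profile of direction-selective neurons.

    Per-neuron mean delay rates are re-indexed by offset from the neuron's
    preferred direction and normalized to the preferred rate (neurons with a
    zero preferred rate are excluded with a warning).  Reports a paired
    t-test of the mean +/-90 rate against the 180 rate across neurons, and
    the mean ratio |pref - anti| / |r(+90) - r(-90)| (zero-denominator
    neurons excluded).
    """
    task = Task(task)
    means = window_mean_matrix(dataset, window)
    sel_flag = "sig_perceptual" if task is Task.PERCEPTUAL else "sig_mnemonic"
    pref_field = "pref_perceptual" if task is Task.PERCEPTUAL else "pref_mnemonic"
    trial_sel = np.array(
        [t.task is task and t.outcome is Outcome.CORRECT for t in dataset.trials]
    )
    dirs = np.array([t.direction for t in dataset.trials])[trial_sel]

    rows, ratios, skipped = [], [], []
    for j, c in enumerate(classifications):
        if not getattr(c, sel_flag):
            continue
        rates = means[trial_sel, j]
        pref = getattr(c, pref_field)
        by_offset = {}
        for o in OFFSETS:
            ang = (pref + o) % 360.0
            vals = rates[dirs == ang]
            by_offset[o] = float(vals.mean()) if vals.size else np.nan
        if not np.isfinite(by_offset[0]) or by_offset[0] == 0:
            skipped.append(c.neuron_id)
            continue
        denom = abs(by_offset[90] - by_offset[-90])
        if denom > 0:
            ratios.append(abs(by_offset[0] - by_offset[180]) / denom)
        rows.append(
            {"neuron_id": c.neuron_id}
            | {f"rate_{o}": by_offset[o] for o in OFFSETS}
            | {f"norm_{o}": by_offset[o] / by_offset[0] for o in OFFSETS}
        )
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} neuron(s) with zero preferred rate from normalization",
            stacklevel=2,
        )
    df = pd.DataFrame(rows)
    result = {"per_neuron": df, "n_neurons": len(df), "excluded_zero_pref": skipped}
    if len(df) >= 2:
        near = 0.5 * (df["rate_90"] + df["rate_-90"])
        far = df["rate_180"]
        res = stats.ttest_rel(near, far, alternative="greater")
        result["p_90_vs_180"] = float(res.pvalue)
        result["mean_normalized"] = {o: float(df[f"norm_{o}"].mean()) for o in OFFSETS}
    result["mean_ratio_pref_anti_vs_orthogonal"] = float(np.mean(ratios)) if ratios else None
    return result


def topography_cluster_test(
    dataset: Dataset,
    classifications: Sequence[NeuronClassification],
    task: Task,
    threshold: float = 0.75,
    n_shuffles: int = 1000,
    rng: np.random.Generator | int | None = None,
    by_subject: bool = True,
) -> dict[str, dict]:
    """Are high-discriminability neurons anatomically clustered?

    Per subject: the observed mean pairwise distance between neurons with
    discriminability above ``threshold`` is compared to surrogates in which
    positions are shuffled among all of that subject's neurons.  Small p
    (fraction of surrogates below the observed mean, add-one estimator)
    indicates clustering.  Subjects with fewer than two qualifying neurons
    are skipped with a notice.
    """
    rng = np.random.default_rng(rng)
    task = Task(task)
    metric_field = "auroc_perceptual" if task is Task.PERCEPTUAL else "auroc_mnemonic"
    metric = np.array([getattr(c, metric_field) for c in classifications])
    positions = np.stack([nr.position_mm for nr in dataset.neurons])
    subjects = np.array([nr.subject_id for nr in dataset.neurons])
    groups = np.unique(subjects) if by_subject else np.array(["all"])

    out: dict[str, dict] = {}
    for subject in groups:
        idx = np.flatnonzero(subjects == subject) if by_subject else np.arange(len(subjects))
        high = idx[metric[idx] > threshold]
        if high.size < 2:
            out[str(subject)] = {
                "skipped": True,
                "n_high": int(high.size),
                "note": "fewer than 2 neurons above threshold; test skipped",
            }
            continue
        observed = float(pdist(positions[high]).mean())
        pos = positions[idx]
        k = high.size
        surrogates = np.empty(n_shuffles)
        for s in range(n_shuffles):
            picked = pos[rng.permutation(idx.size)[:k]]
            surrogates[s] = pdist(picked).mean()
        out[str(subject)] = {
            "skipped": False,
            "n_high": int(k),
            "n_total": int(idx.size),
            "observed_mean_distance_mm": observed,
            "p": perm_pvalue(observed, surrogates, tail="less"),
        }
    return out
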