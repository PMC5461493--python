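"""Choice probability: predicting trial outcome from delay activity.

Choice probability (CP) is the auROC between a neuron's delay-period rates
on correct versus error trials whose sample moved in the neuron's preferred
direction; CP > 0.5 means higher rates precede correct responses.  Only
neurons with delay-period direction selectivity in the task are analysed,
and neurons with fewer than five correct or five error preferred-direction
trials are excluded (CP is *absent*, not an error).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import auroc
from .data_model import AnalysisWindow, Dataset, Outcome, Task, window_mean_matrix
from .discriminability import NeuronClassification

__all__ = ["choice_probability", "cp_table", "cp_group_tests"]

MIN_TRIALS_PER_OUTCOME = 5


def choice_probability(
    dataset: Dataset,
    neuron_id: str,
    task: Task,
    preferred_direction: float,
    window: AnalysisWindow | None = None,
) -> float | None:
    """CP for one neuron/task, or None when the trial-count filter fails."""
    task = Task(task)
    j = dataset.neuron_index(neuron_id)
    means = window_mean_matrix(dataset, window)[:, j]
    sel = np.array(
        [t.task is task and t.direction == float(preferred_direction) % 360.0 for t in dataset.trials]
    )
    outcomes = np.array([t.outcome is Outcome.CORRECT for t in dataset.trials])
    correct_rates = means[sel & outcomes]
    error_rates = means[sel & ~outcomes]
    if correct_rates.size < MIN_TRIALS_PER_OUTCOME or error_rates.size < MIN_TRIALS_PER_OUTCOME:
        return None
    # oriented so CP > 0.5 <=> higher rates on correct trials
    return auroc(error_rates, correct_rates)


def cp_table(
    dataset: Dataset,
    classifications: list[NeuronClassification],
    window: AnalysisWindow | None = None,
) -> pd.DataFrame:
    """Per-neuron CP in each task where the neuron is direction-selective.

    The selectivity gate is the permutation-test significance from the
    discriminability stage; the preferred direction is task-specific.
    """
    rows = []
    for c in classifications:
        cp_p = (
            choice_probability(dataset, c.neuron_id, Task.PERCEPTUAL, c.pref_perceptual, window)
            if c.sig_perceptual
            else None
        )
        cp_m = (
            choice_probability(dataset, c.neuron_id, Task.MEMORY, c.pref_mnemonic, window)
            if c.sig_mnemonic
            else None
        )
        rows.append({"neuron_id": c.neuron_id, "cp_perceptual": cp_p, "cp_mnemonic": cp_m})
    return pd.DataFrame(rows)


def cp_group_tests(cp: pd.DataFrame, min_neurons: int = 5) -> dict:
    """Population-level CP statistics.

    One-tailed Wilcoxon signed-rank tests of mean CP > 0.5 per task, plus a
    one-tailed within-neuron test of memory CP - perceptual CP > 0.
    """
    out: dict = {}
    for task, col in (("perceptual", "cp_perceptual"), ("memory", "cp_mnemonic")):
        vals = cp[col].dropna().astype(float).to_numpy()
        out[f"n_{task}"] = int(vals.size)
        if vals.size >= min_neurons:
            out[f"mean_cp_{task}"] = float(vals.mean())
            diffs = vals - 0.5
            if np.allclose(diffs, 0.0):
                out[f"p_{task}"] = 1.0  # all at chance: nothing to rank
            else:
                out[f"p_{task}"] = float(
                    stats.wilcoxon(diffs, alternative="greater").pvalue
                )
        else:
            out[f"mean_cp_{task}"] = float(vals.mean()) if vals.size else None
            out[f"p_{task}"] = None
    both = cp.dropna(subset=["cp_perceptual", "cp_mnemonic"])
    out["n_both"] = int(len(both))
    if len(both) >= min_neurons:
        delta = both["cp_mnemonic"].to_numpy(float) - both["cp_perceptual"].to_numpy(float)
        out["mean_cp_memory_minus_perceptual"] = float(delta.mean())
        if np.allclose(delta, 0.0):
            out["p_memory_gt_perceptual"] = 1.0
        else:
            out["p_memory_gt_perceptual"] = float(
                stats.wilcoxon(delta, alternative="greater").pvalue
            )
    else:
        out["mean_cp_memory_minus_perceptual"] = None
        out["p_memory_gt_perceptual"] = None
    return out
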