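"""Shared statistical primitives: auROC, rectification, permutation p-values."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auroc", "rectify", "perm_pvalue", "max_pair_auroc_batch"]


def auroc(rates_a, rates_b) -> float:
    """Area under the ROC curve separating two rate distributions.

    Mann-Whitney identity: the fraction of ordered pairs ``(a, b)`` with
    ``b > a``, ties counted 0.5.  Values near 1 mean ``rates_b`` tends to
    exceed ``rates_a``; 0.5 means indistinguishable distributions.
    """
    a = np.asarray(rates_a, dtype=float).ravel()
    b = np.asarray(rates_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("auroc requires two non-empty rate lists")
    ranks = rankdata(np.concatenate([a, b]))
    r_b = ranks[a.size :].sum()
    u_b = r_b - b.size * (b.size + 1) / 2.0
    return float(u_b / (a.size * b.size))


def rectify(value: float) -> float:
    """Fold an auROC in [0, 1] to the direction-agnostic range [0.5, 1]."""
    v = np.asarray(value, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("auROC values must lie in [0, 1]")
    out = np.maximum(v, 1.0 - v)
    return float(out) if out.ndim == 0 else out


def perm_pvalue(real: float, surrogates: np.ndarray, tail: str = "greater") -> float:
    """Add-one permutation p-value: (1 + #{surrogate at least as extreme}) / (1 + n)."""
    surrogates = np.asarray(surrogates, dtype=float)
    if tail == "greater":
        k = int(np.sum(surrogates >= real))
    elif tail == "less":
        k = int(np.sum(surrogates <= real))
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    return (1 + k) / (1 + surrogates.size)


def max_pair_auroc_batch(rate_rows: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Rectified max-over-pairs auROC for many label-to-rate assignments at once.

    ``rate_rows`` is (K, n_trials) with trials grouped contiguously by
    direction (group g occupies columns ``offs[g]:offs[g+1]`` given by
    ``counts``); each row is one assignment of rates to that fixed grouping.
    Returns the per-row maximum over all unordered group pairs of the
    rectified auROC — the discriminability statistic.
    """
    rate_rows = np.atleast_2d(np.asarray(rate_rows, dtype=float))
    counts = np.asarray(counts, dtype=int)
    offs = np.concatenate([[0], np.cumsum(counts)])
    best = np.full(rate_rows.shape[0], 0.5)
    n_groups = counts.size
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            sub = np.concatenate(
                [rate_rows[:, offs[i] : offs[i + 1]], rate_rows[:, offs[j] : offs[j + 1]]],
                axis=1,
            )
            ranks = rankdata(sub, axis=1)
            m = counts[j]
            r_b = ranks[:, counts[i] :].sum(axis=1)
            v = (r_b - m * (m + 1) / 2.0) / (counts[i] * m)
            best = np.maximum(best, np.maximum(v, 1.0 - v))
    return best
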