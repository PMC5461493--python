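"""Diagonal linear discriminant analysis and fold-wise preprocessing.

The decoder is a Gaussian classifier with class-specific means and a single
pooled *diagonal* covariance (independent feature variances), trained with
uniform priors on balanced classes.  Preprocessing — per-feature
z-scoring and one-way-ANOVA feature selection — is always fitted on
training rows only and applied unchanged to test rows.

A vectorized leave-one-out engine computes, via exact rank-one downdates of
the class sums, the same per-fold models (including fold-wise ANOVA
selection) that a literal refit loop would produce.  Because the
discriminant is invariant to per-feature affine maps, and both the ANOVA F
statistic and the relative variance floor are scale-free, the fast path can
skip the per-fold re-standardization without changing any prediction; the
equivalence is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

__all__ = ["Preprocess", "preprocess_fit", "DiagLDA", "anova_f_pvalues", "loo_predict", "LOOModels"]

#: relative variance floor for degenerate (zero-variance) features
VAR_FLOOR_FRAC = 1e-6


def _floor_variances(var: np.ndarray) -> np.ndarray:
    scale = var.mean() if var.ndim == 1 else var.mean(axis=-1, keepdims=True)
    eps = VAR_FLOOR_FRAC * np.where(scale > 0, scale, 1.0)
    return np.maximum(var, eps)


def anova_f_pvalues(X: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    """One-way ANOVA p-value per feature (column) for a class main effect."""
    N, F = X.shape
    ss_total = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
    ssw = np.zeros(F)
    for c in range(n_classes):
        Xc = X[y == c]
        if len(Xc):
            ssw += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    ssb = ss_total - ssw
    df1, df2 = n_classes - 1, N - n_classes
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (ssb / df1) / (ssw / df2)
    p = np.where(
        ssw > 0,
        f_dist.sf(np.where(ssw > 0, fstat, 0.0), df1, df2),
        np.where(ssb > 0, 0.0, 1.0),  # all signal / no variation at all
    )
    return p


@dataclass
class Preprocess:
    """Fitted z-scoring parameters + ANOVA-selected feature set."""

    mean: np.ndarray
    sd: np.ndarray
    selected: np.ndarray  # boolean mask over features
    alpha: float

    def apply(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mean) / self.sd)[:, self.selected]


def preprocess_fit(
    X_train: np.ndarray, y_train: np.ndarray, n_classes: int, alpha: float = 0.01
) -> Preprocess:
    """Fit z-scoring and ANOVA feature selection on training rows only."""
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.sqrt(_floor_variances(sd**2))
    p = anova_f_pvalues(X_train, y_train, n_classes)
    return Preprocess(mean=mean, sd=sd, selected=p < alpha, alpha=alpha)


class DiagLDA:
    """Shared-diagonal-covariance Gaussian classifier with uniform priors.

    The score of class c for sample x is
    ``-sum_f (x_f - mu_{c,f})^2 / (2 sigma_f^2)`` (up to a constant);
    prediction ties break toward the lowest class index.
    """

    def fit(self, X: np.ndarray, y: np.ndarray, n_classes: int | None = None) -> "DiagLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if n_classes is None:
            n_classes = int(y.max()) + 1
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y, minlength=n_classes)
        if np.any(counts < 2):
            raise ValueError(f"every class needs >= 2 training rows; counts={counts.tolist()}")
        self.n_classes_ = n_classes
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in range(n_classes)])
        ssw = np.zeros(X.shape[1])
        for c in range(n_classes):
            ssw += ((X[y == c] - self.means_[c]) ** 2).sum(axis=0)
        pooled = ssw / (len(X) - n_classes)
        self.var_ = _floor_variances(pooled)
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = X[:, None, :] - self.means_[None, :, :]
        return -0.5 * (d**2 / self.var_[None, None, :]).sum(axis=2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X).argmax(axis=1)  # argmax -> lowest index on ties


@dataclass
class LOOModels:
    """Per-fold diagonal-LDA models: row i was trained on all rows but i."""

    mu: np.ndarray        # (N, C, F) class means
    inv_var: np.ndarray   # (N, F) 1 / pooled variance
    mask: np.ndarray      # (N, F) fold-wise ANOVA-selected features

    def predict_heldout(self, X_test: np.ndarray) -> np.ndarray:
        """Predict row i of X_test with the model that excluded row i."""
        d = X_test[:, None, :] - self.mu  # (N, C, F)
        scores = -np.einsum("ncf,nf->nc", d**2, self.inv_var * self.mask)
        return scores.argmax(axis=1)


def loo_fold_models(
    X: np.ndarray, y: np.ndarray, n_classes: int, alpha: float = 0.01
) -> LOOModels:
    """Exact leave-one-out fold models via rank-one downdates.

    Equivalent to refitting preprocessing (ANOVA selection at ``alpha``) and
    the classifier from scratch on each fold's N-1 training rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    N, F = X.shape
    C = n_classes
    counts = np.bincount(y, minlength=C).astype(float)
    if np.any(counts < 3):
        # a fold removes one row; remaining classes still need >= 2 rows
        raise ValueError(f"every class needs >= 3 rows for LOO; counts={counts.tolist()}")
    onehot = np.eye(C)[y]  # (N, C)
    S = onehot.T @ X       # (C, F) class sums
    Q = onehot.T @ X**2    # (C, F) class sums of squares

    n_fold = counts[None, :] - onehot                      # (N, C)
    S_fold = S[None, :, :] - onehot[:, :, None] * X[:, None, :]   # (N, C, F)
    mu = S_fold / n_fold[:, :, None]

    W = Q - S**2 / counts[:, None]                          # (C, F) within-class SS
    # within-class SS of the held-out row's class, with that row removed
    S_own = S[y] - X                                        # (N, F)
    n_own = counts[y] - 1.0
    W_own = Q[y] - X**2 - S_own**2 / n_own[:, None]
    ssw = W.sum(axis=0)[None, :] - W[y] + W_own             # (N, F)

    df2 = N - 1 - C
    pooled = ssw / df2
    inv_var = 1.0 / _floor_variances(pooled)

    # fold-wise ANOVA over the N-1 training rows
    tot_S = S.sum(axis=0)[None, :] - X
    tot_Q = Q.sum(axis=0)[None, :] - X**2
    ss_total = tot_Q - tot_S**2 / (N - 1)
    ssb = ss_total - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (ssb / (C - 1)) / (ssw / df2)
    pvals = np.where(
        ssw > 0,
        f_dist.sf(np.where(ssw > 0, fstat, 0.0), C - 1, df2),
        np.where(ssb > 0, 0.0, 1.0),
    )
    return LOOModels(mu=mu, inv_var=inv_var, mask=(pvals < alpha).astype(float))


def loo_predict(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    alpha: float = 0.01,
    X_test: np.ndarray | None = None,
) -> np.ndarray:
    """Leave-one-out predictions with fold-wise preprocessing.

    ``X_test``, when given, supplies the held-out feature vectors (same row
    order as ``X``) — used for cross-temporal decoding where training and
    testing read different time windows of the same trials.
    """
    models = loo_fold_models(X, y, n_classes, alpha)
    return models.predict_heldout(X if X_test is None else np.asarray(X_test, dtype=float))
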