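"""State-space analysis of the morphometry table.

The ten parameters are standardized to z-scores (X - X_mean)/X_SD and
embedded with a 3-component PCA; separation of the emotional states in
that space is summarized by the mean silhouette coefficient. The
neutral-interval statistic reports, for each parameter, what fraction of
another state's values fall above / below / within the neutral
mean ± 2 SD band.

The binary mouth-opening column is z-scored like every other column;
SDs are sample SDs (ddof=1). Zero-variance columns are flagged and
excluded rather than divided by zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score


@dataclass
class StandardizationStats:
    """Per-column mean/SD retained for the inverse mapping; ``kept``
    marks the columns that had nonzero variance."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # bool per original column

    def unstandardize(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd[self.kept] + self.mean[self.kept]


@dataclass
class Embedding:
    """PC scores (n x k), loadings (p x k) and explained-variance
    fractions, k <= 3."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray


def zscore(table) -> tuple[np.ndarray, StandardizationStats]:
    """Standardize columns to mean 0, SD 1 (sample SD).

    Accepts an array or DataFrame of shape (n, p), n >= 2. Zero-variance
    columns are dropped with a warning and recorded in the returned
    stats. Rows containing NaN must be handled by the caller.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("zscore needs a 2-D table with n >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    kept = sd > 0
    if not kept.all():
        warnings.warn(
            f"excluding {int((~kept).sum())} zero-variance column(s) "
            f"from standardization", stacklevel=2)
    Z = (X[:, kept] - mean[kept]) / sd[kept]
    return Z, StandardizationStats(mean=mean, sd=sd, kept=kept)


def pca3(standardized: np.ndarray, n_components: int = 3) -> Embedding:
    """Top principal components of a standardized table.

    Eigendecomposition of the sample covariance; components are ordered
    by decreasing eigenvalue and each loading column's sign is fixed so
    its largest-magnitude entry is positive. If the matrix rank is below
    ``n_components`` the embedding is reduced with a warning.
    """
    Z = np.asarray(standardized, dtype=float)
    n, p = Z.shape
    if n < 4:
        raise ValueError("pca3 needs at least 4 rows")
    Zc = Z - Z.mean(axis=0)
    cov = Zc.T @ Zc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = int((evals > 1e-10 * max(evals[0], 1.0)).sum())
    k = min(n_components, p)
    if rank < k:
        warnings.warn(f"rank {rank} < {k}; returning {rank} component(s)",
                      stacklevel=2)
        k = max(rank, 1)
    load = evecs[:, :k].copy()
    for j in range(k):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    scores = Zc @ load
    total = evals.sum()
    frac = evals[:k] / total if total > 0 else np.zeros(k)
    return Embedding(scores=scores, loadings=load,
                     explained_variance_fraction=frac)


def total_variance(standardized: np.ndarray) -> float:
    """Sum of all covariance eigenvalues; equals the number of columns
    on perfectly standardized data."""
    Z = np.asarray(standardized, dtype=float)
    Zc = Z - Z.mean(axis=0)
    cov = Zc.T @ Zc / (Z.shape[0] - 1)
    return float(np.trace(cov))


def coverage_2sd(neutral_values, other_values) -> dict[str, float]:
    """Percent of ``other_values`` above / below / within the neutral
    mean ± 2 SD interval (sample SD). The three fractions sum to 100."""
    x = np.asarray(neutral_values, dtype=float)
    y = np.asarray(other_values, dtype=float)
    if x.size < 2 or y.size == 0:
        raise ValueError("coverage_2sd needs >= 2 neutral and >= 1 other values")
    lo = x.mean() - 2 * x.std(ddof=1)
    hi = x.mean() + 2 * x.std(ddof=1)
    above = float((y > hi).mean() * 100)
    below = float((y < lo).mean() * 100)
    return {"above": above, "below": below,
            "within": 100.0 - above - below}


def separation_score(scores: np.ndarray, labels) -> float:
    """Mean silhouette coefficient of the labeled points; in [-1, 1].

    Classes with a single member are excluded with a warning (the
    silhouette is undefined for them).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = np.asarray(labels)
    vals, counts = np.unique(labels, return_counts=True)
    keep_classes = vals[counts >= 2]
    if len(keep_classes) < 2:
        raise ValueError("separation_score needs >= 2 classes with >= 2 members")
    if len(keep_classes) < len(vals):
        warnings.warn("excluding singleton class(es) from silhouette",
                      stacklevel=2)
        sel = np.isin(labels, keep_classes)
        scores, labels = scores[sel], labels[sel]
    return float(silhouette_score(scores, labels))
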