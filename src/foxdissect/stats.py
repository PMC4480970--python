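"""Exact set statistics and sample-level summaries.

The inferential layer on the regulation-call summaries: exact two-sided
binomial tests of a direction split against the baseline split of all
regulated genes, Fisher 2x2 enrichment, Euclidean sample distances, PCA
variance fractions and hierarchical clustering.

Point masses are computed through log-gamma so that p-values on the
1e-70 scale neither underflow nor lose precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

# relative slack when comparing point masses, so that masses equal to the
# observed one up to float rounding are still counted (same convention as
# the common exact-test implementations)
_REL_EPS = 1e-7


def _binom_logpmf(k: np.ndarray, n: int, p: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + k * np.log(p) + (n - k) * np.log1p(-p))


def binom_two_sided(x: int, n: int, p0: float, method: str = "min_likelihood") -> float:
    """Exact two-sided binomial test of ``x`` successes in ``n`` trials.

    ``method='min_likelihood'`` (default): sum of all point masses not
    exceeding the mass at ``x`` — the standard exact two-sided convention.
    ``method='doubling'``: twice the smaller tail, capped at 1.
    """
    if not (0 <= x <= n) or n < 1:
        raise ValueError("require 0 <= x <= n, n >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    ks = np.arange(n + 1)
    logpmf = _binom_logpmf(ks, n, p0)
    if method == "min_likelihood":
        cutoff = logpmf[x] + np.log1p(_REL_EPS)
        p = float(np.exp(logpmf[logpmf <= cutoff]).sum())
    elif method == "doubling":
        pmf = np.exp(logpmf)
        lower = pmf[: x + 1].sum()
        upper = pmf[x:].sum()
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return min(p, 1.0)


@dataclass
class DirectionSplit:
    """Up/down counts of a gene set with the regulated-set baseline split."""

    n_up: int
    n_down: int
    baseline_up: int
    baseline_total: int

    def __post_init__(self) -> None:
        if self.n_up < 0 or self.n_down < 0 or self.n_up + self.n_down < 1:
            raise ValueError("need at least one gene in the set")
        if not (0 < self.baseline_up < self.baseline_total):
            raise ValueError("baseline must be a proper split")


def direction_distribution_test(split: DirectionSplit, method: str = "min_likelihood") -> float:
    """Two-sided binomial test of a set's up/down split vs the baseline."""
    p0 = split.baseline_up / split.baseline_total
    return binom_two_sided(split.n_up, split.n_up + split.n_down, p0, method=method)


def go_term_distribution_test(n_immuno: int, n_other: int,
                              baseline_immuno: int, baseline_other: int,
                              method: str = "min_likelihood") -> float:
    """Binomial test of an immunology/other term split vs the baseline list."""
    if baseline_immuno <= 0 or baseline_other <= 0:
        raise ValueError("baseline counts must be positive")
    p0 = baseline_immuno / (baseline_immuno + baseline_other)
    return binom_two_sided(n_immuno, n_immuno + n_other, p0, method=method)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    Sums hypergeometric point masses not exceeding the observed table's
    mass, with margins fixed.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c
    k_min = max(0, r1 + c1 - n)
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    logpmf = (gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
              + gammaln(n - r1 + 1) - gammaln(c1 - ks + 1) - gammaln(n - r1 - c1 + ks + 1)
              - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))
    obs = logpmf[ks == a][0]
    keep = logpmf <= obs + np.log1p(_REL_EPS)
    return float(min(np.exp(logpmf[keep]).sum(), 1.0))


def sample_distances(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples (columns of ``expr``)."""
    if expr.isna().any().any():
        raise ValueError("missing values in expression matrix")
    d = squareform(pdist(expr.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def pca_summary(expr: pd.DataFrame):
    """Centered PCA over samples.

    ``expr`` is gene-by-sample; samples are the observations.  Returns
    ``(scores, variance_fractions)`` where ``scores`` is a sample-by-PC
    DataFrame and fractions sum to 1.
    """
    X = expr.to_numpy().T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant expression matrix")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    scores = pd.DataFrame(U * s, index=expr.columns,
                          columns=[f"PC{i+1}" for i in range(len(s))])
    return scores, frac


def hierarchical_cluster(dist: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """Agglomerative clustering on a symmetric distance matrix.

    Returns the scipy linkage matrix (merge order and heights).
    """
    d = dist.to_numpy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    return linkage(squareform(d, checks=False), method=method)


def rlog_like(norm_counts: pd.DataFrame) -> pd.DataFrame:
    """Simple variance-stabilizing stand-in: log2(normalized count + 1).

    Used for clustering/PCA inputs; deliberately not a regularized-log
    reimplementation.
    """
    return np.log2(norm_counts + 1.0)
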