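"""Robust FPKM and NE/LE/INT/HE expression classification.

Bulk RNA-seq expression of a replicate, viewed on the log2-FPKM scale, is
bimodal: a low mode of background/leaky transcription (LE) and a high mode
of genuinely expressed genes (HE).  Each replicate is classified
independently: genes with zero counts are "not expressed" (NE); the
remaining log2-FPKM values are fitted with a two-component unequal-variance
Gaussian mixture by expectation-maximization, and class boundaries are
placed where the tail false discovery rate of each class crosses a target
level (default 0.05).  Genes between the boundaries are "intermediate"
(INT).

The classes feed the differential-expression filter downstream: genes that
never leave the NE/LE modes in either condition of a contrast are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from foxdissect.io import CountMatrix

CLASS_ORDER = ["NE", "LE", "INT", "HE"]


def compute_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    The per-gene reference is the geometric mean of counts across samples,
    restricted to genes with no zero count in any sample; each sample's
    factor is the median ratio of its counts to the reference.
    """
    counts = cm.counts.to_numpy(dtype=float)
    no_zero = (counts > 0).all(axis=1)
    if not no_zero.any():
        raise ValueError("cannot form reference: every gene has a zero count in some sample")
    ref = np.exp(np.mean(np.log(counts[no_zero]), axis=1))
    factors = np.median(counts[no_zero] / ref[:, None], axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor")
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def compute_fpkm(cm: CountMatrix, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million, on size-factor-normalized counts.

    FPKM_gj = (c_gj / s_j) / (len_g / 1e3) / (S_j / 1e6) where S_j is the
    column total of normalized counts.  Zero counts map to zero FPKM.
    """
    if size_factors is None:
        size_factors = compute_size_factors(cm)
    norm_counts = cm.counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    col_totals = norm_counts.sum(axis=0)
    if (col_totals <= 0).any():
        raise ValueError("sample with zero total counts")
    kb = cm.gene_lengths.to_numpy() / 1e3
    fpkm = norm_counts / kb[:, None] / (col_totals[None, :] / 1e6)
    return pd.DataFrame(fpkm, index=cm.counts.index, columns=cm.counts.columns)


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture on log2 FPKM, ordered by mean."""

    pi_LE: float
    pi_HE: float
    mu_LE: float
    mu_HE: float
    sigma_LE: float
    sigma_HE: float
    loglik: float
    n_points: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.mu_LE < self.mu_HE):
            raise ValueError("components must be ordered by mean")
        if self.sigma_LE <= 0 or self.sigma_HE <= 0:
            raise ValueError("component sd must be positive")


def _em_loglik(x: np.ndarray, pi: float, mu1: float, s1: float, mu2: float, s2: float) -> float:
    d = pi * norm.pdf(x, mu1, s1) + (1.0 - pi) * norm.pdf(x, mu2, s2)
    return float(np.sum(np.log(np.maximum(d, 1e-300))))


def _em_run(x: np.ndarray, pi: float, mu1: float, s1: float, mu2: float, s2: float,
            max_iter: int, tol: float, sigma_floor: float = 1e-3):
    """One EM run from one start point; log-likelihood is non-decreasing."""
    ll = _em_loglik(x, pi, mu1, s1, mu2, s2)
    converged = False
    for _ in range(max_iter):
        # E step: responsibilities of component 1
        p1 = pi * norm.pdf(x, mu1, s1)
        p2 = (1.0 - pi) * norm.pdf(x, mu2, s2)
        tot = np.maximum(p1 + p2, 1e-300)
        r = p1 / tot
        # M step
        n1 = r.sum()
        n2 = len(x) - n1
        if n1 < 1e-10 or n2 < 1e-10:
            break  # a component died: leave parameters at last stable value
        pi = n1 / len(x)
        mu1 = float(np.sum(r * x) / n1)
        mu2 = float(np.sum((1 - r) * x) / n2)
        s1 = max(float(np.sqrt(np.sum(r * (x - mu1) ** 2) / n1)), sigma_floor)
        s2 = max(float(np.sqrt(np.sum((1 - r) * (x - mu2) ** 2) / n2)), sigma_floor)
        ll_new = _em_loglik(x, pi, mu1, s1, mu2, s2)
        # EM guarantee up to the sigma floor; tolerate tiny float noise
        assert ll_new >= ll - 1e-8 * max(1.0, abs(ll)), "EM log-likelihood decreased"
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return pi, mu1, s1, mu2, s2, ll, converged


def fit_bimodal(values: np.ndarray, max_iter: int = 500, tol: float = 1e-8,
                n_restarts: int = 5, seed: int = 0) -> MixtureFit:
    """Fit a two-component unequal-variance Gaussian mixture by EM.

    Parameters
    ----------
    values
        Finite log2-FPKM values of expressed genes in one replicate
        (NE genes must be excluded by the caller).
    n_restarts
        Number of random restarts in addition to the deterministic
        median-split initialization; the best log-likelihood wins.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError("need at least 50 finite values to fit a mixture")
    if np.ptp(x) < 1e-12:
        raise ValueError("unimodal/degenerate input: all values equal")

    starts = []
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(lo) >= 2 and len(hi) >= 2:
        starts.append((0.5, float(lo.mean()), max(float(lo.std()), 1e-2),
                       float(hi.mean()), max(float(hi.std()), 1e-2)))
    rng = np.random.default_rng(seed)
    sd = float(x.std())
    for _ in range(n_restarts):
        m1, m2 = sorted(rng.uniform(x.min(), x.max(), size=2))
        starts.append((float(rng.uniform(0.2, 0.8)), m1, sd / 2, m2, sd / 2))

    best = None
    for s in starts:
        fit = _em_run(x, *s, max_iter=max_iter, tol=tol)
        if best is None or fit[5] > best[5]:
            best = fit
    pi, mu1, s1, mu2, s2, ll, converged = best
    if mu1 > mu2:  # order components by mean
        pi, mu1, s1, mu2, s2 = 1.0 - pi, mu2, s2, mu1, s1
    return MixtureFit(pi_LE=float(pi), pi_HE=float(1.0 - pi), mu_LE=mu1, mu_HE=mu2,
                      sigma_LE=s1, sigma_HE=s2, loglik=ll, n_points=len(x),
                      converged=converged)


@dataclass
class ClassBoundaries:
    """LE/HE class boundaries on the log2-FPKM axis at a target FDR."""

    t_LE: float
    t_HE: float
    fdr: float = 0.05
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.t_LE > self.t_HE + 1e-9:
            raise ValueError("t_LE must not exceed t_HE")


def _fdr_he(fit: MixtureFit, x: float) -> float:
    """Tail FDR of calling > x "HE": LE mass above x over total mass above x."""
    a = fit.pi_LE * norm.sf(x, fit.mu_LE, fit.sigma_LE)
    b = fit.pi_HE * norm.sf(x, fit.mu_HE, fit.sigma_HE)
    return a / (a + b) if (a + b) > 0 else 0.0


def _fdr_le(fit: MixtureFit, x: float) -> float:
    """Tail FDR of calling < x "LE": HE mass below x over total mass below x."""
    a = fit.pi_HE * norm.cdf(x, fit.mu_HE, fit.sigma_HE)
    b = fit.pi_LE * norm.cdf(x, fit.mu_LE, fit.sigma_LE)
    return a / (a + b) if (a + b) > 0 else 0.0


def class_boundaries(fit: MixtureFit, fdr: float = 0.05) -> ClassBoundaries:
    """Place LE/HE boundaries where each tail FDR crosses ``fdr``.

    t_HE is the smallest x whose HE-call tail FDR is at or below ``fdr``;
    t_LE the largest x whose LE-call tail FDR is at or below ``fdr``.  Both
    are located by bisection to 1e-6.  When the components are so separated
    that the FDR never exceeds ``fdr`` between the means, the crossing of
    the two scaled component densities is returned for both, flagged
    degenerate.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    span = 10.0 * max(fit.sigma_LE, fit.sigma_HE)
    lo = fit.mu_LE - span
    hi = fit.mu_HE + span

    def bisect(f, a, b, increasing):
        # smallest (decreasing f) / largest (increasing f) x with f(x) <= fdr
        for _ in range(200):
            m = 0.5 * (a + b)
            if (f(m) <= fdr) != increasing:
                b = m
            else:
                a = m
            if b - a < 1e-7:
                break
        return 0.5 * (a + b)

    if _fdr_he(fit, lo) <= fdr or _fdr_le(fit, hi) <= fdr:
        # components effectively disjoint: fall back to the density crossing
        def diff(x):
            return (fit.pi_LE * norm.pdf(x, fit.mu_LE, fit.sigma_LE)
                    - fit.pi_HE * norm.pdf(x, fit.mu_HE, fit.sigma_HE))
        try:
            t = float(brentq(diff, fit.mu_LE, fit.mu_HE, xtol=1e-8))
        except ValueError:
            t = 0.5 * (fit.mu_LE + fit.mu_HE)
        return ClassBoundaries(t_LE=t, t_HE=t, fdr=fdr, degenerate=True)

    t_he = bisect(lambda x: _fdr_he(fit, x), lo, hi, increasing=False)
    t_le = bisect(lambda x: _fdr_le(fit, x), lo, hi, increasing=True)
    if t_le > t_he:  # heavy overlap: collapse INT to a single point
        t_le = t_he = 0.5 * (t_le + t_he)
    return ClassBoundaries(t_LE=t_le, t_HE=t_he, fdr=fdr)


def posterior_boundaries(fit: MixtureFit, fdr: float = 0.05) -> ClassBoundaries:
    """Alternative boundary rule based on the local posterior probability.

    t_HE is the smallest x where the posterior of the LE component drops to
    ``fdr``; t_LE the largest x where the posterior of the HE component is
    ``fdr``.  Kept as an alternative to the default tail-FDR rule.
    """
    def post_le(x):
        a = fit.pi_LE * norm.pdf(x, fit.mu_LE, fit.sigma_LE)
        b = fit.pi_HE * norm.pdf(x, fit.mu_HE, fit.sigma_HE)
        return a / (a + b) if (a + b) > 0 else 0.0

    span = 10.0 * max(fit.sigma_LE, fit.sigma_HE)
    lo, hi = fit.mu_LE - span, fit.mu_HE + span
    try:
        t_he = float(brentq(lambda x: post_le(x) - fdr, fit.mu_LE, hi, xtol=1e-8))
    except ValueError:
        t_he = fit.mu_HE
    try:
        t_le = float(brentq(lambda x: (1.0 - post_le(x)) - fdr, lo, fit.mu_HE, xtol=1e-8))
    except ValueError:
        t_le = fit.mu_LE
    if t_le > t_he:
        t_le = t_he = 0.5 * (t_le + t_he)
    return ClassBoundaries(t_LE=t_le, t_HE=t_he, fdr=fdr)


def classify_genes(fpkm: pd.DataFrame, counts: pd.DataFrame,
                   boundaries: dict[str, ClassBoundaries]) -> pd.DataFrame:
    """Assign NE/LE/INT/HE per gene per replicate.

    Zero counts give NE; otherwise log2 FPKM at or below t_LE gives LE, at
    or above t_HE gives HE, strictly between gives INT.  ``boundaries``
    maps sample id to that replicate's fitted boundaries.
    """
    missing = set(fpkm.columns) - set(boundaries)
    if missing:
        raise ValueError(f"missing boundaries for samples: {sorted(missing)}")
    out = pd.DataFrame("INT", index=fpkm.index, columns=fpkm.columns)
    for s in fpkm.columns:
        b = boundaries[s]
        with np.errstate(divide="ignore"):
            lv = np.log2(fpkm[s].to_numpy())
        col = np.full(len(fpkm), "INT", dtype=object)
        col[lv <= b.t_LE] = "LE"
        col[lv >= b.t_HE] = "HE"
        col[counts[s].to_numpy() == 0] = "NE"
        out[s] = col
    return out


def classify_replicates(cm: CountMatrix, fdr: float = 0.05, seed: int = 0,
                        boundary_rule: str = "tail"):
    """Fit a mixture and boundaries per replicate and classify every gene.

    Returns ``(classes, fits, bounds, fpkm)`` where ``classes`` is a
    gene-by-sample DataFrame of labels.
    """
    sf = compute_size_factors(cm)
    fpkm = compute_fpkm(cm, sf)
    fits: dict[str, MixtureFit] = {}
    bounds: dict[str, ClassBoundaries] = {}
    rule = {"tail": class_boundaries, "posterior": posterior_boundaries}[boundary_rule]
    for s in cm.sample_ids:
        expressed = fpkm[s].to_numpy()
        expressed = expressed[cm.counts[s].to_numpy() > 0]
        fit = fit_bimodal(np.log2(expressed), seed=seed)
        fits[s] = fit
        bounds[s] = rule(fit, fdr=fdr)
    classes = classify_genes(fpkm, cm.counts, bounds)
    return classes, fits, bounds, fpkm
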