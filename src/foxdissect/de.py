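"""Simplified negative-binomial Wald differential expression.

This stage honors the standard NB-GLM contract — per-gene dispersion
estimation with shrinkage toward a mean-dispersion trend, moderated log2
fold changes via a zero-centered normal prior, Wald tests and
Benjamini–Hochberg adjustment — without reproducing any particular
engine's numerics.  It is deliberately pluggable: downstream set logic
consumes only the :class:`DEResult` columns.

Model: counts ~ NB(mu, alpha) with variance mu + alpha * mu^2,
mu_gj = s_j * q_g * 2^(beta_g * [j in B]) for a two-condition contrast
A vs B; beta is the log2 fold change of B over A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm

from foxdissect.io import CountMatrix


@dataclass
class Contrast:
    """A two-condition comparison; log2 fold changes are B relative to A."""

    condition_A: str
    condition_B: str


@dataclass
class DEResult:
    """Per-gene DE summary for one contrast.

    ``table`` columns: baseMean, log2fc, se, p, padj, dispersion; index is
    the gene id.  Untestable genes (all-zero in both conditions) carry NaN
    statistics and are excluded from the BH denominator.
    """

    contrast: Contrast
    table: pd.DataFrame


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    NaN entries pass through unchanged and do not count toward the number
    of tests.  padj_i = min over ranks >= rank(i) of p_j * m / rank_j,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    defined = ~np.isnan(p)
    pd_ = p[defined]
    if ((pd_ < 0) | (pd_ > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pd_)
    if m == 0:
        return out
    order = np.argsort(pd_, kind="stable")
    ranked = pd_[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[defined] = res
    return out


def estimate_dispersions(cm: CountMatrix, size_factors: pd.Series,
                         conditions: list[str] | None = None,
                         prior_df: float = 30.0,
                         trend_min_mean: float = 5.0) -> pd.Series:
    """Per-gene NB dispersion with shrinkage toward a 1/mean trend.

    Method-of-moments within-condition estimates are pooled, a trend
    ``alpha(mu) = a + b/mu`` is fitted over well-expressed genes, and the
    per-gene estimate is shrunk toward the trend with weight proportional
    to the residual degrees of freedom against ``prior_df`` pseudo-d.f.
    All-zero genes get NaN (untestable).
    """
    if conditions is None:
        conditions = cm.conditions
    y = cm.counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    groups = [np.array([cm.sample_ids.index(s) for s in cm.samples_of(c)]) for c in conditions]
    n_total = sum(len(g) for g in groups)
    df = n_total - len(groups)
    if df < 1:
        raise ValueError("need at least 2 replicates in some condition")

    # pooled within-condition variance and overall mean
    ss = np.zeros(y.shape[0])
    mean_all = np.zeros(y.shape[0])
    n_used = 0
    for g in groups:
        sub = y[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        mean_all += sub.sum(axis=1)
        n_used += len(g)
    mean_all /= n_used
    s2 = ss / df

    # untruncated method-of-moments value: noisy but unbiased, so the trend
    # regression is not pushed upward by flooring at zero
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mm = (s2 - mean_all) / mean_all**2
    alpha_mm = np.where(mean_all > 0, alpha_mm, np.nan)

    # trend alpha(mu) = a + b/mu over well-expressed genes.  Per-gene MoM
    # values share their noise with the regressor 1/mean, which attenuates a
    # naive OLS fit; pooling second moments within log-spaced mean bins and
    # fitting the line through the bin aggregates avoids that bias.
    sel = (mean_all >= trend_min_mean) & np.isfinite(alpha_mm)
    a = b = None
    if sel.sum() >= 200:
        bins = np.geomspace(trend_min_mean, mean_all[sel].max() + 1.0, 16)
        bin_idx = np.digitize(mean_all[sel], bins)
        mus, alphas, weights = [], [], []
        for bi in np.unique(bin_idx):
            mask = bin_idx == bi
            if mask.sum() >= 20:
                mm, vv = mean_all[sel][mask], s2[sel][mask]
                mus.append(mm.mean())
                alphas.append((vv.mean() - mm.mean()) / (mm**2).mean())
                weights.append(mask.sum())
        if len(mus) >= 3:
            X = np.column_stack([np.ones(len(mus)), 1.0 / np.asarray(mus)])
            W = np.asarray(weights, dtype=float)
            coef = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * np.asarray(alphas)))
            a, b = float(coef[0]), max(float(coef[1]), 0.0)
    if a is None and sel.sum() >= 10:
        X = np.column_stack([np.ones(sel.sum()), 1.0 / mean_all[sel]])
        coef, *_ = np.linalg.lstsq(X, alpha_mm[sel], rcond=None)
        a, b = float(coef[0]), max(float(coef[1]), 0.0)
    if a is None:
        a, b = float(np.nanmedian(alpha_mm)), 0.0
    with np.errstate(divide="ignore"):
        trend = np.maximum(a + b / np.maximum(mean_all, 1e-12), 0.0)

    alpha = (df * alpha_mm + prior_df * trend) / (df + prior_df)
    alpha = np.maximum(alpha, 1e-8)  # floor only after shrinkage
    alpha = np.where(mean_all > 0, alpha, np.nan)
    return pd.Series(alpha, index=cm.counts.index, name="dispersion")


def _nb_negloglik_and_grad(params, k_a, s_a, k_b, s_b, alpha, prior_sd):
    """Penalized NB negative log-likelihood in (log q, beta) and gradient."""
    logq, beta = params
    ln2 = np.log(2.0)
    q = np.exp(logq)
    inv_a = 1.0 / alpha
    nll = 0.0
    g_logq = 0.0
    g_beta = 0.0
    for k, s, scale_beta in ((k_a, s_a, 0.0), (k_b, s_b, 1.0)):
        mu = s * q * 2.0 ** (beta * scale_beta)
        nll -= np.sum(gammaln(k + inv_a) - gammaln(inv_a) - gammaln(k + 1.0)
                      + k * np.log(alpha * mu / (1.0 + alpha * mu))
                      - inv_a * np.log1p(alpha * mu))
        # d nll / d log mu, then chain through logq (1) and beta (ln2 * scale)
        dmu = -(k - (k + inv_a) * (alpha * mu) / (1.0 + alpha * mu))
        g_logq += np.sum(dmu)
        g_beta += np.sum(dmu) * scale_beta * ln2
    nll += 0.5 * beta**2 / prior_sd**2
    g_beta += beta / prior_sd**2
    return nll, np.array([g_logq, g_beta])


def wald_test(cm: CountMatrix, size_factors: pd.Series, contrast: Contrast,
              dispersions: pd.Series, shrinkage_prior_sd: float = 2.0) -> DEResult:
    """Moderated log2 fold change and Wald p for one two-condition contrast.

    The fold change is the posterior mode under a zero-centered normal
    prior (sd ``shrinkage_prior_sd``); the standard error comes from the
    observed information of the penalized log-likelihood at the optimum.
    """
    samples_a = cm.samples_of(contrast.condition_A)
    samples_b = cm.samples_of(contrast.condition_B)
    sf = size_factors
    ka = cm.counts[samples_a].to_numpy(dtype=float)
    kb = cm.counts[samples_b].to_numpy(dtype=float)
    sa = sf[samples_a].to_numpy()
    sb = sf[samples_b].to_numpy()
    alphas = dispersions.loc[cm.counts.index].to_numpy()

    n = len(cm.counts)
    log2fc = np.full(n, np.nan)
    se = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    base_mean = (np.concatenate([ka / sa[None, :], kb / sb[None, :]], axis=1)).mean(axis=1)

    for i in range(n):
        if not np.isfinite(alphas[i]):
            continue
        ra, rb = ka[i], kb[i]
        if ra.sum() == 0 and rb.sum() == 0:
            continue
        q0 = max(base_mean[i], 1e-8)
        ma = max((ra / sa).mean(), 1e-8)
        mb = max((rb / sb).mean(), 1e-8)
        x0 = np.array([np.log(q0), np.clip(np.log2(mb / ma), -10, 10)])
        res = minimize(_nb_negloglik_and_grad, x0, jac=True,
                       args=(ra, sa, rb, sb, max(alphas[i], 1e-8), shrinkage_prior_sd),
                       method="L-BFGS-B")
        beta = float(res.x[1])
        # observed information by central differences on the gradient
        h = 1e-4
        info = np.zeros((2, 2))
        for j in range(2):
            xp = res.x.copy(); xp[j] += h
            xm = res.x.copy(); xm[j] -= h
            _, gp = _nb_negloglik_and_grad(xp, ra, sa, rb, sb, max(alphas[i], 1e-8), shrinkage_prior_sd)
            _, gm = _nb_negloglik_and_grad(xm, ra, sa, rb, sb, max(alphas[i], 1e-8), shrinkage_prior_sd)
            info[:, j] = (gp - gm) / (2 * h)
        info = 0.5 * (info + info.T)
        try:
            cov = np.linalg.inv(info)
            se_i = float(np.sqrt(max(cov[1, 1], 1e-30)))
        except np.linalg.LinAlgError:
            se_i = np.nan
        log2fc[i] = beta
        se[i] = se_i
        if np.isfinite(se_i) and se_i > 0:
            pval[i] = 2.0 * norm.sf(abs(beta) / se_i)

    padj = bh_adjust(pval)
    table = pd.DataFrame(
        {"baseMean": base_mean, "log2fc": log2fc, "se": se,
         "p": pval, "padj": padj, "dispersion": alphas},
        index=cm.counts.index,
    )
    return DEResult(contrast=contrast, table=table)


def run_de(cm: CountMatrix, contrast_pairs: list[tuple[str, str]],
           shrinkage_prior_sd: float = 2.0) -> dict[tuple[str, str], DEResult]:
    """Dispersion estimation plus Wald tests for several contrasts."""
    from foxdissect.classify import compute_size_factors

    sf = compute_size_factors(cm)
    disp = estimate_dispersions(cm, sf)
    return {
        (a, b): wald_test(cm, sf, Contrast(a, b), disp, shrinkage_prior_sd)
        for a, b in contrast_pairs
    }
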