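import numpy as np
import pandas as pd
import pytest

from foxdissect.classify import (ClassBoundaries, MixtureFit, class_boundaries,
                                 classify_genes, classify_replicates,
                                 compute_fpkm, compute_size_factors, fit_bimodal,
                                 posterior_boundaries)
from foxdissect.io import CountMatrix


def _cm(counts: pd.DataFrame, lengths=None) -> CountMatrix:
    if lengths is None:
        lengths = pd.Series(1000.0, index=counts.index)
    meta = pd.DataFrame({"condition": ["x"] * counts.shape[1],
                         "replicate": range(1, counts.shape[1] + 1)},
                        index=counts.columns)
    return CountMatrix(counts=counts, gene_lengths=lengths, metadata=meta)


# ---------------------------------------------------------------- size factors

def test_size_factors_identical_samples():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]},
                          index=["g1", "g2", "g3"])
    sf = compute_size_factors(_cm(counts))
    assert np.allclose(sf, [1.0, 1.0])


def test_size_factors_doubled_sample():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                          index=["g1", "g2", "g3"])
    sf = compute_size_factors(_cm(counts))
    assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_zero_gene_excluded_from_reference():
    base = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                        index=["g1", "g2", "g3"])
    with_zero = pd.concat([base, pd.DataFrame({"s1": [0], "s2": [999]}, index=["gz"])])
    assert np.allclose(compute_size_factors(_cm(with_zero)),
                       compute_size_factors(_cm(base)))


def test_size_factors_no_reference_error():
    counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="cannot form reference"):
        compute_size_factors(_cm(counts))


# ------------------------------------------------------------------------ FPKM

def test_fpkm_direct_substitution():
    # single sample, size factor 1, column total 1e6, length 1 kb, count 100
    counts = pd.DataFrame({"s1": [100, 1_000_000 - 100]}, index=["g1", "g2"])
    lengths = pd.Series([1000.0, 2000.0], index=counts.index)
    cm = _cm(counts, lengths)
    fpkm = compute_fpkm(cm, size_factors=pd.Series([1.0], index=["s1"]))
    assert fpkm.loc["g1", "s1"] == pytest.approx(100.0)


def test_fpkm_zero_count_is_zero(tiny_counts):
    fpkm = compute_fpkm(tiny_counts)
    assert (fpkm.loc["g4"] == 0).all()


def test_fpkm_invariant_under_sample_rescaling():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(1, 1000, size=(50, 3)),
                          index=[f"g{i}" for i in range(50)],
                          columns=["s1", "s2", "s3"])
    cm = _cm(counts)
    doubled = counts.copy()
    doubled["s2"] = doubled["s2"] * 2
    cm2 = _cm(doubled)
    pd.testing.assert_frame_equal(compute_fpkm(cm), compute_fpkm(cm2))


# -------------------------------------------------------------------- EM fits

def test_fit_bimodal_recovers_planted_mixture():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(-2, 1, 2500), rng.normal(6, 1, 2500)])
    fit = fit_bimodal(x, seed=0)
    assert abs(fit.mu_LE - (-2)) < 0.1 and abs(fit.mu_HE - 6) < 0.1
    assert abs(fit.pi_LE - 0.5) < 0.03
    assert fit.converged


def test_fit_bimodal_matches_reference_mixture_library():
    # independent cross-check of the hand-written EM, not the implementation
    sklearn = pytest.importorskip("sklearn.mixture")
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(-1, 0.8, 1500), rng.normal(4, 1.5, 3000)])
    fit = fit_bimodal(x, seed=0)
    gm = sklearn.GaussianMixture(2, n_init=5, random_state=0, tol=1e-8,
                                 max_iter=500).fit(x[:, None])
    means = np.sort(gm.means_.ravel())
    assert abs(fit.mu_LE - means[0]) < 0.05
    assert abs(fit.mu_HE - means[1]) < 0.05


def test_fit_bimodal_degenerate_input():
    with pytest.raises(ValueError, match="degenerate"):
        fit_bimodal(np.full(100, 3.0))


def test_fit_bimodal_needs_50_values():
    with pytest.raises(ValueError, match="50"):
        fit_bimodal(np.arange(49, dtype=float))


def test_fit_bimodal_ordering_across_seeds():
    rng = np.random.default_rng(5)
    x = np.concatenate([rng.normal(0, 1, 500), rng.normal(3, 2, 500)])
    for seed in range(5):
        fit = fit_bimodal(x, seed=seed)
        assert fit.mu_LE < fit.mu_HE
        assert fit.sigma_LE > 0 and fit.sigma_HE > 0


# ------------------------------------------------------------------ boundaries

WELLSEP = dict(pi_LE=0.5, pi_HE=0.5, mu_LE=-2.0, mu_HE=6.0,
               sigma_LE=1.0, sigma_HE=1.0, loglik=0.0, n_points=1000)


def test_boundary_tail_fdr_closed_form():
    # tail FDR of an HE call at x=2 is ~3.2e-5 <= 0.05, so t_HE <= 2
    from scipy.stats import norm
    fit = MixtureFit(**WELLSEP)
    a = 0.5 * norm.sf(2, -2, 1)
    b = 0.5 * norm.sf(2, 6, 1)
    assert a / (a + b) == pytest.approx(3.2e-5, rel=0.1)
    bounds = class_boundaries(fit, fdr=0.05)
    assert bounds.t_HE <= 2.0
    assert bounds.t_LE <= bounds.t_HE


def test_boundary_monotone_in_fdr():
    rng = np.random.default_rng(7)
    for _ in range(20):
        mu1 = rng.uniform(-4, 0)
        mu2 = mu1 + rng.uniform(1, 8)
        pi = rng.uniform(0.2, 0.8)
        fit = MixtureFit(pi_LE=pi, pi_HE=1.0 - pi, mu_LE=mu1,
                         mu_HE=mu2, sigma_LE=rng.uniform(0.5, 2),
                         sigma_HE=rng.uniform(0.5, 2), loglik=0.0, n_points=100)
        b05 = class_boundaries(fit, fdr=0.05)
        b01 = class_boundaries(fit, fdr=0.01)
        assert b05.t_LE <= b05.t_HE and b01.t_LE <= b01.t_HE
        collapsed = (b05.degenerate or b01.degenerate
                     or b05.t_LE == b05.t_HE or b01.t_LE == b01.t_HE)
        if not collapsed:  # midpoint collapse breaks per-bound monotonicity
            assert b01.t_HE >= b05.t_HE - 1e-6
            assert b01.t_LE <= b05.t_LE + 1e-6


def test_boundary_degenerate_flag_when_fdr_never_reached():
    # pi_LE <= fdr keeps the HE tail FDR below target everywhere, so the
    # boundary falls back to the scaled-density crossing, flagged degenerate
    fit = MixtureFit(pi_LE=0.02, pi_HE=0.98, mu_LE=-2.0, mu_HE=6.0,
                     sigma_LE=1.0, sigma_HE=1.0, loglik=0.0, n_points=100)
    b = class_boundaries(fit, fdr=0.05)
    assert b.degenerate and b.t_LE == b.t_HE
    assert fit.mu_LE < b.t_LE < fit.mu_HE


def test_boundary_collapse_at_extreme_separation():
    # equal weights, huge separation: both raw boundaries land in the gap
    # and the result is a single cut point between the means
    fit = MixtureFit(pi_LE=0.5, pi_HE=0.5, mu_LE=-50.0, mu_HE=50.0,
                     sigma_LE=0.5, sigma_HE=0.5, loglik=0.0, n_points=100)
    b = class_boundaries(fit, fdr=0.05)
    assert b.t_LE <= b.t_HE
    assert -50 < b.t_LE and b.t_HE < 50


def test_posterior_boundaries_alternative_rule():
    fit = MixtureFit(**WELLSEP)
    b = posterior_boundaries(fit, fdr=0.05)
    assert b.t_LE <= b.t_HE
    assert fit.mu_LE < b.t_HE < fit.mu_HE


def test_boundaries_reject_bad_fdr():
    with pytest.raises(ValueError):
        class_boundaries(MixtureFit(**WELLSEP), fdr=0.0)
    with pytest.raises(ValueError):
        ClassBoundaries(t_LE=2.0, t_HE=1.0)


# -------------------------------------------------------------- classification

def test_classify_rules():
    fpkm = pd.DataFrame({"s1": [0.0, 2.0 ** -5, 2.0 ** 7, 2.0 ** 1]},
                        index=["gNE", "gLE", "gHE", "gINT"])
    counts = pd.DataFrame({"s1": [0, 3, 500, 40]}, index=fpkm.index)
    bounds = {"s1": ClassBoundaries(t_LE=-1.0, t_HE=3.0)}
    out = classify_genes(fpkm, counts, bounds)
    assert list(out["s1"]) == ["NE", "LE", "HE", "INT"]


def test_classify_boundary_values_inclusive():
    fpkm = pd.DataFrame({"s1": [2.0 ** -1.0, 2.0 ** 3.0]}, index=["gL", "gH"])
    counts = pd.DataFrame({"s1": [5, 5]}, index=fpkm.index)
    out = classify_genes(fpkm, counts, {"s1": ClassBoundaries(t_LE=-1.0, t_HE=3.0)})
    assert list(out["s1"]) == ["LE", "HE"]


def test_classify_missing_boundaries_error():
    fpkm = pd.DataFrame({"s1": [1.0]}, index=["g"])
    with pytest.raises(ValueError, match="missing boundaries"):
        classify_genes(fpkm, fpkm.astype(int), {})


def test_classification_monotone_in_fpkm():
    # raising a gene's FPKM (with a nonzero count) never lowers its class
    order = {"NE": 0, "LE": 1, "INT": 2, "HE": 3}
    rng = np.random.default_rng(11)
    bounds = {"s1": ClassBoundaries(t_LE=-1.0, t_HE=3.0)}
    vals = np.sort(rng.uniform(2.0 ** -6, 2.0 ** 6, 200))
    fpkm = pd.DataFrame({"s1": vals}, index=[f"g{i}" for i in range(200)])
    counts = pd.DataFrame({"s1": np.ones(200, dtype=int)}, index=fpkm.index)
    labels = [order[c] for c in classify_genes(fpkm, counts, bounds)["s1"]]
    assert labels == sorted(labels)


def test_classify_replicates_he_fdr_on_planted_mixture():
    # plant a mixture as FPKM directly (no count noise): the fraction of
    # LE-component genes called HE must respect the boundary's FDR target
    rng = np.random.default_rng(13)
    n = 4000
    is_le = rng.random(n) < 0.5
    log2fpkm = np.where(is_le, rng.normal(-2, 1, n), rng.normal(6, 1, n))
    fit = fit_bimodal(log2fpkm, seed=0)
    b = class_boundaries(fit, fdr=0.05)
    he_calls = log2fpkm >= b.t_HE
    fdp = (he_calls & is_le).sum() / max(he_calls.sum(), 1)
    se = np.sqrt(0.05 * 0.95 / he_calls.sum())
    assert fdp <= 0.05 + 2 * se
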