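"""REML variance components, heritability categories, genotype PCs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from pansvherit.kinship import compute_grm, partition_variants
from pansvherit.synthpop import TraitSpec, simulate_traits
from pansvherit.varcomp import (assign_h2_category, build_covariates,
                                default_category_anchors, eigen_grm,
                                h2_partition_report, pca_covariates,
                                percent_increase, profile_reml_1grm, reml_fit)


def grid_profile_oracle(y, X, K, n_grid=20001):
    """Eigen-rotation profile-likelihood grid search over h2 (independent of
    the AI-REML implementation)."""
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0)
    yr, Xr = U.T @ y, U.T @ X
    n, p = X.shape
    best, best_ll = 0.0, -np.inf
    for h2 in np.linspace(0, 1 - 1e-6, n_grid):
        d = h2 * lam + (1 - h2)
        w = 1.0 / d
        XtWX = Xr.T @ (Xr * w[:, None])
        beta = np.linalg.solve(XtWX, Xr.T @ (yr * w))
        r = yr - Xr @ beta
        rss = float(r @ (r * w))
        s2 = rss / (n - p)
        ll = -0.5 * (np.sum(np.log(d)) + np.linalg.slogdet(XtWX)[1]
                     + (n - p) * np.log(s2) + (n - p))
        if ll > best_ll:
            best, best_ll = h2, ll
    return best


def he_regression(y, X, K):
    """Haseman–Elston regression oracle: off-diagonal cross-products of the
    covariate-residualized phenotype regressed on the equally-projected
    kinship entries (E[r r'] = h2 M K M + s2e M with M = I - QQ')."""
    Q, _ = np.linalg.qr(X)
    r = y - Q @ (Q.T @ y)
    r = r / r.std(ddof=0)
    MK = K - Q @ (Q.T @ K)
    MKM = MK - (MK @ Q) @ Q.T
    n = y.size
    iu = np.triu_indices(n, k=1)
    cp = np.outer(r, r)[iu]
    k = MKM[iu]
    slope = np.sum((k - k.mean()) * (cp - cp.mean())) / np.sum((k - k.mean()) ** 2)
    return slope


@pytest.fixture(scope="module")
def pop_fit_inputs(default_pop):
    cat, g, _, het = default_pop
    X = build_covariates(g, cat, k=4)
    parts = partition_variants(cat, kind="by_class")
    Ks = {c: compute_grm(g, parts[c], label=c) for c in ("SNP", "INDEL", "SV")}
    return cat, g, het, X, Ks


def test_single_grm_reml_matches_grid_oracle(pop_fit_inputs, rng):
    cat, g, het, X, Ks = pop_fit_inputs
    specs = [TraitSpec("t", h2_by_class={"SNP": 0.4, "INDEL": 0.0, "SV": 0.0})]
    tt, _ = simulate_traits(g, cat, specs, het, seed=31)
    y = tt.values["t"].to_numpy()
    fit = reml_fit(y, X, [Ks["SNP"]], labels=["SNP"])
    oracle = grid_profile_oracle(y, X, Ks["SNP"].matrix)
    assert fit.h2["SNP"] == pytest.approx(oracle, abs=1e-4)
    # the fast eigen-rotation path agrees too
    h2_fast, _, _, _, _ = profile_reml_1grm(y, X, eigen_grm(Ks["SNP"]))
    assert h2_fast == pytest.approx(oracle, abs=1e-4)


def test_null_trait_h2_near_zero(pop_fit_inputs, rng):
    cat, g, het, X, Ks = pop_fit_inputs
    ests = []
    for i in range(20):
        y = rng.standard_normal(g.n_accessions)
        fit = reml_fit(y, X, [Ks["SNP"]], labels=["SNP"])
        ests.append(fit.h2["SNP"])
    mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
    # constrained estimates pile up at zero, so the mean sits just above it
    assert np.mean(ests) < max(0.05, 3 * mc_se)


def test_constrained_fit_never_negative_and_matches_unconstrained(pop_fit_inputs):
    cat, g, het, X, Ks = pop_fit_inputs
    specs = [TraitSpec("t", h2_by_class={"SNP": 0.15, "INDEL": 0.0, "SV": 0.35},
                       n_causal_by_class={"SNP": 100, "INDEL": 0, "SV": 30})]
    tt, _ = simulate_traits(g, cat, specs, het, seed=41)
    y = tt.values["t"].to_numpy()
    K_list = [Ks["SNP"], Ks["SV"]]
    fit_c = reml_fit(y, X, K_list, labels=["SNP", "SV"], constrain=True)
    assert all(v >= 0 for v in fit_c.h2.values())
    fit_u = reml_fit(y, X, K_list, labels=["SNP", "SV"], constrain=False)
    if all(v > 0.01 for v in fit_u.h2.values()):
        for lab in ("SNP", "SV"):
            assert fit_c.h2[lab] == pytest.approx(fit_u.h2[lab], abs=1e-3)


def test_three_component_recovery_single_replicate(pop_fit_inputs):
    cat, g, het, X, Ks = pop_fit_inputs
    specs = [TraitSpec("t", h2_by_class={"SNP": 0.10, "INDEL": 0.04, "SV": 0.27})]
    tt, truth = simulate_traits(g, cat, specs, het, seed=51)
    fit = reml_fit(tt.values["t"].to_numpy(), X,
                   [Ks["SNP"], Ks["INDEL"], Ks["SV"]], labels=["SNP", "INDEL", "SV"])
    # single replicate: just demand the right ballpark and ordering of SV share
    assert fit.total_h2 == pytest.approx(0.41, abs=0.2)
    assert fit.h2["SV"] > fit.h2["INDEL"]


def test_haseman_elston_consistent_with_reml(pop_fit_inputs):
    cat, g, het, X, Ks = pop_fit_inputs
    reml_est, he_est = [], []
    for rep in range(15):
        specs = [TraitSpec("t", h2_by_class={"SNP": 0.4, "INDEL": 0.0, "SV": 0.0})]
        tt, _ = simulate_traits(g, cat, specs, het, seed=100 + rep)
        y = tt.values["t"].to_numpy()
        fit = reml_fit(y, X, [Ks["SNP"]], labels=["SNP"])
        reml_est.append(fit.h2["SNP"])
        he_est.append(he_regression(y, X, Ks["SNP"].matrix))
    diff = np.array(reml_est) - np.array(he_est)
    se = np.std(diff, ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean()) < 3 * max(se, 0.01)


def test_blups_and_se_reported(pop_fit_inputs):
    cat, g, het, X, Ks = pop_fit_inputs
    specs = [TraitSpec("t", h2_by_class={"SNP": 0.3, "INDEL": 0.0, "SV": 0.2},
                       n_causal_by_class={"SNP": 100, "INDEL": 0, "SV": 30})]
    tt, _ = simulate_traits(g, cat, specs, het, seed=61)
    fit = reml_fit(tt.values["t"].to_numpy(), X, [Ks["SNP"], Ks["SV"]],
                   labels=["SNP", "SV"])
    assert set(fit.blups) >= {"SNP", "SV"}
    assert fit.blups["SNP"].shape == (g.n_accessions,)
    for lab in fit.labels:
        if fit.h2[lab] > 0.05:
            assert np.isfinite(fit.se_h2[lab]) and fit.se_h2[lab] > 0


def test_reml_input_validation(pop_fit_inputs):
    cat, g, het, X, Ks = pop_fit_inputs
    y = np.zeros(g.n_accessions)
    y[0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        reml_fit(y, X, [Ks["SNP"]])
    with pytest.raises(ValueError, match="too few"):
        reml_fit(np.zeros(4), np.ones((4, 1)), [np.eye(4)] * 3)


# ---------------------------------------------------------------------------
# report arithmetic and categories
# ---------------------------------------------------------------------------

def test_percent_increase_worked_example():
    assert percent_increase(0.41, 0.33) == 24


def test_partition_report_identical_models():
    rep = h2_partition_report({"a": [0.3, 0.4, 0.5], "b": [0.3, 0.4, 0.5]})
    assert rep["wilcoxon_p"][("a", "b")] == 1.0
    assert rep["percent_increase"][("a", "b")] == 0


def test_category_vertices_and_centroid():
    assert assign_h2_category((1, 0, 0)) == "SNP"
    assert assign_h2_category((0, 0, 0.7)) == "SV"
    assert assign_h2_category((1 / 3, 1 / 3, 1 / 3)) == "ALL"
    assert assign_h2_category((0, 0, 0)) == "unclassifiable"


def test_category_matches_brute_force_scan(rng):
    anchors = default_category_anchors()
    A = anchors.to_numpy()
    for _ in range(200):
        v = rng.dirichlet(np.ones(3))
        label = assign_h2_category(v)
        d = np.linalg.norm(A - v, axis=1)
        assert label == anchors.index[int(np.argmin(d))]


# ---------------------------------------------------------------------------
# genotype PCs
# ---------------------------------------------------------------------------

def test_pcs_orthogonal_and_deterministic_sign(default_pop):
    cat, g, _, _ = default_pop
    pcs = pca_covariates(g, cat, k=4)
    G = pcs.T @ pcs
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()
    pcs2 = pca_covariates(g, cat, k=4)
    np.testing.assert_allclose(pcs, pcs2)


def test_pcs_validate_k(default_pop):
    cat, g, _, _ = default_pop
    assert pca_covariates(g, cat, k=0).shape == (g.n_accessions, 0)
    with pytest.raises(ValueError):
        pca_covariates(g, cat, k=g.n_accessions)
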