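"""Multi-component restricted maximum likelihood (REML) and BLUP.

Fits y ~ N(X beta, sum_k sigma2_k K_k + sigma2_e I) by average-information
(AI) REML with EM fallback steps, the standard composite ("multiple kinship
matrices") model for partitioning heritability by variant category.  With
``constrain=True`` components hitting the zero boundary are clamped and the
model is refit without them, so no negative heritability is reported.

Also provides a fast eigen-rotation profile likelihood for the single-GRM
case (used by the association scan and genomic prediction), the simplex
nearest-anchor heritability-category assignment, and genotype-PC covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix
from .kinship import GRM


@dataclass
class VarCompFit:
    """Result of a (multi-)component REML fit.

    ``sigma2`` includes the residual as its last entry (label ``residual``);
    ``h2`` are variance shares sigma2_k / sum(sigma2) for the genetic
    components.  Standard errors come from the inverse average-information
    matrix (sigma2 scale) and the delta method (h2 scale).
    """

    labels: list
    sigma2: np.ndarray
    se_sigma2: np.ndarray
    h2: dict
    se_h2: dict
    total_h2: float
    loglik: float
    n_iter: int
    converged: bool
    beta: np.ndarray
    blups: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)


def _as_matrix(K) -> np.ndarray:
    return K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)


def _reml_core(y, X, Ks, tol, max_iter, theta0=None):
    """AI-REML with EM fallback; Ks excludes the identity (appended here)."""
    n = y.size
    mats = [np.asarray(K) for K in Ks] + [np.eye(n)]
    k = len(mats)
    vy = float(np.var(y, ddof=1))
    theta = np.full(k, vy / k) if theta0 is None else np.array(theta0, dtype=float)
    floor = 1e-8 * vy

    def loglik_parts(th):
        V = sum(t * M for t, M in zip(th, mats))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        sgn, logdetX = np.linalg.slogdet(XtViX)
        if sgn <= 0:
            return None
        ViX = Vi @ X
        P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        Py = P @ y
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return ll, P, Py, Vi, XtViX

    parts = loglik_parts(theta)
    if parts is None:
        raise ValueError("initial variance matrix not positive definite")
    ll = parts[0]
    it, converged = 0, False
    for it in range(1, max_iter + 1):
        _, P, Py, _, _ = parts
        KPy = [M @ Py for M in mats]
        score = np.array([-0.5 * (np.sum(P * M) - Py @ KPy[i])
                          for i, M in enumerate(mats)])
        AI = np.empty((k, k))
        PKPy = [P @ v for v in KPy]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(KPy[i] @ PKPy[j])
        # AI step with step-halving; EM fallback on failure
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = None
        new_parts, new_theta = None, None
        if delta is not None:
            stepsize = 1.0
            for _ in range(6):
                cand = np.maximum(theta + stepsize * delta, floor)
                cp = loglik_parts(cand)
                if cp is not None and cp[0] >= ll - 1e-10:
                    new_parts, new_theta = cp, cand
                    break
                stepsize *= 0.5
        if new_parts is None:
            # EM update: theta_i <- theta_i + theta_i^2/n (y'P K P y - tr(P K))
            cand = np.array([max(t + (t * t / n) * float(Py @ KPy[i] - np.sum(P * mats[i])),
                                 floor)
                             for i, t in enumerate(theta)])
            cp = loglik_parts(cand)
            if cp is None:
                break
            new_parts, new_theta = cp, cand
        dll = new_parts[0] - ll
        dtheta = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), floor))
        theta, parts, ll = new_theta, new_parts, new_parts[0]
        if abs(dll) < tol and dtheta < np.sqrt(tol):
            converged = True
            break
    # final AI matrix for standard errors
    _, P, Py, Vi, XtViX = parts
    KPy = [M @ Py for M in mats]
    PKPy = [P @ v for v in KPy]
    AI = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(KPy[i] @ PKPy[j])
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    return theta, se, cov, ll, it, converged, beta, Vi


def reml_fit(y, X, K_list, labels=None, constrain: bool = True,
             tol: float = 1e-6, max_iter: int = 200) -> VarCompFit:
    """Fit the composite variance-component model.

    Parameters
    ----------
    y : (n,) complete trait vector.
    X : (n, p) fixed-effect design (include the intercept; typically also
        the first 4 genotype PCs).
    K_list : list of GRMs (``GRM`` objects or arrays).
    constrain : clamp negative components to zero and refit without them.

    BLUPs are sigma2_k K_k V^-1 (y - X beta) per retained component.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains missing values")
    if labels is None:
        labels = [K.label or f"K{i+1}" if isinstance(K, GRM) else f"K{i+1}"
                  for i, K in enumerate(K_list)]
    mats = [_as_matrix(K) for K in K_list]
    for lab, M in zip(labels, mats):
        if not np.allclose(M, M.T, atol=1e-8):
            raise ValueError(f"kinship {lab} is not symmetric")
    if n < len(mats) + p + 1:
        raise ValueError("too few observations for the number of components and covariates")

    active = list(range(len(mats)))
    dropped = []
    while True:
        theta, se, cov, ll, it, conv, beta, Vi = _reml_core(
            y, X, [mats[i] for i in active], tol, max_iter)
        vy = float(np.var(y, ddof=1))
        boundary = [i for i, t in enumerate(theta[:-1]) if t <= 1e-6 * vy]
        if constrain and boundary and len(active) > 0:
            worst = boundary[int(np.argmin(theta[boundary]))]
            dropped.append(active.pop(worst))
            if active:
                continue
            # all genetic components at zero: residual-only model
            theta = np.array([float(np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0],
                                           ddof=X.shape[1]))])
            se = np.array([theta[0] * np.sqrt(2.0 / (n - p))])
            ll, it, conv = np.nan, 0, True
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            Vi = np.eye(n) / theta[0]
        break

    full = np.zeros(len(mats) + 1)
    full_se = np.zeros(len(mats) + 1)
    for slot, i in enumerate(active):
        full[i], full_se[i] = theta[slot], se[slot]
    full[-1], full_se[-1] = theta[-1], se[-1]
    total = float(full.sum())
    h2 = {lab: float(full[i] / total) for i, lab in enumerate(labels)}
    # delta-method SEs for shares (from the reduced-model AI covariance)
    se_h2 = {}
    kact = len(active)
    if kact and np.all(np.isfinite(cov)):
        S = float(theta.sum())
        grad = np.zeros((kact, kact + 1))
        for a in range(kact):
            grad[a] = -theta[a] / S ** 2
            grad[a, a] += 1.0 / S
        var_h = grad @ cov @ grad.T
        for a, i in enumerate(active):
            se_h2[labels[i]] = float(np.sqrt(max(var_h[a, a], 0.0)))
    for i, lab in enumerate(labels):
        se_h2.setdefault(lab, 0.0 if i in dropped else np.nan)

    resid = y - X @ beta
    blups = {}
    for slot, i in enumerate(active):
        blups[labels[i]] = full[i] * (mats[i] @ (Vi @ resid))
    for i in dropped:
        blups[labels[i]] = np.zeros(n)
    return VarCompFit(list(labels), full, full_se, h2, se_h2,
                      float(sum(h2.values())), float(ll), it, bool(conv), beta,
                      blups, [labels[i] for i in dropped])


# ---------------------------------------------------------------------------
# fast single-GRM profile REML (eigen rotation)
# ---------------------------------------------------------------------------

def eigen_grm(K) -> tuple:
    """Eigendecomposition of a GRM for repeated single-component fits."""
    vals, vecs = np.linalg.eigh(_as_matrix(K))
    return np.maximum(vals, 0.0), vecs


def profile_reml_1grm(y, X, eig, h2_grid: int = 64):
    """Single-GRM REML via eigen rotation.

    ``eig`` is ``(eigenvalues, eigenvectors)`` from :func:`eigen_grm`.
    Profiles out beta and the total variance; optimizes the restricted
    likelihood over h2 = sigma2_g / (sigma2_g + sigma2_e) on [0, 1).
    Returns (h2, sigma2_g, sigma2_e, beta, loglik).
    """
    lam, U = eig
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    yr, Xr = U.T @ y, U.T @ X

    def negll(h2):
        d = h2 * lam + (1.0 - h2)
        w = 1.0 / d
        XtWX = Xr.T @ (Xr * w[:, None])
        XtWy = Xr.T @ (yr * w)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        r = yr - Xr @ beta
        rss = float(r @ (r * w))
        s2 = rss / (n - p)
        sgn, logdetX = np.linalg.slogdet(XtWX)
        ll = -0.5 * (np.sum(np.log(d)) + logdetX + (n - p) * np.log(s2) + (n - p))
        return -ll, beta, s2

    res = optimize.minimize_scalar(lambda h: negll(h)[0], bounds=(0.0, 1.0 - 1e-6),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    h2 = float(res.x)
    nll, beta, s2 = negll(h2)
    return h2, h2 * s2, (1.0 - h2) * s2, beta, -nll


# ---------------------------------------------------------------------------
# reporting and categories
# ---------------------------------------------------------------------------

def percent_increase(m1: float, m2: float) -> int:
    """Percent increase of mean m1 over mean m2, rounded to integer."""
    return int(round(100.0 * (m1 / m2 - 1.0)))


def h2_partition_report(fits_by_model: dict) -> dict:
    """Summarize total h2 across traits for several models.

    ``fits_by_model`` maps model label -> list of VarCompFit (or floats).
    Returns a dict with a summary DataFrame (mean/median h2 per model),
    pairwise two-sided Wilcoxon rank-sum p-values, and pairwise percent
    increases of model means.
    """
    totals = {}
    for label, fits in fits_by_model.items():
        totals[label] = np.array([f.total_h2 if isinstance(f, VarCompFit) else float(f)
                                  for f in fits])
    summary = pd.DataFrame({
        "mean_h2": {k: v.mean() for k, v in totals.items()},
        "median_h2": {k: np.median(v) for k, v in totals.items()},
        "n_traits": {k: len(v) for k, v in totals.items()},
    })
    labels = list(totals)
    pvals, pct = {}, {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if np.array_equal(totals[a], totals[b]):
                pvals[(a, b)] = 1.0
            else:
                pvals[(a, b)] = float(stats.ranksums(totals[a], totals[b]).pvalue)
            pct[(a, b)] = percent_increase(float(totals[a].mean()), float(totals[b].mean()))
    return {"summary": summary, "wilcoxon_p": pvals, "percent_increase": pct}


def default_category_anchors() -> pd.DataFrame:
    """Seven anchors on the (SNP, INDEL, SV) proportion simplex: three
    vertices, three edge midpoints and the centroid."""
    coords = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
              (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5),
              (1 / 3, 1 / 3, 1 / 3)]
    labels = ["SNP", "INDEL", "SV", "SNP+INDEL", "SNP+SV", "INDEL+SV", "ALL"]
    return pd.DataFrame(coords, index=labels, columns=["SNP", "INDEL", "SV"])


def assign_h2_category(shares, anchors: pd.DataFrame | None = None) -> str:
    """Nearest-anchor category for a (SNP, INDEL, SV) heritability share.

    Shares are normalized to the simplex; traits with zero total h2 are
    ``"unclassifiable"``.  Ties break by anchor order.
    """
    if anchors is None:
        anchors = default_category_anchors()
    v = np.asarray(shares, dtype=float)
    tot = v.sum()
    if tot <= 0:
        return "unclassifiable"
    v = v / tot
    d = np.linalg.norm(anchors.to_numpy() - v, axis=1)
    return str(anchors.index[int(np.argmin(d))])


# ---------------------------------------------------------------------------
# genotype PCs
# ---------------------------------------------------------------------------

def pca_covariates(g: GenotypeMatrix, catalog: pd.DataFrame | None = None,
                   k: int = 4, classes=("SNP", "INDEL")) -> np.ndarray:
    """Top-k principal component scores of the centered, standardized
    SNP+indel dosage matrix, with a deterministic sign convention (the
    largest-magnitude loading of each PC is positive).  ``k=0`` returns an
    (n, 0) array (intercept-only covariates)."""
    n = g.n_accessions
    if k >= n:
        raise ValueError(f"k={k} must be < n accessions ({n})")
    if k == 0:
        return np.empty((n, 0))
    if catalog is not None:
        ids = catalog.loc[catalog["var_class"].isin(classes), "variant_id"].to_list()
        X = g.columns(ids)
    else:
        X = g.dosages
    X = np.where(np.isfinite(X), X, np.nan)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isfinite(X), X, mu[None, :])
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    PC = U[:, :k] * s[:k]
    for j in range(PC.shape[1]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            PC[:, j] *= -1.0
    return PC


def build_covariates(g: GenotypeMatrix, catalog=None, k: int = 4) -> np.ndarray:
    """Intercept + top-k genotype PCs, the default fixed-effect design."""
    pcs = pca_covariates(g, catalog, k=k)
    return np.column_stack([np.ones(g.n_accessions), pcs])
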