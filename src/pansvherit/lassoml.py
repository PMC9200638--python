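"""Multilocus LASSO mapping with first-entry significance.

The evidence statistic for each variant is the penalty lambda at which it
first enters the active set along the LARS path (for the first entrant this
is lambda_max = max_j |x_j' y| / n on standardized predictors).  Significance
is assessed against a permutation null built per *rank*: permuting the
response and recording the sorted first-entry penalties gives the null
distribution of each order statistic, and the variant of observed rank r is
compared with the rank-r null.  This makes the p-values approximately
uniform per rank, so the 1/m significance threshold yields about one
expected null discovery per scan, and the permutation false-discovery rate
at the threshold is estimated as (mean permuted discovery count)/(observed
discovery count).

Workflows: per-gene cis-SV scans flagging allelic heterogeneity (>= 2
significant SVs in the +/-50 kb window) and the co-expression-module-guided
trait scan that resolves locus heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lars_path

from .genio import GeneModel, GenotypeMatrix, TraitTable


@dataclass
class LassoResult:
    """Per-variant first-entry penalties and permutation significance."""

    table: pd.DataFrame          # variant_id, lambda_entry, rank, p, selected
    threshold: float             # significance threshold on p (default 1/m)
    fdr: float                   # permutation FDR at the threshold (NaN if 0 hits)
    n_perm: int
    seed: int
    allelic_het: bool = False    # >= 2 selected variants

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def _standardize_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xs = X - X.mean(axis=0)
    sd = Xs.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return Xs / sd, y - y.mean()


def lasso_entry_stats(X, y) -> np.ndarray:
    """First-entry penalty lambda_entry per column of X.

    Columns are standardized and y centered internally; the LARS path is
    computed and lambda_entry(j) is the penalty at which j first joins the
    active set (variants never entering get 0).  Exact duplicate columns
    inherit their twin's entry penalty (LARS can only admit one of them);
    simultaneous entries tie-break by lower column index.
    """
    Xs, yc = _standardize_xy(X, y)
    n, m = Xs.shape
    if m == 0:
        raise ValueError("no predictors")
    lam = np.zeros(m)
    # collapse exact duplicate columns before LARS (it can admit only one),
    # then propagate each representative's entry penalty to its twins
    _, first_idx, inverse = np.unique(np.round(Xs, 12), axis=1,
                                      return_index=True, return_inverse=True)
    rep = np.sort(first_idx)
    Xu = Xs[:, rep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, active, _ = lars_path(Xu, yc, method="lar", verbose=False)
    for step, col in enumerate(active):
        lam[rep[col]] = alphas[step]
    for j in range(m):
        lam[j] = lam[int(first_idx[inverse[j]])]
    return lam


def lasso_path_coefs(X, y, lambdas) -> np.ndarray:
    """Lasso coefficients at the requested penalties via the LARS path.

    The lasso solution path is piecewise linear in lambda, so coefficients
    at arbitrary penalties are obtained exactly by linear interpolation
    between path knots.  X is standardized and y centered internally;
    returns an array of shape (len(lambdas), m).
    """
    Xs, yc = _standardize_xy(X, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, _, coefs = lars_path(Xs, yc, method="lasso", verbose=False)
    lambdas = np.asarray(lambdas, dtype=float)
    out = np.empty((lambdas.size, Xs.shape[1]))
    # alphas decrease along the path; np.interp needs increasing x
    for j in range(Xs.shape[1]):
        out[:, j] = np.interp(lambdas, alphas[::-1], coefs[j, ::-1],
                              left=coefs[j, -1], right=0.0)
    return out


def _rank_null(X, y, n_perm, rng, null_lambdas=None):
    """Matrix (n_perm, m) of descending-sorted entry penalties under
    permutation of y (or a supplied precomputed null)."""
    if null_lambdas is not None:
        return np.asarray(null_lambdas, dtype=float)
    m = X.shape[1]
    out = np.empty((n_perm, m))
    for b in range(n_perm):
        yp = y[rng.permutation(y.size)]
        out[b] = np.sort(lasso_entry_stats(X, yp))[::-1]
    return out


def lasso_pvalues(X, y, n_perm: int = 1000, seed: int = 0,
                  threshold: float | None = None, variant_ids=None,
                  null_lambdas=None) -> LassoResult:
    """Permutation p-values for the first-entry penalties of X against y.

    p(j) = (1 + #{permutations with rank-r null >= observed lambda_j}) /
    (n_perm + 1), where r is j's observed rank.  ``threshold`` defaults to
    1/m; the FDR at the threshold is the mean permuted discovery count over
    the observed discovery count (NaN when nothing is selected).  A
    precomputed ``null_lambdas`` matrix (n_perm x m, rows sorted descending)
    may be supplied to share one null across many scans.
    """
    if null_lambdas is None and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    rng = np.random.default_rng(seed)
    obs = lasso_entry_stats(X, y)
    order = np.argsort(-obs, kind="mergesort")  # rank 0 = largest entry penalty
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(m)
    null = _rank_null(X, y, n_perm, rng, null_lambdas)
    n_perm_eff = null.shape[0]
    lam_sorted = obs[order]
    p_rank = np.array([(1.0 + np.sum(null[:, r] >= lam_sorted[r])) / (n_perm_eff + 1.0)
                       for r in range(m)])
    # isotonize: reassign the sorted p multiset in evidence order, so p is
    # monotone in lambda_entry while discovery counts (and hence the 1/m
    # calibration) are untouched
    p = np.empty(m)
    p[order] = np.sort(p_rank)
    thr = (1.0 / m) if threshold is None else float(threshold)
    selected = p < thr
    # permutation discovery counts at the same threshold
    null_disc = np.zeros(n_perm_eff)
    sorted_null = np.sort(null, axis=0)
    for r in range(m):
        col = null[:, r]
        pb = (1.0 + (n_perm_eff - np.searchsorted(sorted_null[:, r], col, side="left"))) \
            / (n_perm_eff + 1.0)
        null_disc += (pb < thr)
    d_obs = int(selected.sum())
    fdr = float(null_disc.mean() / d_obs) if d_obs > 0 else np.nan
    ids = list(variant_ids) if variant_ids is not None else [f"x{j}" for j in range(m)]
    table = pd.DataFrame({"variant_id": ids, "lambda_entry": obs, "rank": ranks,
                          "p": p, "selected": selected})
    return LassoResult(table, thr, fdr, n_perm_eff, seed,
                       allelic_het=bool(d_obs >= 2))


def cis_sv_scan(gene: GeneModel, g: GenotypeMatrix, catalog: pd.DataFrame,
                response, window: int = 50_000, n_perm: int = 200,
                seed: int = 0, maf_min: float = 0.0) -> LassoResult:
    """LASSO scan of the SVs in a gene's +/-``window`` against a response.

    ``response`` is the preprocessed expression vector or (preferably) the
    summed component BLUPs from a composite REML fit of that expression
    trait.  The gene is flagged for allelic heterogeneity when >= 2 SVs are
    significant at the 1/m threshold.  With no cis-SVs an empty, flagged-off
    result is returned.
    """
    sub = catalog[(catalog["var_class"] == "SV") & (catalog["chrom"] == gene.chrom) &
                  (catalog["pos"] >= gene.start - window) &
                  (catalog["pos"] <= gene.end + window) &
                  (catalog["maf"] >= maf_min)]
    ids = sub["variant_id"].to_list()
    if not ids:
        empty = pd.DataFrame(columns=["variant_id", "lambda_entry", "rank", "p", "selected"])
        return LassoResult(empty, np.nan, np.nan, 0, seed, allelic_het=False)
    X = g.columns(ids)
    return lasso_pvalues(X, np.asarray(response, dtype=float), n_perm=n_perm,
                         seed=seed, variant_ids=ids)


def module_guided_trait_scan(y, module_genes, g: GenotypeMatrix,
                             catalog: pd.DataFrame, expr: TraitTable,
                             responses: dict | None = None, window: int = 50_000,
                             n_perm: int = 200, seed: int = 0) -> pd.DataFrame:
    """Two-stage module-guided search for locus heterogeneity.

    Stage 1: per module gene, a cis-SV LASSO scan against its expression
    (or a supplied BLUP response in ``responses``); genes with at least one
    significant cis-SV eQTL are retained.  Stage 2: the retained genes'
    cis-SVs are pooled and scanned jointly against the trait ``y``.
    Significant SVs are reported with their host gene, entry penalty, p,
    and a two-sided Wilcoxon rank-sum contrast of the trait between SV
    genotype groups (dosage 0 vs 2).

    Returns a DataFrame (sv, gene, lambda_entry, p, wilcoxon_p,
    median_ref, median_alt); empty if stage 1 retains nothing.
    """
    y = np.asarray(y, dtype=float).ravel()
    stage1 = {}
    for k, gene in enumerate(module_genes):
        resp = (responses or {}).get(gene.gene_id)
        if resp is None:
            resp = expr.values[gene.gene_id].to_numpy()
        res = cis_sv_scan(gene, g, catalog, resp, window=window, n_perm=n_perm,
                          seed=seed + 1000 + k)
        hits = res.table.loc[res.table["selected"], "variant_id"].to_list()
        if hits:
            stage1[gene.gene_id] = res
    cols = ["sv", "gene", "lambda_entry", "p", "wilcoxon_p", "median_ref", "median_alt"]
    if not stage1:
        return pd.DataFrame(columns=cols)
    # pool all cis-SVs of stage-1 genes (the "cis-SV set")
    pool, host = [], {}
    gene_by_id = {gm.gene_id: gm for gm in module_genes}
    for gid in stage1:
        gm = gene_by_id[gid]
        sub = catalog[(catalog["var_class"] == "SV") & (catalog["chrom"] == gm.chrom) &
                      (catalog["pos"] >= gm.start - window) &
                      (catalog["pos"] <= gm.end + window)]
        for v in sub["variant_id"]:
            if v not in host:
                pool.append(v)
                host[v] = gid
    res2 = lasso_pvalues(g.columns(pool), y, n_perm=max(n_perm, 100), seed=seed,
                         variant_ids=pool)
    rows = []
    for _, r in res2.table[res2.table["selected"]].iterrows():
        x = g.col(r["variant_id"])
        ref, alt = y[x <= 0.5], y[x >= 1.5]
        if ref.size and alt.size:
            wp = float(stats.ranksums(ref, alt).pvalue)
        else:
            wp = np.nan
        rows.append((r["variant_id"], host[r["variant_id"]], r["lambda_entry"], r["p"],
                     wp, float(np.median(ref)) if ref.size else np.nan,
                     float(np.median(alt)) if alt.size else np.nan))
    return pd.DataFrame(rows, columns=cols)
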