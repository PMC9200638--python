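"""Genomic selection by GBLUP with cross-validation, marker-set comparison
and SV-based marker-assisted selection (MAS).

GBLUP is solved in the kinship parameterization: on the training fold the
variance ratio of y = mu + g + e, g ~ N(0, sigma2_g K) is estimated by
REML (eigen-rotation profile likelihood), and held-out breeding values are
predicted through the kinship cross-block,
g_test = K[test, train] (sigma2_g^-1 sigma2_e I + K[train, train])^-1 (y_train - mu).
Accuracy is the squared Pearson correlation between observed phenotypes and
genome-estimated breeding values, pooled per replicate of a five-fold
cross-validation (five repetitions by default) and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .kinship import GRM, compute_grm
from .varcomp import eigen_grm, profile_reml_1grm


@dataclass
class GSReport:
    """Cross-validated genomic-selection accuracy for one marker set."""

    label: str
    accuracy: float              # mean over repetitions of pooled r^2
    per_rep: np.ndarray
    folds: int
    reps: int
    seed: int


def _fold_assignments(n, folds, reps, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        idx = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        for f in range(folds):
            assign[idx[f::folds]] = f
        out.append(assign)
    return out


def gblup_cv(y, K, folds: int = 5, reps: int = 5, seed: int = 0,
             label: str = "") -> GSReport:
    """Five-fold (x five repetitions) cross-validated GBLUP accuracy."""
    y = np.asarray(y, dtype=float).ravel()
    Km = K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)
    n = y.size
    if n // folds < 5:
        raise ValueError("each fold needs at least 5 accessions")
    per_rep = np.empty(reps)
    for rep, assign in enumerate(_fold_assignments(n, folds, reps, seed)):
        pred = np.empty(n)
        for f in range(folds):
            te = assign == f
            tr = ~te
            Ktr = Km[np.ix_(tr, tr)]
            ytr = y[tr]
            eig = eigen_grm(Ktr)
            X = np.ones((tr.sum(), 1))
            h2, s2g, s2e, beta, _ = profile_reml_1grm(ytr, X, eig)
            mu = float(beta[0])
            if s2g <= 1e-12 * (s2g + s2e):
                pred[te] = mu
                continue
            lam_ridge = s2e / s2g
            sol = np.linalg.solve(Ktr + lam_ridge * np.eye(Ktr.shape[0]), ytr - mu)
            pred[te] = mu + Km[np.ix_(te, tr)] @ sol
        if np.std(pred) == 0 or np.std(y) == 0:
            per_rep[rep] = 0.0
        else:
            per_rep[rep] = float(np.corrcoef(pred, y)[0, 1] ** 2)
    return GSReport(label, float(per_rep.mean()), per_rep, folds, reps, seed)


def gblup_cv_many(Y: pd.DataFrame, K, folds: int = 5, reps: int = 5,
                  seed: int = 0, label: str = "") -> pd.Series:
    """Accuracy for many traits sharing one kinship (fold eigendecompositions
    reused across traits); returns trait -> mean accuracy."""
    Km = K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)
    n = Km.shape[0]
    assigns = _fold_assignments(n, folds, reps, seed)
    eigs = {}
    for rep, assign in enumerate(assigns):
        for f in range(folds):
            tr = assign != f
            eigs[(rep, f)] = eigen_grm(Km[np.ix_(tr, tr)])
    out = {}
    for trait in Y.columns:
        y = Y[trait].to_numpy(dtype=float)
        per_rep = np.empty(reps)
        for rep, assign in enumerate(assigns):
            pred = np.empty(n)
            for f in range(folds):
                te = assign == f
                tr = ~te
                ytr = y[tr]
                X = np.ones((int(tr.sum()), 1))
                h2, s2g, s2e, beta, _ = profile_reml_1grm(ytr, X, eigs[(rep, f)])
                mu = float(beta[0])
                if s2g <= 1e-12 * (s2g + s2e):
                    pred[te] = mu
                    continue
                sol = np.linalg.solve(Km[np.ix_(tr, tr)] + (s2e / s2g) * np.eye(int(tr.sum())),
                                      ytr - mu)
                pred[te] = mu + Km[np.ix_(te, tr)] @ sol
            per_rep[rep] = 0.0 if np.std(pred) == 0 else \
                float(np.corrcoef(pred, y)[0, 1] ** 2)
        out[trait] = float(per_rep.mean())
    return pd.Series(out, name=label)


def compare_marker_sets(Y: pd.DataFrame, marker_sets: dict, g: GenotypeMatrix,
                        alpha: float = -0.5, folds: int = 5, reps: int = 5,
                        seed: int = 0) -> dict:
    """Cross-validated accuracies per trait for several marker sets.

    ``marker_sets`` maps label -> variant id list; empty sets are skipped
    with a warning.  Returns a dict with the accuracy table (trait x set)
    and paired two-sided Wilcoxon signed-rank p-values between set pairs
    across traits (p = 1 for identical sets).
    """
    acc = {}
    for label, ids in marker_sets.items():
        if not list(ids):
            warnings.warn(f"marker set {label!r} is empty; skipped")
            continue
        K = compute_grm(g, list(ids), alpha=alpha, label=label)
        acc[label] = gblup_cv_many(Y, K, folds=folds, reps=reps, seed=seed, label=label)
    table = pd.DataFrame(acc)
    pvals = {}
    labels = list(table.columns)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = table[a] - table[b]
            if np.allclose(d, 0):
                pvals[(a, b)] = 1.0
            else:
                pvals[(a, b)] = float(stats.wilcoxon(table[a], table[b]).pvalue)
    return {"accuracy": table, "wilcoxon_p": pvals}


def mas_select(g: GenotypeMatrix, sv_favorable: dict, y, catalog=None) -> dict:
    """Marker-assisted selection on favorable SV alleles.

    ``sv_favorable`` maps SV id -> favorable homozygous dosage (0 or 2).
    Accessions are grouped by the count of favorable homozygous genotypes
    they carry; the report gives per-group n/mean/median, pairwise two-sided
    Wilcoxon rank-sum p-values, and whether the all-favorable group's median
    exceeds every single-marker group's median.
    """
    y = np.asarray(y, dtype=float).ravel()
    for sv in sv_favorable:
        if sv not in g._col_index:
            raise KeyError(f"SV {sv!r} absent from callset")
    n_sv = len(sv_favorable)
    count = np.zeros(g.n_accessions, dtype=int)
    for sv, fav in sv_favorable.items():
        count += (np.abs(g.col(sv) - float(fav)) < 0.5).astype(int)
    groups = {}
    for k in range(n_sv + 1):
        sel = count == k
        yk = y[sel]
        groups[k] = {"n": int(sel.sum()),
                     "mean": float(yk.mean()) if yk.size else np.nan,
                     "median": float(np.median(yk)) if yk.size else np.nan}
    pvals = {}
    ks = sorted(groups)
    for i, a in enumerate(ks):
        for b in ks[i + 1:]:
            ya, yb = y[count == a], y[count == b]
            pvals[(a, b)] = float(stats.ranksums(ya, yb).pvalue) \
                if ya.size and yb.size else np.nan
    full = groups[n_sv]["median"]
    singles = [groups[k]["median"] for k in range(1, n_sv)]
    best_flag = bool(np.isfinite(full) and
                     all(np.isfinite(s) and full > s for s in singles)) if singles else \
        bool(np.isfinite(full))
    return {"groups": groups, "wilcoxon_p": pvals, "both_favorable_best": best_flag,
            "counts": count}
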