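"""Signed weighted co-expression network construction and module detection.

Follows the weighted-correlation-network recipe: signed adjacency
a_ij = ((1 + cor_ij)/2)^beta, topological overlap similarity (TOM),
average-linkage hierarchical clustering on 1 - TOM with a static height
cut, a minimum module size, and iterative merging of modules whose
eigengenes (first principal component of the module's expression) are more
similar than a dissimilarity threshold.  Default parameters: soft power 9,
minimum module size 10, merge dissimilarity 0.15.  Genes in clusters below
the minimum size stay unassigned ("grey").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus module eigengenes and parameters."""

    labels: pd.Series                  # gene -> module label ("grey" = unassigned)
    eigengenes: pd.DataFrame           # accession x module, unit-normalized
    beta: float
    merge_height: float
    min_size: int

    @property
    def modules(self) -> list:
        return [m for m in self.eigengenes.columns]

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != "grey"].value_counts()


def signed_adjacency(expr: pd.DataFrame, beta: float = 9) -> pd.DataFrame:
    """Signed soft-threshold adjacency ((1 + cor)/2)^beta, diagonal 1.

    ``expr`` holds genes as columns.  Anticorrelated genes get adjacency
    near 0 (the signed convention).  Zero-variance genes are an error.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 accessions")
    sd = expr.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"zero-variance gene {bad!r}")
    C = np.corrcoef(expr.to_numpy(), rowvar=False)
    A = ((1.0 + C) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=expr.columns, columns=expr.columns)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix on a [0,1] symmetric adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    connectivity k = row sums minus the diagonal; diagonal set to 1.
    """
    A = adj.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    Ad = A.copy()
    np.fill_diagonal(Ad, 0.0)
    k = Ad.sum(axis=1)
    num = Ad @ Ad + Ad
    den = np.minimum.outer(k, k) + 1.0 - Ad
    T = num / den
    np.fill_diagonal(T, 1.0)
    T = np.clip(0.5 * (T + T.T), 0.0, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def _eigengene(expr_block: pd.DataFrame) -> np.ndarray:
    """First principal component of a module's expression (unit norm), sign
    aligned with the module's average expression profile."""
    Z = expr_block.to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0, ddof=0) == 0, 1.0,
                                        Z.std(axis=0, ddof=0))
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    e = U[:, 0]
    mean_profile = Z.mean(axis=1)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return e


def detect_modules(tom: pd.DataFrame, expr: pd.DataFrame, min_size: int = 10,
                   merge_height: float = 0.15, cut_quantile: float = 0.99,
                   beta: float = 9) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with static cut + eigengene merge.

    The tree is cut at the ``cut_quantile`` quantile of its merge heights;
    clusters smaller than ``min_size`` become "grey".  Modules whose
    eigengene dissimilarity 1 - cor falls below ``merge_height`` are merged
    iteratively until stable.  Labels are "M1", "M2", ... by decreasing size.
    """
    genes = list(tom.index)
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, cut_quantile))
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    small = sizes[sizes < min_size].index
    labels[labels.isin(small)] = -1  # grey

    def groups(lbl):
        return {k: list(v.index) for k, v in lbl.groupby(lbl) if k != -1}

    grp = groups(labels)
    if not grp:
        warnings.warn("all genes unassigned (grey)")
        return ModuleAssignment(pd.Series("grey", index=genes),
                                pd.DataFrame(index=expr.index), beta,
                                merge_height, min_size)
    # iterative eigengene merging
    while True:
        keys = sorted(grp)
        eg = {k: _eigengene(expr[grp[k]]) for k in keys}
        if len(keys) < 2:
            break
        best, best_d = None, merge_height
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = 1.0 - float(np.corrcoef(eg[a], eg[b])[0, 1])
                if d < best_d:
                    best, best_d = (a, b), d
        if best is None:
            break
        a, b = best
        grp[a] = grp[a] + grp.pop(b)
    ordered = sorted(grp, key=lambda k: (-len(grp[k]), k))
    final = pd.Series("grey", index=genes)
    eg_cols = {}
    for rank, k in enumerate(ordered, start=1):
        name = f"M{rank}"
        final[grp[k]] = name
        eg_cols[name] = _eigengene(expr[grp[k]])
    eigengenes = pd.DataFrame(eg_cols, index=expr.index)
    return ModuleAssignment(final, eigengenes, beta, merge_height, min_size)


def module_summary(assignment: ModuleAssignment | pd.Series,
                   n_expressed_genes: int) -> dict:
    """Module count, assigned genes, mean size (1 d.p.) and mean size as a
    percentage of expressed genes (2 d.p.)."""
    labels = assignment.labels if isinstance(assignment, ModuleAssignment) else assignment
    sizes = labels[labels != "grey"].value_counts()
    if sizes.empty:
        raise ValueError("empty assignment")
    mean_size = round(float(sizes.mean()), 1)
    return {
        "n_modules": int(sizes.size),
        "n_assigned_genes": int(sizes.sum()),
        "mean_module_size": mean_size,
        "mean_size_pct_of_expressed": round(100.0 * sizes.mean() / n_expressed_genes, 2),
        "sizes": sizes,
    }


def pick_soft_power(expr: pd.DataFrame, powers=range(1, 21), target_r2: float = 0.8,
                    n_bins: int = 10) -> tuple:
    """Choose the soft-thresholding power by approximate scale-free topology.

    For each candidate beta the signed fit index of the log10 p(k) ~ log10 k
    regression on binned connectivities is computed; the smallest beta
    reaching ``target_r2`` is chosen, else the argmax.  Returns
    (beta, DataFrame of per-power fits).
    """
    if expr.shape[1] < 50:
        raise ValueError("need at least 50 genes")
    C = np.corrcoef(expr.to_numpy(), rowvar=False)
    rows = []
    for beta in powers:
        A = ((1.0 + C) / 2.0) ** beta
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() == 0:
                continue
            kb = float(k[sel].mean())
            pb = float(sel.mean())
            if kb > 0 and pb > 0:
                xs.append(np.log10(kb))
                ys.append(np.log10(pb))
        if len(xs) < 3:
            rows.append((beta, 0.0, 0.0))
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        yhat = np.polyval([slope, intercept], xs)
        ss_res = float(np.sum((np.array(ys) - yhat) ** 2))
        ss_tot = float(np.sum((np.array(ys) - np.mean(ys)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        rows.append((beta, -np.sign(slope) * r2, slope))
    fits = pd.DataFrame(rows, columns=["beta", "signed_r2", "slope"])
    ok = fits[fits["signed_r2"] >= target_r2]
    beta = int(ok["beta"].iloc[0]) if not ok.empty else \
        int(fits.loc[fits["signed_r2"].idxmax(), "beta"])
    return beta, fits
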