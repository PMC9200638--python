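"""LD pruning, MAF-weighted genomic relationship matrices and LD profiling.

The GRM follows the MAF-weighted ("thin") parameterization: with dosage
x_j, allele frequency f_j and power parameter alpha,

    K = (1/c) * sum_j s_j (x_j - 2 f_j)(x_j - 2 f_j)^T,
    s_j = [2 f_j (1 - f_j)]^alpha,

which realizes E[h_j^2] proportional to [f_j(1-f_j)]^(1+alpha) under
standardized effects.  alpha = -1 recovers the fully column-standardized
GRM; the default alpha = -0.5 lets per-variant heritability taper with
decreasing MAF.  c normalizes the mean diagonal to 1 so variance components
are comparable across partitions, and is additive over disjoint partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix


@dataclass
class GRM:
    """Genomic relationship matrix with its provenance."""

    matrix: np.ndarray
    variant_ids: list
    alpha: float
    label: str = ""
    scale: float = 1.0  # normalization constant c (additive over partitions)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


def compute_grm(g: GenotypeMatrix, variant_ids=None, alpha: float = -0.5,
                label: str = "", maf=None) -> GRM:
    """MAF-weighted GRM over a variant set (default: all variants).

    Monomorphic variants are excluded with a warning.  Dosages must be
    imputed (no NaN).  Allele frequencies are taken from the dosage mean
    unless ``maf`` (aligned with ``variant_ids``) is supplied for the
    weights; centering always uses the dosage mean.
    """
    ids = list(variant_ids) if variant_ids is not None else list(g.variant_ids)
    if len(ids) == 0:
        raise ValueError("compute_grm requires at least one variant")
    X = g.columns(ids)
    if not np.all(np.isfinite(X)):
        raise ValueError("dosages contain missing values; impute first")
    p = X.mean(axis=0) / 2.0
    f = np.minimum(p, 1 - p)
    mono = (f <= 0) | (f >= 1)
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic variant(s) excluded from GRM")
        keep = ~mono
        X, p, f = X[:, keep], p[keep], f[keep]
        ids = [v for v, k in zip(ids, keep) if k]
        if len(ids) == 0:
            raise ValueError("all variants monomorphic")
    s = (2.0 * f * (1.0 - f)) ** alpha
    Z = (X - 2.0 * p) * np.sqrt(s)
    K = Z @ Z.T
    c = float(np.trace(K)) / K.shape[0]
    K /= c
    K = 0.5 * (K + K.T)
    return GRM(K, ids, alpha, label, scale=c)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _prune_window(R2: np.ndarray, maf: np.ndarray, pos: np.ndarray,
                  kept: np.ndarray, r2_max: float) -> None:
    """Greedy in-place pruning of one window given its pairwise R^2 matrix.

    Pairs are scanned left-to-right; when a kept pair exceeds ``r2_max`` the
    member with lower MAF is dropped (tie: the later position)."""
    k = R2.shape[0]
    for i in range(k):
        if not kept[i]:
            continue
        for j in range(i + 1, k):
            if not kept[j] or not kept[i]:
                if not kept[i]:
                    break
                continue
            if R2[i, j] > r2_max:
                if maf[i] < maf[j]:
                    kept[i] = False
                elif maf[j] < maf[i]:
                    kept[j] = False
                else:
                    kept[j if pos[j] > pos[i] else i] = False


def ld_prune(g: GenotypeMatrix, catalog: pd.DataFrame, mode: str = "window_count",
             window: float = 50, step: int = 5, r2_max: float = 0.2) -> list:
    """Greedy left-to-right LD pruning; returns kept variant ids.

    ``mode="window_count"`` slides windows of ``window`` variants advancing
    by ``step`` (the PLINK ``-indep-pairwise 50 5 0.2`` dialect);
    ``mode="window_kb"`` compares all pairs within ``window`` kilobases
    (the LDAK ``--window-kb`` dialect; ``step`` ignored).  Within a window,
    when a pair exceeds ``r2_max`` the lower-MAF member is dropped (tie:
    later position).  No retained pair within a window exceeds ``r2_max``.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    kept_ids = []
    for chrom, sub in catalog.groupby("chrom", sort=False):
        ids = sub["variant_id"].to_list()
        pos = sub["pos"].to_numpy()
        maf = sub["maf"].to_numpy()
        m = len(ids)
        if m == 0:
            continue
        X = g.columns(ids)
        sd = X.std(axis=0, ddof=0)
        kept = np.ones(m, dtype=bool)
        kept[sd == 0] = False  # monomorphic carry no information

        def corr2_block(idx):
            Xi = X[:, idx]
            C = np.corrcoef(Xi, rowvar=False)
            if np.isscalar(C):
                C = np.array([[1.0]])
            return C * C

        if mode == "window_count":
            # windows are counted over the *currently kept* variants and the
            # scan repeats until a fixpoint, so pruning a pruned set is the
            # identity (idempotence)
            w, st = int(window), max(1, int(step))
            while True:
                alive = np.nonzero(kept)[0]
                changed = False
                for s0 in range(0, max(alive.size - 1, 1), st):
                    idx = alive[s0:s0 + w]
                    if idx.size < 2 or kept[idx].sum() < 2:
                        if s0 + w >= alive.size:
                            break
                        continue
                    R2 = corr2_block(idx)
                    loc = kept[idx].copy()
                    _prune_window(R2, maf[idx], pos[idx], loc, r2_max)
                    if not np.array_equal(loc, kept[idx]):
                        changed = True
                    kept[idx] = loc
                    if s0 + w >= alive.size:
                        break
                if not changed:
                    break
        elif mode == "window_kb":
            span = float(window) * 1000.0
            for j in range(m):
                if not kept[j]:
                    continue
                left = np.nonzero(kept[:j] & (pos[:j] >= pos[j] - span))[0]
                for i in left:
                    if not kept[j]:
                        break
                    if not kept[i]:
                        continue
                    r = np.corrcoef(X[:, i], X[:, j])[0, 1] ** 2
                    if r > r2_max:
                        if maf[i] < maf[j]:
                            kept[i] = False
                        else:
                            kept[j] = False  # lower or tied MAF at later position
        else:
            raise ValueError(f"unknown mode {mode!r}")
        kept_ids.extend([ids[i] for i in range(m) if kept[i]])
    return kept_ids


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def partition_variants(catalog: pd.DataFrame, genes=None, kind: str = "by_class",
                       cis_window: int = 50_000, gene_id: str | None = None,
                       module_genes=None) -> dict:
    """Partition variant ids into labelled disjoint sets.

    * ``by_class`` -> {SNP, INDEL, SV}
    * ``cis_trans`` -> 6 sets crossing class x (within ``cis_window`` of the
      focal gene's span vs not); requires ``gene_id`` and ``genes``
    * ``module_proximal`` -> variants within ``cis_window`` of any gene in
      ``module_genes`` vs the rest
    """
    ids = catalog["variant_id"].to_numpy()
    cls = catalog["var_class"].to_numpy()
    if kind == "by_class":
        return {c: [v for v, k in zip(ids, cls) if k == c] for c in ("SNP", "INDEL", "SV")}
    pos = catalog["pos"].to_numpy()
    chrom = catalog["chrom"].to_numpy()
    if kind == "cis_trans":
        if gene_id is None or genes is None:
            raise ValueError("cis_trans requires genes and a focal gene_id")
        match = [gm for gm in genes if gm.gene_id == gene_id]
        if not match:
            raise ValueError(f"unknown gene id {gene_id!r}")
        gm = match[0]
        cis = (chrom == gm.chrom) & (pos >= gm.start - cis_window) & (pos <= gm.end + cis_window)
        out = {}
        for c in ("SNP", "INDEL", "SV"):
            out[f"cis_{c}"] = [v for v, k, w in zip(ids, cls, cis) if k == c and w]
            out[f"trans_{c}"] = [v for v, k, w in zip(ids, cls, cis) if k == c and not w]
        return out
    if kind == "module_proximal":
        if module_genes is None or genes is None:
            raise ValueError("module_proximal requires genes and module_genes")
        module_set = set(module_genes)
        unknown = module_set - {gm.gene_id for gm in genes}
        if unknown:
            raise ValueError(f"unknown gene id {sorted(unknown)[0]!r}")
        prox = np.zeros(len(ids), dtype=bool)
        for gm in genes:
            if gm.gene_id in module_set:
                prox |= (chrom == gm.chrom) & (pos >= gm.start - cis_window) & \
                        (pos <= gm.end + cis_window)
        return {"module_proximal": list(ids[prox]), "rest": list(ids[~prox])}
    raise ValueError(f"unknown partition kind {kind!r}")


# ---------------------------------------------------------------------------
# LD profiling
# ---------------------------------------------------------------------------

def max_adjacent_r2(g: GenotypeMatrix, catalog: pd.DataFrame,
                    focal_class: str = "SV", window: int = 50_000) -> pd.DataFrame:
    """Per-focal-variant maximum squared correlation with flanking small
    variants within ``window`` bp on either side.

    Returns a DataFrame (variant_id, chrom, pos, max_r2, best_tag); focal
    variants with no neighbours get NaN.
    """
    out = []
    for chrom, sub in catalog.groupby("chrom", sort=False):
        ids = sub["variant_id"].to_numpy()
        pos = sub["pos"].to_numpy()
        cls = sub["var_class"].to_numpy()
        X = g.columns(list(ids))
        Xc = X - X.mean(axis=0)
        ss = np.sqrt((Xc ** 2).sum(axis=0))
        focal = np.nonzero(cls == focal_class)[0]
        small = np.nonzero(cls != focal_class)[0]
        for j in focal:
            near = small[(pos[small] >= pos[j] - window) & (pos[small] <= pos[j] + window)]
            if near.size == 0 or ss[j] == 0:
                out.append((ids[j], chrom, int(pos[j]), np.nan, None))
                continue
            denom = ss[j] * ss[near]
            ok = denom > 0
            r = np.zeros(near.size)
            r[ok] = (Xc[:, near[ok]].T @ Xc[:, j]) / denom[ok]
            r2 = r * r
            b = int(np.argmax(r2))
            out.append((ids[j], chrom, int(pos[j]), float(r2[b]), ids[near[b]]))
    return pd.DataFrame(out, columns=["variant_id", "chrom", "pos", "max_r2", "best_tag"])
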