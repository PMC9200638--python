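"""Single-variant mixed-model association with leave-one-chromosome-out
(LOCO) kinship, significance thresholds, QTL clustering and cis/trans calls.

For each chromosome c the variance components of
y ~ N(X beta, sigma2_g K_(-c) + sigma2_e I) are estimated once from a GRM
built on LD-pruned variants of all *other* chromosomes; every variant on c
is then tested by generalized least squares with that fixed variance ratio
(the GCTA-MLMA / GRAMMAR-style approximation).  Wald chi-square p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, GeneModel
from .kinship import compute_grm, ld_prune
from .varcomp import build_covariates, eigen_grm, profile_reml_1grm, reml_fit


@dataclass
class QTL:
    """A cluster of linked significant variants."""

    members: list
    lead: str
    chrom: str
    start: int
    end: int
    lead_p: float


def bonferroni_threshold(n_markers: int, famwise: float = 0.05) -> float:
    """-log10 of the Bonferroni-corrected per-marker threshold."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return float(-np.log10(famwise / n_markers))


class LocoMLM:
    """Precomputed LOCO mixed-model scanner.

    Builds per-chromosome leave-one-out GRMs from LD-pruned variants and
    caches their eigendecompositions so many traits can be scanned cheaply.
    ``covariates`` defaults to intercept + top-4 genotype PCs.
    """

    def __init__(self, g: GenotypeMatrix, catalog: pd.DataFrame, covariates=None,
                 grm_prune=(50, 5, 0.2), alpha: float = -0.5):
        self.g, self.catalog = g, catalog
        self.X = build_covariates(g, catalog) if covariates is None else \
            np.atleast_2d(np.asarray(covariates, dtype=float))
        if self.X.shape[0] != g.n_accessions:
            self.X = self.X.T
        chroms = list(pd.unique(catalog["chrom"]))
        self.single_chrom = len(chroms) < 2
        if self.single_chrom:
            warnings.warn("single-chromosome input: falling back to a whole-genome GRM")
        w, s, r2 = grm_prune
        kept = ld_prune(g, catalog, mode="window_count", window=w, step=s, r2_max=r2)
        kept_by_chrom = {}
        kc = catalog.set_index("variant_id")["chrom"]
        for v in kept:
            kept_by_chrom.setdefault(kc[v], []).append(v)
        self._eig = {}
        self._chrom_ids = {}
        self.grm_variant_ids = {}  # chrom -> ids that built its LOCO kinship
        for c in chroms:
            ids = [v for cc in chroms if (cc != c or self.single_chrom)
                   for v in kept_by_chrom.get(cc, [])]
            self.grm_variant_ids[c] = list(ids)
            K = compute_grm(g, ids, alpha=alpha, label=f"loco_{c}")
            self._eig[c] = eigen_grm(K)
            sub = catalog[catalog["chrom"] == c]
            self._chrom_ids[c] = (sub["variant_id"].to_list(), sub["pos"].to_numpy())
        # rotated genotypes and covariates are trait-independent; cache them
        self._rot = {}
        for c in chroms:
            lam, U = self._eig[c]
            ids, _ = self._chrom_ids[c]
            self._rot[c] = (U.T @ self.g.columns(ids), U.T @ self.X)

    def scan(self, y) -> pd.DataFrame:
        """Association statistics for every variant; returns a DataFrame with
        columns variant_id, chrom, pos, beta, se, p, neglog10p."""
        y = np.asarray(y, dtype=float).ravel()
        rows = []
        for c, (ids, pos) in self._chrom_ids.items():
            lam, U = self._eig[c]
            h2, s2g, s2e, _, _ = profile_reml_1grm(y, self.X, (lam, U))
            d = s2g * lam + s2e
            w = 1.0 / d
            yr = U.T @ y
            Gr, Xr = self._rot[c]
            XtWX = Xr.T @ (Xr * w[:, None])
            XtWXi = np.linalg.inv(XtWX)
            # residualize y and g against covariates in the W metric
            yres = yr - Xr @ (XtWXi @ (Xr.T @ (yr * w)))
            A = XtWXi @ (Xr.T @ (Gr * w[:, None]))
            Gres = Gr - Xr @ A
            gWg = np.einsum("ij,ij->j", Gres, Gres * w[:, None])
            gWy = Gres.T @ (yres * w)
            ok = gWg > 1e-12
            beta = np.full(len(ids), np.nan)
            se = np.full(len(ids), np.nan)
            beta[ok] = gWy[ok] / gWg[ok]
            se[ok] = np.sqrt(1.0 / gWg[ok])
            chi2 = np.zeros(len(ids))
            chi2[ok] = (beta[ok] / se[ok]) ** 2
            p = np.where(ok, stats.chi2.sf(chi2, df=1), np.nan)
            p = np.clip(p, np.finfo(float).tiny, 1.0)
            for i, v in enumerate(ids):
                rows.append((v, c, int(pos[i]), beta[i], se[i], float(p[i])))
        df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "beta", "se", "p"])
        df["neglog10p"] = -np.log10(df["p"])
        return df


def mlm_loco_scan(y, g: GenotypeMatrix, catalog: pd.DataFrame, covariates=None,
                  grm_prune=(50, 5, 0.2)) -> pd.DataFrame:
    """One-shot LOCO mixed-model scan (see :class:`LocoMLM` for batches)."""
    return LocoMLM(g, catalog, covariates, grm_prune).scan(y)


def cluster_qtls(records: pd.DataFrame, g: GenotypeMatrix, r2_link: float = 0.20,
                 max_dist: float = 1e6, min_members: int = 4) -> list:
    """Group significant variants into QTLs.

    A single left-to-right pass per chromosome links *adjacent* significant
    variants when their dosage R^2 exceeds ``r2_link`` AND their distance is
    below ``max_dist``; clusters with at least ``min_members`` variants
    ("more than three") become QTLs.  The leading variant is the smallest p
    (tie: smallest position).
    """
    qtls = []
    df = records.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, sub in df.groupby("chrom", sort=False):
        ids = sub["variant_id"].to_list()
        pos = sub["pos"].to_numpy()
        ps = sub["p"].to_numpy()
        if not ids:
            continue
        X = g.columns(ids)
        cluster = [0]
        clusters = []
        for i in range(1, len(ids)):
            a, b = X[:, i - 1], X[:, i]
            r2 = 0.0
            if a.std() > 0 and b.std() > 0:
                r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
            if r2 > r2_link and (pos[i] - pos[i - 1]) < max_dist:
                cluster.append(i)
            else:
                clusters.append(cluster)
                cluster = [i]
        clusters.append(cluster)
        for cl in clusters:
            if len(cl) < min_members:
                continue
            cp = ps[cl]
            best = min(range(len(cl)), key=lambda k: (cp[k], pos[cl[k]]))
            qtls.append(QTL([ids[i] for i in cl], ids[cl[best]], chrom,
                            int(pos[cl].min()), int(pos[cl].max()),
                            float(cp[best])))
    return qtls


def classify_eqtl(qtl: QTL, gene: GeneModel, records: pd.DataFrame | None = None,
                  window: int = 50_000, lead_pos: int | None = None) -> str:
    """cis/trans call for an eQTL: cis iff the leading variant lies on the
    gene's chromosome within ``window`` bp of the gene start or end."""
    if qtl.chrom != gene.chrom:
        return "trans"
    if lead_pos is None:
        if records is not None:
            lead_pos = int(records.set_index("variant_id").loc[qtl.lead, "pos"])
        else:
            raise ValueError("need records or lead_pos to locate the leading variant")
    d = min(abs(lead_pos - gene.start), abs(lead_pos - gene.end))
    if gene.start <= lead_pos <= gene.end:
        d = 0
    return "cis" if d < window else "trans"


def variant_set_h2(y, g: GenotypeMatrix, variant_ids, covariates,
                   alpha: float = -0.5) -> float:
    """Heritability explained by one variant set: single-GRM REML total h2.

    For a single variant this reduces to the standardized regression R^2
    under the mixed model.
    """
    ids = list(variant_ids)
    if not ids:
        raise ValueError("variant set is empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        K = compute_grm(g, ids, alpha=alpha, label="set")
    fit = reml_fit(np.asarray(y, dtype=float), covariates, [K], labels=["set"])
    return float(fit.h2["set"])
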