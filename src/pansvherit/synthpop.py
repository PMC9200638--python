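"""Synthetic inbred population generator.

Emulates the statistical structure of a resequenced crop diversity panel:
~330 inbred accessions drawn from three subpopulations, three co-segregating
variant classes (SNP / indel / SV), incomplete linkage disequilibrium between
SVs and their flanking small variants (tunable maximum tag R^2, reference
value 0.70), and a degraded "linear callset" retaining only ~20% of SVs —
the footprint of reference bias when mapping against a single linear genome.

The mechanism is founder-mosaic, not coalescent: each subpopulation carries a
small founder haplotype panel (allele frequencies drifted from a shared
ancestral frequency, Balding–Nichols style), and every accession is a
homozygous recombinant mosaic of its subpopulation's founders.  Inbred lines
are therefore (near-)fully homozygous by construction, dosages in {0, 2}.

Traits are built with *in-sample exact* variance scaling: per-class genetic
scores are orthogonalized and rescaled so realized variance fractions equal
their targets to machine precision, which keeps parameter-recovery tests
sharp at n ~ 330.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GeneModel, GenotypeMatrix, TraitTable, folded_maf, make_catalog

# subpopulation fractions mirror a 217/98/17 panel of 332 inbred accessions
DEFAULT_SUBPOP_FRACTIONS = (217 / 332, 98 / 332, 17 / 332)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic population."""

    n_accessions: int = 332
    n_founders: int = 8                      # founder haplotypes per subpopulation
    subpop_fractions: tuple = DEFAULT_SUBPOP_FRACTIONS
    n_chrom: int = 6
    chrom_length: int = 2_000_000
    variants_per_chrom: dict = field(
        default_factory=lambda: {"SNP": 700, "INDEL": 70, "SV": 35})
    target_sv_tag_r2: float = 0.70           # median max R^2 of SVs with small variants
    sv_retention_linear: float = 0.20        # SV fraction surviving the linear callset
    recomb_events_per_chrom: float = 3.0
    fst: float = 0.15                        # subpopulation differentiation
    n_genes_per_chrom: int = 25
    n_allelic_het_genes: int = 5             # genes forced to carry >=2 low-MAF cis-SVs
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.subpop_fractions) - 1.0) > 1e-9:
            raise ValueError("subpop_fractions must sum to 1")
        if not (0.0 <= self.sv_retention_linear <= 1.0):
            raise ValueError("sv_retention_linear must be in [0, 1]")
        if not (0.0 <= self.target_sv_tag_r2 <= 1.0):
            raise ValueError("target_sv_tag_r2 must be in [0, 1]")


@dataclass
class TraitSpec:
    """Requested architecture for one simulated trait.

    ``kind`` is one of:

    * ``"by_class"`` — polygenic with per-class heritability targets
      ``h2_by_class`` and causal counts ``n_causal_by_class``;
    * ``"allelic_het"`` — a single gene whose +/-50 kb window carries >= 2
      low-MAF causal SVs (MAF pattern ~0.017 / ~0.032) plus optional
      polygenic background;
    * ``"module"`` — driven by the cis-SVs of several co-expression module
      genes through a latent module score (locus heterogeneity).
    """

    name: str
    kind: str = "by_class"
    h2_by_class: dict = field(default_factory=lambda: {"SNP": 0.10, "INDEL": 0.04, "SV": 0.27})
    n_causal_by_class: dict = field(default_factory=lambda: {"SNP": 120, "INDEL": 24, "SV": 24})
    # allelic_het
    gene_id: str | None = None
    n_het_svs: int = 2
    h2_het: float = 0.30
    h2_background: float = 0.20     # polygenic SNP background of het traits
    n_background_causal: int = 100
    # module
    module_genes: list | None = None
    h2_module: float = 0.40
    alpha: float = -0.5


@dataclass
class SimTruth:
    """Ground-truth causal architecture for parameter-recovery tests."""

    causal_ids: dict            # trait -> list of causal variant ids
    effects: dict               # trait -> {variant_id: beta on standardized dosage}
    h2_by_class: dict           # trait -> {class: realized in-sample h2 fraction}
    het_windows: dict           # gene_id -> list of causal SV ids (with MAFs)
    module_membership: dict     # gene_id -> module label
    module_scores: dict         # module label -> per-accession latent score


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _subpop_sizes(n: int, fractions) -> np.ndarray:
    sizes = np.floor(np.asarray(fractions) * n).astype(int)
    sizes[0] += n - sizes.sum()
    return sizes


def _mosaic_haplotypes(rng, founders, n_acc, positions, chrom_length, recomb_rate):
    """Homozygous mosaic accessions from one subpopulation's founder panel."""
    n_f, m = founders.shape
    out = np.empty((n_acc, m), dtype=np.int8)
    for a in range(n_acc):
        n_bk = rng.poisson(recomb_rate)
        breaks = np.sort(rng.uniform(0, chrom_length, size=n_bk))
        seg = np.searchsorted(breaks, positions)  # segment index per variant
        choice = rng.integers(0, n_f, size=n_bk + 1)
        out[a] = founders[choice[seg], np.arange(m)]
    return out


def _calibrate_flips(rng, base: np.ndarray, target_r2: float) -> np.ndarray:
    """Copy a binary allele vector and flip entries to degrade its correlation
    with the original towards sqrt(target_r2)."""
    n = base.size
    out = base.copy()
    if target_r2 >= 1.0:
        return out
    order = rng.permutation(n)
    best, best_gap = out.copy(), abs(_r2(base, out) - target_r2)
    cur = out.copy()
    for i, idx in enumerate(order):
        cur[idx] = 1 - cur[idx]
        gap = abs(_r2(base, cur) - target_r2)
        if gap < best_gap:
            best, best_gap = cur.copy(), gap
        if _r2(base, cur) < target_r2 - 0.05 and i > 2:
            break
    return best


def _r2(a, b) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    c = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
    return float(c * c)


def simulate_population(cfg: SimConfig):
    """Simulate (catalog, GenotypeMatrix, genes list).

    Founder haplotypes are drawn per subpopulation around shared ancestral
    frequencies (Balding–Nichols drift at ``cfg.fst``); accessions are
    homozygous founder mosaics.  SV columns are then re-derived from a
    flanking small variant and degraded by random allele flips so the
    distribution of per-SV maximum R^2 with small variants within +/-50 kb
    has median near ``cfg.target_sv_tag_r2``.  A subset of genes is forced
    to carry >= 2 low-MAF cis-SVs for allelic-heterogeneity scenarios.
    Fully deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = _subpop_sizes(cfg.n_accessions, cfg.subpop_fractions)
    n_sub = len(sizes)

    rows, hap_cols = [], []
    m_per_chrom = sum(cfg.variants_per_chrom.values())
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1:02d}"
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length), size=m_per_chrom,
                                 replace=False))
        classes = np.concatenate([np.repeat(k, v) for k, v in cfg.variants_per_chrom.items()])
        rng.shuffle(classes)
        # ancestral frequencies; SVs skewed towards lower frequency
        p0 = np.where(classes == "SV",
                      rng.beta(0.9, 1.8, size=m_per_chrom),
                      rng.uniform(0.05, 0.95, size=m_per_chrom))
        p0 = np.clip(p0, 0.02, 0.98)
        a = p0 * (1 - cfg.fst) / cfg.fst
        b = (1 - p0) * (1 - cfg.fst) / cfg.fst
        haps = np.empty((cfg.n_accessions, m_per_chrom), dtype=np.int8)
        row0 = 0
        for s in range(n_sub):
            ps = rng.beta(a, b)
            founders = (rng.uniform(size=(cfg.n_founders, m_per_chrom)) < ps).astype(np.int8)
            haps[row0:row0 + sizes[s]] = _mosaic_haplotypes(
                rng, founders, sizes[s], pos, cfg.chrom_length, cfg.recomb_events_per_chrom)
            row0 += sizes[s]
        for j in range(m_per_chrom):
            cls = classes[j]
            if cls == "SNP":
                svt, ln = "NA", 1
            elif cls == "INDEL":
                svt, ln = "NA", int(rng.integers(1, 51))
            else:
                svt = rng.choice(["INS", "DEL", "INV"], p=[0.5, 0.45, 0.05])
                ln = int(np.clip(rng.lognormal(6.5, 1.2), 51, 100_000))
            rows.append(dict(variant_id=f"{cls.lower()}{c + 1}_{pos[j]}", chrom=chrom,
                             pos=int(pos[j]), var_class=cls, sv_type=svt, length=ln,
                             maf=np.nan))
        hap_cols.append(haps)

    haps = np.concatenate(hap_cols, axis=1)
    cat = pd.DataFrame(rows)

    # --- SV tagging: rebuild each SV from a flanking small variant ----------
    small_mask = (cat["var_class"] != "SV").to_numpy()
    for chrom, sub in cat.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        sv_local = np.nonzero((~small_mask[idx]))[0]
        small_local = np.nonzero(small_mask[idx])[0]
        if small_local.size == 0:
            continue
        for sl in sv_local:
            near = small_local[np.abs(pos[small_local] - pos[sl]) <= 50_000]
            near = near[[haps[:, idx[t]].std() > 0 for t in near]]  # polymorphic tags only
            if near.size == 0:
                continue
            tag = near[np.argmin(np.abs(pos[near] - pos[sl]))]
            target = float(np.clip(rng.normal(cfg.target_sv_tag_r2, 0.15), 0.02, 1.0)) \
                if cfg.target_sv_tag_r2 < 1.0 else 1.0
            base = haps[:, idx[tag]]
            haps[:, idx[sl]] = _calibrate_flips(rng, base, target)

    # --- gene models --------------------------------------------------------
    genes = []
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1:02d}"
        starts = np.sort(rng.choice(np.arange(10_000, cfg.chrom_length - 20_000),
                                    size=cfg.n_genes_per_chrom, replace=False))
        for k, st in enumerate(starts):
            ln = int(rng.integers(2_000, 10_000))
            genes.append(GeneModel(f"gene{c + 1:02d}_{k:03d}", chrom, int(st),
                                   int(st + ln), rng.choice(["+", "-"])))

    # --- force low-MAF allelic-het cis-SV pairs near some genes -------------
    cat_pos = cat["pos"].to_numpy()
    cat_chrom = cat["chrom"].to_numpy()
    is_sv = (cat["var_class"] == "SV").to_numpy()
    cis_svs = {}
    for gi, gm in enumerate(genes):
        win = (cat_chrom == gm.chrom) & (cat_pos >= gm.start - 50_000) & \
              (cat_pos <= gm.end + 50_000) & is_sv
        sv_idx = np.nonzero(win)[0]
        if sv_idx.size >= 2:
            cis_svs[gi] = sv_idx
    candidates = np.array(sorted(cis_svs))
    het_genes = rng.choice(candidates,
                           size=min(cfg.n_allelic_het_genes, candidates.size),
                           replace=False) if candidates.size else np.array([], dtype=int)
    het_windows = {}
    for gi in het_genes:
        gm = genes[gi]
        sv_idx = cis_svs[gi]
        chosen = rng.choice(sv_idx, size=2, replace=False)
        for k, j in enumerate(chosen):
            # MAF pattern ~0.017 and ~0.032: few homozygous carriers
            n_carr = max(2, int(round((0.017 if k == 0 else 0.032) * cfg.n_accessions)))
            col = np.zeros(cfg.n_accessions, dtype=np.int8)
            col[rng.choice(cfg.n_accessions, size=n_carr, replace=False)] = 1
            haps[:, j] = col
        het_windows[gm.gene_id] = [cat.iloc[j]["variant_id"] for j in chosen]

    dosages = 2.0 * haps.astype(float)
    cat["maf"] = [folded_maf(dosages[:, j]) for j in range(dosages.shape[1])]
    # drop monomorphic columns
    keep = cat["maf"].to_numpy() > 0
    cat = cat.loc[keep].reset_index(drop=True)
    dosages = dosages[:, keep]
    cat = make_catalog(cat.to_dict("records"))
    accessions = [f"acc{i:04d}" for i in range(cfg.n_accessions)]
    g = GenotypeMatrix(accessions, list(cat["variant_id"]), dosages)
    g.subpop = np.repeat(np.arange(n_sub), sizes)  # convenience attribute
    return cat, g, genes, het_windows


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _exact_components(rng, scores: list, h2s: list, n: int):
    """Orthogonalize component scores sequentially and scale them so each
    contributes exactly its target variance fraction; residual noise is
    orthogonal to all components.  Returns (y, scaled components)."""
    comps, basis = [], []
    for gsc, h2 in zip(scores, h2s):
        v = gsc - gsc.mean()
        for b in basis:
            v = v - b * (b @ v)
        nv = np.linalg.norm(v)
        if nv < 1e-12 or h2 <= 0:
            comps.append(np.zeros(n))
            continue
        u = v / nv
        basis.append(u)
        comps.append(u * np.sqrt(h2 * n))  # sample variance exactly h2
    e = rng.standard_normal(n)
    e = e - e.mean()
    for b in basis:
        e = e - b * (b @ e)
    h_tot = sum(h2s)
    if h_tot < 1.0:
        e = e / e.std(ddof=0) * np.sqrt(1.0 - h_tot)
    else:
        e = np.zeros(n)
    y = np.sum(comps, axis=0) + e
    return y, comps


def simulate_traits(g: GenotypeMatrix, catalog: pd.DataFrame, specs,
                    het_windows: dict | None = None, seed: int = 0,
                    module_scores: dict | None = None):
    """Simulate traits per a list of :class:`TraitSpec`.

    Effects on standardized dosages are drawn with variance proportional to
    ``[f(1-f)]^(1+alpha)`` (alpha default -0.5) so per-variant heritability
    tapers with MAF, matching the estimation-side weighting.  Realized
    per-class variance fractions equal their targets exactly in-sample.

    Returns ``(TraitTable, SimTruth)``.
    """
    rng = np.random.default_rng(seed)
    n = g.n_accessions
    maf = catalog["maf"].to_numpy()
    cls = catalog["var_class"].to_numpy()
    truth = SimTruth({}, {}, {}, dict(het_windows or {}), {}, dict(module_scores or {}))
    cols = {}
    for spec in specs:
        if spec.kind == "by_class":
            scores, labels, caus, eff = [], [], [], {}
            for c in ("SNP", "INDEL", "SV"):
                h2 = spec.h2_by_class.get(c, 0.0)
                k = spec.n_causal_by_class.get(c, 0)
                avail = np.nonzero(cls == c)[0]
                if k > avail.size:
                    raise ValueError(f"requested {k} causal {c}s, only {avail.size} available")
                if h2 <= 0 or k == 0:
                    scores.append(np.zeros(n)); labels.append(c)
                    continue
                j = rng.choice(avail, size=k, replace=False)
                w = (maf[j] * (1 - maf[j])) ** (1 + spec.alpha)
                beta = rng.standard_normal(k) * np.sqrt(w)
                Z = _standardize(g.dosages[:, j])
                scores.append(Z @ beta); labels.append(c)
                caus.extend(catalog.iloc[j]["variant_id"])
                eff.update(dict(zip(catalog.iloc[j]["variant_id"], beta)))
            h2s = [spec.h2_by_class.get(c, 0.0) for c in ("SNP", "INDEL", "SV")]
            y, comps = _exact_components(rng, scores, h2s, n)
            truth.h2_by_class[spec.name] = dict(zip(("SNP", "INDEL", "SV"),
                                                    [v.var(ddof=0) / max(y.var(ddof=0), 1e-300)
                                                     for v in comps]))
        elif spec.kind == "allelic_het":
            if not truth.het_windows:
                raise ValueError("no allelic-het windows available in this population")
            gene = spec.gene_id or sorted(truth.het_windows)[0]
            svs = truth.het_windows[gene][: spec.n_het_svs]
            if len(svs) < spec.n_het_svs:
                raise ValueError(f"gene {gene} has only {len(svs)} forced cis-SVs")
            Z = _standardize(g.columns(svs))
            beta = rng.standard_normal(len(svs)) * 0.5 + np.sign(rng.standard_normal(len(svs)))
            score = Z @ beta
            caus, eff = list(svs), dict(zip(svs, beta))
            scores, h2s = [score], [spec.h2_het]
            if spec.h2_background > 0:
                avail = np.nonzero(cls == "SNP")[0]
                jbg = rng.choice(avail, size=min(spec.n_background_causal, avail.size),
                                 replace=False)
                wbg = (maf[jbg] * (1 - maf[jbg])) ** (1 + spec.alpha)
                bbg = rng.standard_normal(jbg.size) * np.sqrt(wbg)
                scores.append(_standardize(g.dosages[:, jbg]) @ bbg)
                h2s.append(spec.h2_background)
                caus.extend(catalog.iloc[jbg]["variant_id"])
                eff.update(dict(zip(catalog.iloc[jbg]["variant_id"], bbg)))
            y, comps = _exact_components(rng, scores, h2s, n)
            truth.h2_by_class[spec.name] = {"SV": spec.h2_het,
                                            "SNP": spec.h2_background}
        elif spec.kind == "module":
            if not spec.module_genes:
                raise ValueError("module spec requires module_genes")
            score = np.zeros(n)
            caus, eff = [], {}
            for gid, sv in spec.module_genes:
                z = _standardize(g.columns([sv]))[:, 0]
                b = 1.0 + 0.5 * rng.standard_normal()
                score = score + b * z
                caus.append(sv); eff[sv] = b
                truth.module_membership[gid] = spec.name
            y, comps = _exact_components(rng, [score], [spec.h2_module], n)
            truth.module_scores[spec.name] = score
            truth.h2_by_class[spec.name] = {"SV": spec.h2_module}
        else:
            raise ValueError(f"unknown trait kind {spec.kind!r}")
        truth.causal_ids[spec.name] = caus
        truth.effects[spec.name] = eff
        cols[spec.name] = y
    tt = TraitTable(pd.DataFrame(cols, index=g.accessions), "agronomic")
    return tt, truth


# ---------------------------------------------------------------------------
# expression matrices with module structure
# ---------------------------------------------------------------------------

def simulate_expression(g: GenotypeMatrix, catalog: pd.DataFrame, genes,
                        module_specs, n_background: int = 60,
                        noise_sd: float = 0.6, seed: int = 0):
    """Expression matrix with planted co-expression modules.

    ``module_specs`` is a list of dicts with keys ``name``, ``genes`` (list
    of (gene_id, cis_sv_id or None)), and optional ``factor_sd``.  Genes in
    a module share a latent factor; genes with a cis-SV additionally load on
    that SV's standardized dosage.  ``n_background`` independent genes are
    appended.  Returns (TraitTable, module_membership, latent_scores).
    """
    rng = np.random.default_rng(seed)
    n = g.n_accessions
    cols, membership, latents = {}, {}, {}
    for ms in module_specs:
        factor = rng.standard_normal(n)
        latents[ms["name"]] = factor
        for gid, sv in ms["genes"]:
            x = ms.get("factor_loading", 1.0) * factor
            if sv is not None:
                x = x + ms.get("sv_loading", 1.0) * _standardize(g.columns([sv]))[:, 0]
            cols[gid] = x + noise_sd * rng.standard_normal(n)
            membership[gid] = ms["name"]
    used = set(membership)
    free = [gm.gene_id for gm in genes if gm.gene_id not in used][:n_background]
    for gid in free:
        cols[gid] = rng.standard_normal(n)
        membership[gid] = "grey"
    tt = TraitTable(pd.DataFrame(cols, index=g.accessions), "expression")
    return tt, membership, latents


# ---------------------------------------------------------------------------
# linear-callset degradation
# ---------------------------------------------------------------------------

def degrade_to_linear_callset(g: GenotypeMatrix, catalog: pd.DataFrame,
                              retention: float = 0.20, seed: int = 0):
    """Emulate a linear-reference callset: keep all SNPs/indels but only a
    uniform random fraction ``retention`` of SVs (sampling without
    replacement, exact count).  Deterministic under ``seed``."""
    if not (0.0 <= retention <= 1.0):
        raise ValueError("retention must be in [0, 1]")
    rng = np.random.default_rng(seed)
    is_sv = (catalog["var_class"] == "SV").to_numpy()
    sv_idx = np.nonzero(is_sv)[0]
    n_keep = int(round(retention * sv_idx.size))
    kept_sv = set(rng.choice(sv_idx, size=n_keep, replace=False)) if n_keep else set()
    keep = np.array([(not s) or (i in kept_sv) for i, s in enumerate(is_sv)])
    cat2 = catalog.loc[keep].reset_index(drop=True)
    g2 = GenotypeMatrix(list(g.accessions), list(cat2["variant_id"]),
                        g.dosages[:, keep].copy())
    return cat2, g2
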