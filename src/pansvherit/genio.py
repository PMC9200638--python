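"""Data model, readers/writers and phenotype preprocessing.

The whole package works on three in-memory containers:

* a *variant catalog* — a :class:`pandas.DataFrame` with one row per variant
  (columns ``variant_id, chrom, pos, var_class, sv_type, length, maf``),
  sorted by position within chromosome;
* a :class:`GenotypeMatrix` — accession x variant dosage matrix with entries
  in {0, 1, 2} and NaN for missing calls;
* a :class:`TraitTable` — accession x trait matrix of phenotypes
  (expression TPM, metabolite intensities or agronomic traits).

Variant classes follow the small/structural convention: SNPs have allele
length 1, indels net length 1-50 bp, structural variants (SVs) > 50 bp.
Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

log = logging.getLogger("pansvherit")

VAR_CLASSES = ("SNP", "INDEL", "SV")
CATALOG_COLUMNS = ("variant_id", "chrom", "pos", "var_class", "sv_type", "length", "maf")

INDEL_MAX_BP = 50  # net allele-length difference separating indels from SVs


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Accession x variant dosage table.

    ``dosages`` is a float array of shape (n_accessions, n_variants) whose
    entries count ALT alleles (0, 1 or 2); missing calls are NaN.  Column
    order matches the accompanying variant catalog.
    """

    accessions: list
    variant_ids: list
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accessions), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.variant_ids)} variants"
            )
        self._col_index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def col(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant id."""
        return self.dosages[:, self._col_index[variant_id]]

    def columns(self, variant_ids) -> np.ndarray:
        idx = [self._col_index[v] for v in variant_ids]
        return self.dosages[:, idx]

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        ids = list(variant_ids)
        return GenotypeMatrix(list(self.accessions), ids, self.columns(ids).copy())


@dataclass
class GeneModel:
    """A gene span (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class TraitTable:
    """Accession x trait phenotype matrix.

    ``values`` holds accessions in rows (index = accession ids) and traits in
    columns; NaN marks missing measurements.  ``trait_kind`` is one of
    ``expression``, ``metabolite`` or ``agronomic``.
    """

    values: pd.DataFrame
    trait_kind: str = "agronomic"

    def __post_init__(self):
        if self.trait_kind not in ("expression", "metabolite", "agronomic"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")

    @property
    def accessions(self):
        return list(self.values.index)

    @property
    def trait_ids(self):
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# catalog helpers
# ---------------------------------------------------------------------------

def folded_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency from non-missing dosages, folded to <= 0.5."""
    x = dosages[np.isfinite(dosages)]
    if x.size == 0:
        return np.nan
    f = float(np.mean(x)) / 2.0
    return min(f, 1.0 - f)


def make_catalog(records) -> pd.DataFrame:
    """Build a variant catalog DataFrame from an iterable of row dicts."""
    cat = pd.DataFrame(list(records), columns=list(CATALOG_COLUMNS))
    return validate_catalog(cat)


def validate_catalog(cat: pd.DataFrame) -> pd.DataFrame:
    """Check catalog invariants; returns the (unchanged) frame."""
    if cat["variant_id"].duplicated().any():
        dup = cat.loc[cat["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant id {dup!r}")
    for chrom, sub in cat.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    bad = ~cat["var_class"].isin(VAR_CLASSES)
    if bad.any():
        raise ValueError(f"unknown var_class {cat.loc[bad, 'var_class'].iloc[0]!r}")
    snp = cat["var_class"] == "SNP"
    if (cat.loc[snp, "length"] != 1).any():
        raise ValueError("SNP with length != 1")
    ind = cat["var_class"] == "INDEL"
    if ((cat.loc[ind, "length"] < 1) | (cat.loc[ind, "length"] > INDEL_MAX_BP)).any():
        raise ValueError(f"INDEL with length outside [1, {INDEL_MAX_BP}]")
    sv = cat["var_class"] == "SV"
    if (cat.loc[sv, "length"] <= INDEL_MAX_BP).any():
        raise ValueError(f"SV with length <= {INDEL_MAX_BP}")
    return cat


def classify_alleles(ref: str, alt: str) -> tuple:
    """(var_class, sv_type, length) from explicit REF/ALT sequences.

    The net allele-length difference decides the class: 0 (with single-base
    alleles) -> SNP, 1-50 bp -> INDEL, > 50 bp -> SV.
    """
    net = abs(len(alt) - len(ref))
    if net == 0:
        if len(ref) == 1:
            return "SNP", "NA", 1
        # balanced substitution; treat by total length
        return ("SV", "INV", len(ref)) if len(ref) > INDEL_MAX_BP else ("INDEL", "NA", len(ref))
    sv_type = "INS" if len(alt) > len(ref) else "DEL"
    if net <= INDEL_MAX_BP:
        return "INDEL", sv_type, net
    return "SV", sv_type, net


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple:
    """Read a VCF into (catalog, GenotypeMatrix).

    Requires biallelic records; symbolic SV ALTs (``<DEL>`` etc.) must carry
    INFO/SVTYPE and INFO/SVLEN.  Dosage = count of ALT alleles; ``./.`` is
    missing.  MAF is computed from non-missing dosages and folded.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS} ({v.ID or 'no id'})")
        alt = v.ALT[0]
        if alt.startswith("<"):
            svtype = v.INFO.get("SVTYPE")
            svlen = v.INFO.get("SVLEN")
            if svlen is None:
                raise ValueError(f"symbolic ALT without SVLEN at {v.CHROM}:{v.POS} ({v.ID or 'no id'})")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            length = abs(int(svlen))
            var_class = "SV" if length > INDEL_MAX_BP else "INDEL"
            sv_type = str(svtype) if svtype else ("DEL" if int(svlen) < 0 else "INS")
        else:
            var_class, sv_type, length = classify_alleles(v.REF, alt)
        dos = np.full(len(accessions), np.nan)
        for i, gt in enumerate(v.genotypes):
            a = [x for x in gt[:-1] if x >= 0]
            if len(a) == len(gt) - 1 and len(a) > 0:
                dos[i] = float(sum(a))
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        rows.append(dict(variant_id=vid, chrom=v.CHROM, pos=v.POS, var_class=var_class,
                         sv_type=sv_type if var_class == "SV" else ("NA" if var_class == "SNP" else sv_type),
                         length=length, maf=folded_maf(dos)))
        cols.append(dos)
    cat = make_catalog(rows)
    g = GenotypeMatrix(accessions, list(cat["variant_id"]), np.column_stack(cols) if cols else
                       np.empty((len(accessions), 0)))
    return cat, g


def _vcf_alleles(row) -> tuple:
    """Synthesize REF/ALT/INFO for one catalog row (for writing)."""
    cls, svt, ln = row["var_class"], row["sv_type"], int(row["length"])
    if cls == "SNP":
        return "A", "T", "."
    if cls == "INDEL":
        if svt == "DEL":
            return "A" + "C" * ln, "A", "."
        return "A", "A" + "C" * ln, "."
    svt = svt if svt in ("INS", "DEL", "INV") else "INS"
    svlen = -ln if svt == "DEL" else ln
    return "A", f"<{svt}>", f"SVTYPE={svt};SVLEN={svlen}"


def write_vcf(path, catalog: pd.DataFrame, g: GenotypeMatrix) -> None:
    """Write catalog + dosages as a minimal VCF v4.2 (GT only).

    Dosage 1 is written as ``0/1`` and 2 as ``1/1`` (accessions here are
    inbred, so heterozygotes are rare but representable); NaN becomes ``./.``.
    Allele sequences are synthetic placeholders carrying the class-defining
    lengths, so ``read_vcf(write_vcf(...))`` round-trips classes and dosages.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(catalog["chrom"]):
            end = int(catalog.loc[catalog["chrom"] == chrom, "pos"].max()) + 100000
            fh.write(f"##contig=<ID={chrom},length={end}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.accessions)) + "\n")
        for _, row in catalog.iterrows():
            ref, alt, info = _vcf_alleles(row)
            dos = g.col(row["variant_id"])
            gts = "\t".join(gt_map.get(d, "./.") if np.isfinite(d) else "./." for d in dos)
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t{ref}\t{alt}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def read_gff3(path) -> list:
    """Read gene models from a GFF3 file (features of type ``gene``)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end, feat.strand or "+"))
    ids = [gm.gene_id for gm in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in GFF3")
    return genes


def write_gff3(path, genes) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            fh.write(f"{gm.chrom}\tpansvherit\tgene\t{gm.start}\t{gm.end}\t.\t{gm.strand}\t.\t"
                     f"ID={gm.gene_id}\n")


# ---------------------------------------------------------------------------
# trait-table I/O
# ---------------------------------------------------------------------------

def read_traits(path, trait_kind="agronomic") -> TraitTable:
    """Tab-delimited trait table: accessions in rows, header row of trait ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TraitTable(df.astype(float), trait_kind)


def write_traits(path, t: TraitTable) -> None:
    t.values.to_csv(path, sep="\t", index_label="accession")


# ---------------------------------------------------------------------------
# genotype preprocessing
# ---------------------------------------------------------------------------

def impute_and_filter(g: GenotypeMatrix, catalog: pd.DataFrame,
                      maf_min: float = 0.0, miss_max: float = 1.0):
    """Mean-impute missing dosages and drop low-MAF / high-missingness variants.

    Returns ``(GenotypeMatrix, catalog_subset)``.  MAF and missingness are
    computed on the non-missing entries before imputation; variants that are
    entirely missing are dropped with a warning.
    """
    if not (0.0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    X = g.dosages
    miss = np.mean(~np.isfinite(X), axis=0)
    all_missing = miss >= 1.0
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} variant(s) entirely missing; dropped")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(all_missing[None, :], 0.0, X), axis=0)
        f = mean / 2.0
        maf = np.minimum(f, 1.0 - f)
    keep = (~all_missing) & (miss <= miss_max) & (maf >= maf_min)
    Xk = X[:, keep].copy()
    mk = mean[keep]
    nan_r, nan_c = np.nonzero(~np.isfinite(Xk))
    Xk[nan_r, nan_c] = mk[nan_c]
    cat2 = catalog.loc[keep].reset_index(drop=True).copy()
    cat2["maf"] = maf[keep]
    return GenotypeMatrix(list(g.accessions), list(cat2["variant_id"]), Xk), cat2


# ---------------------------------------------------------------------------
# phenotype preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Rank-based transform of each column to standard-normal scores.

    Uses offsets (r - 0.5)/n with ties sharing average rank; NaN entries are
    preserved (ranks computed on the non-missing values only).
    """
    out = df.copy().astype(float)
    for col in out.columns:
        x = out[col].to_numpy()
        ok = np.isfinite(x)
        n = int(ok.sum())
        if n == 0:
            continue
        r = rankdata(x[ok], method="average")
        x[ok] = ndtri((r - 0.5) / n)
        out[col] = x
    return out


def _pc_residualize(M: np.ndarray, k: int) -> np.ndarray:
    """Residualize columns of M against the top-k PCs of M (plus intercept)."""
    if k <= 0:
        return M - M.mean(axis=0)
    n = M.shape[0]
    if k >= n:
        raise ValueError(f"k_factors={k} must be < n accessions ({n})")
    C = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(C, full_matrices=False)
    P = U[:, :k]  # orthonormal PC scores
    return C - P @ (P.T @ C)


def preprocess_expression(t: TraitTable, tpm_min: float = 0.5,
                          min_accessions: int = 100, k_factors: int = 4) -> TraitTable:
    """Expression (TPM) preprocessing.

    Keeps genes expressed (TPM > ``tpm_min``) in at least ``min_accessions``
    accessions, quantile-normalizes each gene to standard-normal scores,
    then residualizes against the top ``k_factors`` principal components of
    the expression matrix to absorb batch/confounder structure.  Residuals
    are re-scaled to unit variance.  Constant genes are dropped with a
    warning.  Missing TPM is treated as not expressed (0).
    """
    if t.trait_kind != "expression":
        raise ValueError("trait_kind must be 'expression'")
    df = t.values.fillna(0.0)
    expressed_in = (df > tpm_min).sum(axis=0)
    df = df.loc[:, expressed_in >= min_accessions]
    const = df.std(axis=0, ddof=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s) dropped")
        df = df.loc[:, ~const]
    qn = quantile_normalize(df)
    R = _pc_residualize(qn.to_numpy(), k_factors)
    sd = R.std(axis=0, ddof=0)
    keep = sd > 1e-6  # genes fully absorbed by the factors carry no signal
    R = R[:, keep] / sd[keep]
    out = pd.DataFrame(R, index=df.index, columns=df.columns[keep])
    return TraitTable(out, "expression")


def preprocess_metabolites(t: TraitTable, max_missing: int = 100,
                           replicate_groups: dict | None = None,
                           replicate_suffixes=("_r1", "_r2")) -> TraitTable:
    """Metabolite preprocessing: filter, average replicates, log3, normalize.

    Traits missing in >= ``max_missing`` accessions are dropped; replicate
    column pairs (given explicitly via ``replicate_groups`` as
    {name: [col, col]} or detected by suffix) are averaged; intensities are
    transformed with the ternary logarithm (log base 3) and quantile-
    normalized.  Remaining missing values are set to 0 (the normal-score
    mean) after normalization so retained traits are complete.
    """
    if t.trait_kind != "metabolite":
        raise ValueError("trait_kind must be 'metabolite'")
    df = t.values.copy()
    if replicate_groups is None:
        replicate_groups = {}
        bases = {}
        for col in df.columns:
            for suf in replicate_suffixes:
                if str(col).endswith(suf):
                    bases.setdefault(str(col)[: -len(suf)], []).append(col)
                    break
        replicate_groups = {b: cols for b, cols in bases.items() if len(cols) > 1}
    for name, cols in replicate_groups.items():
        df[name] = df[cols].mean(axis=1)
        df = df.drop(columns=[c for c in cols if c != name])
    n_missing = df.isna().sum(axis=0)
    df = df.loc[:, n_missing < max_missing]
    for col in df.columns:
        x = df[col]
        if (x[x.notna()] <= 0).any():
            raise ValueError(f"nonpositive intensity in trait {col!r}")
    df = np.log(df) / np.log(3.0)
    out = quantile_normalize(df).fillna(0.0)
    return TraitTable(out, "metabolite")
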