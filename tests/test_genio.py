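"""Data model, VCF/GFF3 round-trips, and phenotype preprocessing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pansvherit.genio import (GenotypeMatrix, GeneModel, TraitTable,
                              classify_alleles, folded_maf, impute_and_filter,
                              make_catalog, preprocess_expression,
                              preprocess_metabolites, quantile_normalize,
                              read_gff3, read_vcf, write_gff3, write_vcf)


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ref,alt,expected", [
    ("A", "T", ("SNP", 1)),                       # single-base substitution
    ("A", "ACCT", ("INDEL", 3)),                  # net 3 bp insertion
    ("ACCT", "A", ("INDEL", 3)),                  # net 3 bp deletion
    ("A", "A" + "C" * 50, ("INDEL", 50)),         # boundary: 50 bp stays small
    ("A", "A" + "C" * 51, ("SV", 51)),            # >50 bp is structural
])
def test_allele_length_rules(ref, alt, expected):
    cls, _, ln = classify_alleles(ref, alt)
    assert (cls, ln) == expected


def test_vcf_round_trip_classes_and_dosages(tmp_path):
    """write_vcf then read_vcf preserves dosages, classes and SV metadata,
    including a symbolic 2,628 bp deletion."""
    cat = make_catalog([
        dict(variant_id="snp1_100", chrom="chr01", pos=100, var_class="SNP",
             sv_type="NA", length=1, maf=0.25),
        dict(variant_id="ind1_200", chrom="chr01", pos=200, var_class="INDEL",
             sv_type="INS", length=3, maf=0.25),
        dict(variant_id="sv1_300", chrom="chr01", pos=300, var_class="SV",
             sv_type="DEL", length=2628, maf=0.25),
    ])
    dos = np.array([[0.0, 1.0, 2.0],
                    [2.0, np.nan, 0.0],
                    [1.0, 2.0, 2.0],
                    [0.0, 0.0, np.nan]])
    g = GenotypeMatrix([f"a{i}" for i in range(4)], list(cat["variant_id"]), dos)
    path = tmp_path / "toy.vcf"
    write_vcf(path, cat, g)
    cat2, g2 = read_vcf(path)
    assert list(cat2["var_class"]) == ["SNP", "INDEL", "SV"]
    assert cat2.loc[2, "sv_type"] == "DEL"
    assert cat2.loc[2, "length"] == 2628
    np.testing.assert_array_equal(np.isnan(g2.dosages), np.isnan(dos))
    np.testing.assert_allclose(np.nan_to_num(g2.dosages), np.nan_to_num(dos))


def test_read_vcf_rejects_multiallelic_and_missing_svlen(tmp_path):
    header = ("##fileformat=VCFv4.2\n"
              '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
              "##contig=<ID=chr01,length=1000>\n"
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n")
    multi = tmp_path / "multi.vcf"
    multi.write_text(header + "chr01\t10\tv1\tA\tT,G\t.\tPASS\t.\tGT\t0/1\n")
    with pytest.raises(ValueError, match="multiallelic"):
        read_vcf(multi)
    nosvlen = tmp_path / "nosvlen.vcf"
    nosvlen.write_text(header + "chr01\t10\tv1\tA\t<DEL>\t.\tPASS\tSVTYPE=DEL\tGT\t0/1\n")
    with pytest.raises(ValueError, match="SVLEN"):
        read_vcf(nosvlen)


def test_gff3_round_trip(tmp_path):
    genes = [GeneModel("g1", "chr01", 100, 900, "+"),
             GeneModel("g2", "chr02", 5000, 9000, "-")]
    path = tmp_path / "genes.gff3"
    write_gff3(path, genes)
    back = read_gff3(path)
    assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in back] == \
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes]


def test_catalog_invariants_enforced():
    with pytest.raises(ValueError, match="increasing"):
        make_catalog([
            dict(variant_id="a", chrom="c", pos=10, var_class="SNP", sv_type="NA",
                 length=1, maf=0.1),
            dict(variant_id="b", chrom="c", pos=10, var_class="SNP", sv_type="NA",
                 length=1, maf=0.1)])
    with pytest.raises(ValueError, match="SV with length"):
        make_catalog([dict(variant_id="a", chrom="c", pos=10, var_class="SV",
                           sv_type="DEL", length=20, maf=0.1)])


# ---------------------------------------------------------------------------
# imputation / filtering
# ---------------------------------------------------------------------------

def _toy_g(dosages):
    m = dosages.shape[1]
    cat = make_catalog([dict(variant_id=f"v{j}", chrom="c", pos=10 * (j + 1),
                             var_class="SNP", sv_type="NA", length=1, maf=0.1)
                        for j in range(m)])
    g = GenotypeMatrix([f"a{i}" for i in range(dosages.shape[0])],
                       list(cat["variant_id"]), dosages)
    return g, cat


def test_impute_mean_and_maf_filter():
    dos = np.array([[0.0, 2.0], [2.0, 0.0], [np.nan, 0.0]])
    g, cat = _toy_g(dos)
    g2, cat2 = impute_and_filter(g, cat)
    assert g2.col("v0")[2] == pytest.approx(1.0)  # mean of 0 and 2
    # singleton among 332 inbreds has maf ~0.003 < 0.01 and is dropped
    dos = np.zeros((332, 2))
    dos[0, 0] = 2.0
    dos[:166, 1] = 2.0
    g, cat = _toy_g(dos)
    g3, cat3 = impute_and_filter(g, cat, maf_min=0.01)
    assert list(cat3["variant_id"]) == ["v1"]


def test_filter_identity_on_complete_matrix():
    dos = np.array([[0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
    g, cat = _toy_g(dos)
    g2, cat2 = impute_and_filter(g, cat, miss_max=0.0)
    np.testing.assert_array_equal(g2.dosages, dos)
    assert list(cat2["variant_id"]) == list(cat["variant_id"])


def test_all_missing_variant_dropped_with_warning():
    dos = np.array([[np.nan, 2.0], [np.nan, 0.0], [np.nan, 2.0]])
    g, cat = _toy_g(dos)
    with pytest.warns(UserWarning, match="entirely missing"):
        g2, cat2 = impute_and_filter(g, cat)
    assert list(cat2["variant_id"]) == ["v1"]


# ---------------------------------------------------------------------------
# phenotype preprocessing
# ---------------------------------------------------------------------------

def test_normal_scores_three_values():
    """(5, 1, 9) -> (0, -0.967, 0.967): inverse-normal of (0.5, 1.5, 2.5)/3."""
    df = pd.DataFrame({"t": [5.0, 1.0, 9.0]})
    out = quantile_normalize(df)["t"].to_numpy()
    np.testing.assert_allclose(out, [0.0, -0.9674216, 0.9674216], atol=1e-6)


def test_quantile_normalized_close_to_standard_normal(rng):
    """KS distance of normal scores to N(0,1) below 0.05 for n >= 100."""
    x = rng.lognormal(0, 2, size=(150, 3))
    out = quantile_normalize(pd.DataFrame(x))
    for col in out.columns:
        d = stats.kstest(out[col], "norm").statistic
        assert d < 0.05


def test_expression_filters_and_residualization(rng):
    n = 332
    tpm = rng.lognormal(1, 1, size=(n, 20))
    tpm[:100, 0] = 5.0          # expressed in exactly 100 accessions -> kept
    tpm[100:, 0] = 0.0
    tpm[:99, 1] = 5.0           # expressed in 99 -> dropped
    tpm[99:, 1] = 0.0
    tpm[:, 2] = 3.0             # constant -> dropped with warning
    names = ["A", "B", "C"] + [f"g{j}" for j in range(17)]
    t = TraitTable(pd.DataFrame(tpm, index=[f"a{i}" for i in range(n)],
                                columns=names), "expression")
    with pytest.warns(UserWarning, match="constant"):
        out = preprocess_expression(t, k_factors=4)
    assert "B" not in out.trait_ids and "C" not in out.trait_ids
    assert "A" in out.trait_ids
    vals = out.values.to_numpy()
    assert np.all(np.isfinite(vals))
    np.testing.assert_allclose(vals.mean(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(vals.std(axis=0, ddof=0), 1.0, atol=1e-8)


def test_expression_k_factors_validates():
    t = TraitTable(pd.DataFrame(np.ones((5, 3)) + np.eye(5, 3), columns=list("abc")),
                   "expression")
    with pytest.raises(ValueError, match="k_factors"):
        preprocess_expression(t, min_accessions=1, k_factors=5)


def test_metabolite_log3_replicates_and_missing_filter(rng):
    n = 150
    base = rng.lognormal(2, 0.5, size=n)
    df = pd.DataFrame({
        "m1_r1": 4.0 * np.ones(n), "m1_r2": 8.0 * np.ones(n),  # replicate mean 6
        "m2": base,
        "m3": base.copy(),
    }, index=[f"a{i}" for i in range(n)])
    df.iloc[:100, df.columns.get_loc("m3")] = np.nan  # missing in 100 -> dropped
    t = TraitTable(df, "metabolite")
    out = preprocess_metabolites(t, max_missing=100)
    assert "m3" not in out.trait_ids
    assert "m1" in out.trait_ids and "m2" in out.trait_ids
    assert not out.values.isna().any().any()
    # log3(9) = 2 before normalization
    assert np.log(9.0) / np.log(3.0) == pytest.approx(2.0)


def test_metabolite_nonpositive_raises():
    df = pd.DataFrame({"bad": [1.0, -2.0, 3.0]})
    with pytest.raises(ValueError, match="bad"):
        preprocess_metabolites(TraitTable(df, "metabolite"), max_missing=3)


def test_folded_maf():
    assert folded_maf(np.array([2.0, 2.0, 2.0, 0.0])) == pytest.approx(0.25)
    assert folded_maf(np.array([0.0, 0.0])) == 0.0
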