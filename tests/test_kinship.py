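"""GRM construction, LD pruning, partitions and LD profiling."""

import numpy as np
import pandas as pd
import pytest

from pansvherit.genio import GenotypeMatrix, make_catalog
from pansvherit.kinship import (compute_grm, ld_prune, max_adjacent_r2,
                                partition_variants)


def brute_force_grm(X, alpha):
    """Independent double-loop oracle for the MAF-weighted GRM."""
    n, m = X.shape
    p = X.mean(axis=0) / 2.0
    f = np.minimum(p, 1 - p)
    s = (2 * f * (1 - f)) ** alpha
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for v in range(m):
                K[i, j] += s[v] * (X[i, v] - 2 * p[v]) * (X[j, v] - 2 * p[v])
    c = np.trace(K) / n
    return K / c


def _g_from(X, chrom="c", start=100, spacing=1000, var_class="SNP"):
    m = X.shape[1]
    cat = make_catalog([dict(variant_id=f"v{j}", chrom=chrom, pos=start + spacing * j,
                             var_class=var_class, sv_type="NA" if var_class != "SV" else "INS",
                             length=1 if var_class != "SV" else 60,
                             maf=min(X[:, j].mean() / 2, 1 - X[:, j].mean() / 2))
                        for j in range(m)])
    g = GenotypeMatrix([f"a{i}" for i in range(X.shape[0])], list(cat["variant_id"]), X)
    return g, cat


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("alpha", [-1.0, -0.5, 0.0])
def test_grm_matches_brute_force(rng, alpha):
    X = rng.integers(0, 2, size=(5, 8)).astype(float) * 2
    X[0, 0] = 2.0  # guard against monomorphic columns
    X[1, 0] = 0.0
    g, cat = _g_from(X)
    K = compute_grm(g, alpha=alpha).matrix
    np.testing.assert_allclose(K, brute_force_grm(X, alpha), atol=1e-12)


def test_grm_identical_accessions_off_diagonal():
    X = np.array([[0.0, 2, 0, 2], [0, 2, 0, 2], [2, 0, 2, 0]])
    g, cat = _g_from(X)
    K = compute_grm(g).matrix
    assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)


def test_grm_alpha_minus_one_is_standardized(rng):
    X = (rng.random((40, 12)) < 0.3).astype(float) * 2
    X[:2] = 2.0 - X[:2]
    g, cat = _g_from(X)
    K = compute_grm(g, alpha=-1.0).matrix
    # with alpha=-1 every variant contributes unit expected variance:
    # equivalent to the column-standardized GRM (up to trace normalization)
    p = X.mean(axis=0) / 2
    Z = (X - 2 * p) / np.sqrt(4 * 0.5 * p * (1 - p) * 2)  # s_j = 1/(2f(1-f))
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    K2 = Z @ Z.T
    K2 /= np.trace(K2) / K2.shape[0]
    np.testing.assert_allclose(K, K2, atol=1e-10)


def test_grm_monomorphic_excluded_with_warning():
    X = np.array([[0.0, 2], [0, 0], [0, 2]])
    g, cat = _g_from(X)
    with pytest.warns(UserWarning, match="monomorphic"):
        K = compute_grm(g)
    assert K.n_variants == 1


def test_grm_symmetry_psd_and_diag(default_pop):
    cat, g, _, _ = default_pop
    K = compute_grm(g)
    assert np.allclose(K.matrix, K.matrix.T, atol=1e-10)
    assert np.linalg.eigvalsh(K.matrix).min() > -1e-8
    assert 0.8 < np.diag(K.matrix).mean() < 1.2


def test_partition_grms_sum_to_whole(default_pop):
    """Scale-weighted sum of disjoint-partition GRMs equals the whole GRM."""
    cat, g, _, _ = default_pop
    parts = partition_variants(cat, kind="by_class")
    whole = compute_grm(g)
    acc = np.zeros_like(whole.matrix)
    tot = 0.0
    for ids in parts.values():
        Kp = compute_grm(g, ids)
        acc += Kp.matrix * Kp.scale
        tot += Kp.scale
    np.testing.assert_allclose(acc / tot, whole.matrix, atol=1e-10)
    assert tot == pytest.approx(whole.scale, rel=1e-10)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_prune_drops_one_of_duplicate_pair(rng):
    x = (rng.random(50) < 0.4).astype(float) * 2
    X = np.column_stack([x, x])
    g, cat = _g_from(X, spacing=1000)  # 1 kb apart
    kept = ld_prune(g, cat, mode="window_kb", window=100, r2_max=0.98)
    assert len(kept) == 1


def test_prune_keeps_independent_variants(rng):
    X = (rng.random((200, 20)) < 0.5).astype(float) * 2
    g, cat = _g_from(X)
    kept = ld_prune(g, cat, mode="window_count", window=50, step=5, r2_max=0.9)
    assert len(kept) == 20


@pytest.mark.parametrize("mode,window", [("window_count", 50), ("window_kb", 100)])
def test_prune_leaves_no_violating_pair_and_is_idempotent(default_pop, mode, window):
    """Exhaustive pairwise check of the pruned set, plus idempotence."""
    cat, g, _, _ = default_pop
    sub = cat[cat["chrom"] == "chr01"].reset_index(drop=True)
    kept = ld_prune(g, sub, mode=mode, window=window, step=5, r2_max=0.2)
    info = sub.set_index("variant_id")
    pos = info.loc[kept, "pos"].to_numpy()
    X = g.columns(kept)
    R = np.corrcoef(X, rowvar=False) ** 2
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            # sliding count-windows of width w advancing by step s guarantee
            # co-scanning of pairs up to w - s apart (the PLINK dialect)
            within = (j - i <= 50 - 5) if mode == "window_count" else \
                (pos[j] - pos[i] <= window * 1000)
            if within:
                assert R[i, j] <= 0.2 + 1e-12
    cat_kept = sub[sub["variant_id"].isin(kept)].reset_index(drop=True)
    again = ld_prune(g, cat_kept, mode=mode, window=window, step=5, r2_max=0.2)
    assert set(again) == set(kept)


def test_prune_empty_chromosome_ok(small_pop):
    cat, g, _, _ = small_pop
    empty = cat.iloc[0:0]
    assert ld_prune(g, empty, r2_max=0.2) == []


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def test_partitions_are_disjoint_and_cover(default_pop):
    cat, g, genes, _ = default_pop
    parts = partition_variants(cat, kind="by_class")
    all_ids = sum((list(v) for v in parts.values()), [])
    assert len(all_ids) == len(set(all_ids)) == len(cat)
    module = [gm.gene_id for gm in genes[:10]]
    mp = partition_variants(cat, genes, kind="module_proximal", module_genes=module)
    assert set(mp["module_proximal"]) | set(mp["rest"]) == set(cat["variant_id"])
    assert not (set(mp["module_proximal"]) & set(mp["rest"]))


def test_cis_trans_window_boundaries():
    from pansvherit.genio import GeneModel

    cat = make_catalog([
        dict(variant_id="sv_in", chrom="c", pos=100_000 - 49_999, var_class="SV",
             sv_type="DEL", length=100, maf=0.2),
        dict(variant_id="snp_out", chrom="c", pos=110_000 + 50_001, var_class="SNP",
             sv_type="NA", length=1, maf=0.2),
    ])
    gene = GeneModel("g", "c", 100_000, 110_000)
    parts = partition_variants(cat, [gene], kind="cis_trans", gene_id="g")
    assert parts["cis_SV"] == ["sv_in"]       # 49,999 bp upstream -> cis
    assert parts["trans_SNP"] == ["snp_out"]  # 50,001 bp downstream -> trans
    with pytest.raises(ValueError, match="unknown gene"):
        partition_variants(cat, [gene], kind="cis_trans", gene_id="nope")


# ---------------------------------------------------------------------------
# max adjacent R^2
# ---------------------------------------------------------------------------

def test_max_adjacent_r2_brute_force(small_pop):
    cat, g, _, _ = small_pop
    sub = cat[cat["chrom"] == "chr01"].reset_index(drop=True)
    table = max_adjacent_r2(g, sub).set_index("variant_id")
    info = sub.set_index("variant_id")
    svs = sub[sub["var_class"] == "SV"]["variant_id"].tolist()[:25]
    for sv in svs:
        pos = info.loc[sv, "pos"]
        x = g.col(sv)
        best = np.nan
        for _, row in sub[sub["var_class"] != "SV"].iterrows():
            if abs(row["pos"] - pos) <= 50_000:
                y = g.col(row["variant_id"])
                if x.std() > 0 and y.std() > 0:
                    r2 = np.corrcoef(x, y)[0, 1] ** 2
                    best = r2 if not np.isfinite(best) else max(best, r2)
        got = table.loc[sv, "max_r2"]
        if np.isfinite(best):
            assert got == pytest.approx(best, abs=1e-12)
        else:
            assert not np.isfinite(got)


def test_duplicated_sv_column_reaches_one(rng):
    x = (rng.random(60) < 0.4).astype(float) * 2
    X = np.column_stack([x, x])
    cat = make_catalog([
        dict(variant_id="snp", chrom="c", pos=1000, var_class="SNP", sv_type="NA",
             length=1, maf=0.3),
        dict(variant_id="sv", chrom="c", pos=2000, var_class="SV", sv_type="INS",
             length=80, maf=0.3)])
    g = GenotypeMatrix([f"a{i}" for i in range(60)], ["snp", "sv"], X)
    out = max_adjacent_r2(g, cat)
    assert out.set_index("variant_id").loc["sv", "max_r2"] == pytest.approx(1.0)
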