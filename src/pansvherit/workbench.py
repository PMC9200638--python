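"""Scenario orchestration: the four headline experiments, end to end.

Each scenario simulates a population with :mod:`pansvherit.synthpop`,
runs the relevant analysis stages, and returns a plain-dict report.  With
``outdir`` set, tables are written as TSV/JSON together with a manifest
(seeds, parameters, package version) sufficient to replay the run.  All
scenarios are deterministic under their seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import LocoMLM, bonferroni_threshold
from .coexpr import detect_modules, signed_adjacency, tom_similarity
from .genio import TraitTable
from .gsel import compare_marker_sets, mas_select
from .kinship import compute_grm, partition_variants
from .lassoml import cis_sv_scan, module_guided_trait_scan
from .synthpop import (SimConfig, TraitSpec, degrade_to_linear_callset,
                       simulate_expression, simulate_population, simulate_traits)
from .varcomp import (assign_h2_category, build_covariates, h2_partition_report,
                      reml_fit)

SCENARIOS = ("heritability_comparison", "allelic_het", "locus_het", "genomic_selection")


@dataclass
class ScenarioConfig:
    name: str
    sim: SimConfig = field(default_factory=SimConfig)
    params: dict = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _write_manifest(cfg: ScenarioConfig, extra=None):
    if cfg.outdir is None:
        return
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"scenario": cfg.name, "seed": cfg.seed, "sim": asdict(cfg.sim),
                "params": cfg.params, "version": __version__}
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _sub_seed(seed, k):
    return int((seed * 1000 + k) % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# 1. missing-heritability comparison (graph-like vs degraded callset)
# ---------------------------------------------------------------------------

def run_heritability_comparison(cfg: ScenarioConfig) -> dict:
    """Per-class composite REML on the full ("graph-like") callset vs a
    SNP+indel model on the 20%-SV-retention ("linear") callset.

    Reports mean h2 per model, the percent increase of the composite-model
    mean over the degraded SNP+indel mean, a Wilcoxon p, per-class shares
    and their nearest-anchor categories, and the per-trait direction
    indicator (composite-on-graph > SNP+indel-on-degraded).
    """
    p = {"n_traits": 12, "h2_by_class": {"SNP": 0.10, "INDEL": 0.04, "SV": 0.27}, **cfg.params}
    cat, g, genes, het = simulate_population(cfg.sim)
    cat_lin, g_lin = degrade_to_linear_callset(g, cat, cfg.sim.sv_retention_linear,
                                               seed=_sub_seed(cfg.seed, 1))
    specs = [TraitSpec(f"trait{t:02d}", "by_class", h2_by_class=p["h2_by_class"])
             for t in range(p["n_traits"])]
    traits, truth = simulate_traits(g, cat, specs, het, seed=_sub_seed(cfg.seed, 2))
    X = build_covariates(g, cat, k=4)
    parts = partition_variants(cat, kind="by_class")
    Ks = {c: compute_grm(g, parts[c], label=c) for c in ("SNP", "INDEL", "SV")}
    parts_lin = partition_variants(cat_lin, kind="by_class")
    Ks_lin = {c: compute_grm(g_lin, parts_lin[c], label=c) for c in ("SNP", "INDEL")}

    fits_graph, fits_lin, shares, cats = [], [], [], []
    for t in traits.trait_ids:
        y = traits.values[t].to_numpy()
        fg = reml_fit(y, X, [Ks["SNP"], Ks["INDEL"], Ks["SV"]],
                      labels=["SNP", "INDEL", "SV"])
        fl = reml_fit(y, X, [Ks_lin["SNP"], Ks_lin["INDEL"]], labels=["SNP", "INDEL"])
        fits_graph.append(fg)
        fits_lin.append(fl)
        sh = (fg.h2["SNP"], fg.h2["INDEL"], fg.h2["SV"])
        shares.append(sh)
        cats.append(assign_h2_category(sh))
    report = h2_partition_report({"composite_graph": fits_graph,
                                  "snp_indel_linear": fits_lin})
    direction = np.array([a.total_h2 > b.total_h2 for a, b in zip(fits_graph, fits_lin)])
    out = {"report": report, "shares": pd.DataFrame(shares, columns=["SNP", "INDEL", "SV"],
                                                    index=traits.trait_ids),
           "categories": cats, "direction_fraction": float(direction.mean()),
           "fits_graph": fits_graph, "fits_linear": fits_lin}
    _write_manifest(cfg, {"direction_fraction": out["direction_fraction"]})
    if cfg.outdir:
        out["report"]["summary"].to_csv(Path(cfg.outdir) / "h2_summary.tsv", sep="\t")
        out["shares"].to_csv(Path(cfg.outdir) / "h2_shares.tsv", sep="\t")
    return out


# ---------------------------------------------------------------------------
# 2. allelic heterogeneity: LASSO vs single-variant MLM
# ---------------------------------------------------------------------------

def run_allelic_het(cfg: ScenarioConfig) -> dict:
    """Count genes whose >= 2 planted causal cis-SVs are flagged by the
    multilocus LASSO vs recovered by the single-variant mixed-model top hit."""
    p = {"n_perm": 200, "h2_het": 0.30, **cfg.params}
    cat, g, genes, het = simulate_population(cfg.sim)
    gene_by_id = {gm.gene_id: gm for gm in genes}
    het_genes = sorted(het)
    specs = [TraitSpec(f"expr_{gid}", "allelic_het", gene_id=gid, h2_het=p["h2_het"])
             for gid in het_genes]
    traits, truth = simulate_traits(g, cat, specs, het, seed=_sub_seed(cfg.seed, 3))
    X = build_covariates(g, cat, k=4)
    scanner = LocoMLM(g, cat, covariates=X)
    thr_mlm = bonferroni_threshold(cat.shape[0])
    rows = []
    for k, gid in enumerate(het_genes):
        y = traits.values[f"expr_{gid}"].to_numpy()
        res = cis_sv_scan(gene_by_id[gid], g, cat, y, n_perm=p["n_perm"],
                          seed=_sub_seed(cfg.seed, 10 + k))
        lasso_hits = set(res.table.loc[res.table["selected"], "variant_id"])
        mlm = scanner.scan(y)
        sig = mlm[mlm["neglog10p"] >= thr_mlm]
        causal = set(truth.causal_ids[f"expr_{gid}"])
        cis = res.table["variant_id"].tolist()
        mlm_cis_hits = set(sig["variant_id"]) & set(cis)
        rows.append({"gene": gid, "n_causal": len(causal),
                     "lasso_flagged": res.allelic_het,
                     "lasso_causal_found": len(lasso_hits & causal),
                     "mlm_causal_found": len(mlm_cis_hits & causal),
                     "lambda_entry": res.table["lambda_entry"].max() if len(cis) else np.nan})
    table = pd.DataFrame(rows)
    out = {"table": table,
           "lasso_flag_rate": float(table["lasso_flagged"].mean()),
           "lasso_beats_mlm": int((table["lasso_causal_found"]
                                   > table["mlm_causal_found"]).sum())}
    _write_manifest(cfg, {"lasso_flag_rate": out["lasso_flag_rate"]})
    if cfg.outdir:
        table.to_csv(Path(cfg.outdir) / "allelic_het.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# 3. locus heterogeneity: module-guided trait scan
# ---------------------------------------------------------------------------

def run_locus_het(cfg: ScenarioConfig) -> dict:
    """Module expression -> co-expression detection -> module-guided LASSO
    scan of a metabolite-like trait -> MAS shortlist."""
    p = {"n_module_genes": 6, "n_causal_genes": 4, "n_perm": 200,
         "h2_module": 0.5, "n_background": 50, **cfg.params}
    cat, g, genes, het = simulate_population(cfg.sim)
    rng = np.random.default_rng(_sub_seed(cfg.seed, 4))
    # pick module genes that each have at least one cis-SV
    sv_pos = cat[cat["var_class"] == "SV"]
    mod_genes, gene_sv = [], {}
    for gm in genes:
        win = sv_pos[(sv_pos["chrom"] == gm.chrom) &
                     (sv_pos["pos"] >= gm.start - 50_000) &
                     (sv_pos["pos"] <= gm.end + 50_000)]
        ok = win[win["maf"] >= 0.05]
        if not ok.empty:
            mod_genes.append(gm)
            gene_sv[gm.gene_id] = ok.iloc[int(rng.integers(len(ok)))]["variant_id"]
        if len(mod_genes) >= p["n_module_genes"]:
            break
    causal = mod_genes[: p["n_causal_genes"]]
    expr, membership, latents = simulate_expression(
        g, cat, genes,
        [{"name": "module1", "genes": [(gm.gene_id, gene_sv[gm.gene_id])
                                       for gm in mod_genes]}],
        n_background=p["n_background"], seed=_sub_seed(cfg.seed, 5))
    spec = TraitSpec("metab", "module",
                     module_genes=[(gm.gene_id, gene_sv[gm.gene_id]) for gm in causal],
                     h2_module=p["h2_module"])
    traits, truth = simulate_traits(g, cat, [spec], het, seed=_sub_seed(cfg.seed, 6))
    y = traits.values["metab"].to_numpy()
    # co-expression modules on the simulated expression
    adj = signed_adjacency(expr.values, beta=6)
    tom = tom_similarity(adj)
    modules = detect_modules(tom, expr.values, min_size=4, merge_height=0.15)
    # the module containing most of the planted genes guides the scan
    planted = [gm.gene_id for gm in mod_genes]
    lab = modules.labels[planted].mode().iloc[0]
    scan_genes = [gm for gm in genes
                  if gm.gene_id in set(modules.labels[modules.labels == lab].index)]
    table = module_guided_trait_scan(y, scan_genes, g, cat, expr,
                                     n_perm=p["n_perm"], seed=_sub_seed(cfg.seed, 7))
    n_genes_assoc = table["gene"].nunique() if not table.empty else 0
    shortlist = table[table["wilcoxon_p"] < 0.05] if not table.empty else table
    out = {"table": table, "n_genes_associated": int(n_genes_assoc),
           "module_label": lab, "mas_shortlist": shortlist,
           "true_genes": [gm.gene_id for gm in causal]}
    _write_manifest(cfg, {"n_genes_associated": out["n_genes_associated"]})
    if cfg.outdir and not table.empty:
        table.to_csv(Path(cfg.outdir) / "locus_het.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# 4. genomic selection
# ---------------------------------------------------------------------------

def run_genomic_selection(cfg: ScenarioConfig) -> dict:
    """Marker-set comparison (SNP vs SV kinship) of GBLUP accuracy over a
    panel of SV-causal simulated traits, with paired Wilcoxon p."""
    p = {"n_traits": 10, "h2_by_class": {"SNP": 0.05, "INDEL": 0.0, "SV": 0.45},
         "folds": 5, "reps": 5, **cfg.params}
    cat, g, genes, het = simulate_population(cfg.sim)
    specs = [TraitSpec(f"trait{t:02d}", "by_class", h2_by_class=p["h2_by_class"],
                       n_causal_by_class={"SNP": 40, "INDEL": 0, "SV": 30})
             for t in range(p["n_traits"])]
    traits, truth = simulate_traits(g, cat, specs, het, seed=_sub_seed(cfg.seed, 8))
    parts = partition_variants(cat, kind="by_class")
    res = compare_marker_sets(traits.values, {"SNP": parts["SNP"], "SV": parts["SV"]},
                              g, folds=p["folds"], reps=p["reps"],
                              seed=_sub_seed(cfg.seed, 9))
    acc = res["accuracy"]
    out = {"accuracy": acc, "wilcoxon_p": res["wilcoxon_p"],
           "sv_minus_snp": float((acc["SV"] - acc["SNP"]).mean()),
           "sv_wins": int((acc["SV"] > acc["SNP"]).sum())}
    _write_manifest(cfg, {"sv_minus_snp": out["sv_minus_snp"]})
    if cfg.outdir:
        acc.to_csv(Path(cfg.outdir) / "gs_accuracy.tsv", sep="\t")
    return out


def run_scenario(cfg: ScenarioConfig) -> dict:
    return {"heritability_comparison": run_heritability_comparison,
            "allelic_het": run_allelic_het,
            "locus_het": run_locus_het,
            "genomic_selection": run_genomic_selection}[cfg.name](cfg)
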