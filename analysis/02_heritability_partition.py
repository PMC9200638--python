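#!/usr/bin/env python
"""Partitioned-heritability comparison: full callset vs degraded callset.

Runs the heritability_comparison scenario: traits with per-class targets
(SNP 0.10, indel 0.04, SV 0.27) are simulated; composite 3-kinship REML on
the full callset is compared with SNP+indel REML on the 20%-SV-retention
callset.  Writes results/heritability/{h2_summary,h2_shares}.tsv and the
run manifest.

Finding to look for: mean composite h2 exceeds the degraded-callset
SNP+indel h2 (the missing-heritability gap), SVs contribute the largest
share, and most traits fall in SV-dominated nearest-anchor categories.
"""

import sys
from pathlib import Path

from pansvherit.synthpop import SimConfig
from pansvherit.workbench import ScenarioConfig, run_scenario

OUT = Path(__file__).resolve().parent.parent / "results" / "heritability"


def main(seed: int = 1):
    cfg = ScenarioConfig("heritability_comparison", sim=SimConfig(seed=seed),
                         params={"n_traits": 12}, outdir=str(OUT), seed=seed)
    out = run_scenario(cfg)
    s = out["report"]["summary"]
    pct = out["report"]["percent_increase"][("composite_graph", "snp_indel_linear")]
    p = out["report"]["wilcoxon_p"][("composite_graph", "snp_indel_linear")]
    print(s.round(3))
    print(f"percent increase of composite over degraded SNP+indel: {pct}% "
          f"(Wilcoxon p = {p:.3g})")
    print(f"direction (composite > degraded) in "
          f"{100 * out['direction_fraction']:.0f}% of traits")
    print("category assignments:", out["categories"])


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
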