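#!/usr/bin/env python
"""Allelic heterogeneity: multilocus LASSO vs single-variant mixed model.

Runs the allelic_het scenario: expression-like traits driven by two low-MAF
cis-SVs (MAF pattern ~0.017/~0.032) within one gene's +/-50 kb window, on a
polygenic background.  Each gene is scanned with the cis-SV LASSO
(permutation p-values at the 1/m threshold) and genome-wide LOCO MLM.
Writes results/allelic_het/allelic_het.tsv.

Finding to look for: LASSO flags the two-SV architecture (>= 2 significant
cis-SVs) for most genes, while the single-variant scan rarely reaches both
causal SVs — the power argument for multilocus mapping at shared loci.
"""

import sys
from pathlib import Path

from pansvherit.synthpop import SimConfig
from pansvherit.workbench import ScenarioConfig, run_scenario

OUT = Path(__file__).resolve().parent.parent / "results" / "allelic_het"


def main(seed: int = 1):
    cfg = ScenarioConfig("allelic_het", sim=SimConfig(seed=seed),
                         params={"n_perm": 200}, outdir=str(OUT), seed=seed)
    out = run_scenario(cfg)
    print(out["table"].to_string(index=False))
    print(f"LASSO allelic-het flag rate: {out['lasso_flag_rate']:.0%}")
    print(f"genes where LASSO recovers more causal SVs than MLM: "
          f"{out['lasso_beats_mlm']}/{len(out['table'])}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
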