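"""Resistance and resilience of gene abundances, ratios and fluxes to drought.

Standardizes each variable to its site x vegetation mean, assembles matched
drought-control pairs, computes Orwin-Wardle RS/RL per pair, aggregates with
95% t-intervals per vegetation x warming group, and tests warmed vs ambient
by one-way ANOVA.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
shared = importlib.import_module("00_config")

import pandas as pd  # noqa: E402

from droughtflux import pipeline  # noqa: E402

cfg = shared.config()
report = pipeline.RunReport()
pipeline.stage_indices(cfg, report)

groups = pd.read_csv(f"{cfg.outdir}/rr_groups.csv")
print("group means by variable and kind (95% CI classification):")
summ = groups.groupby(["variable", "kind"]).agg(
    mean=("mean", "mean"), frac_ci_contains_1=("contains_1", "mean")
).round(3)
print(summ)
warm = pd.read_csv(f"{cfg.outdir}/rr_warming_anova.csv")
sig = warm[warm.p < 0.05]
print(f"\nwarmed vs ambient ANOVA: {len(sig)} of {len(warm)} contrasts significant at 0.05")
if len(sig):
    print(sig[["site", "vegetation_type", "variable", "kind", "F", "df1", "df2", "p"]]
          .round(4).to_string(index=False))
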