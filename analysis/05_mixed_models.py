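"""Mixed models: treatment effects on genes and fluxes; day-56 gene-GHG models.

Fits the full three-way fixed structure (timepoint x vegetation x warming x
drought) with pair-within-origin-treatment random intercepts, simplifies the
random structure by ML deletion tests, and partitions variance into marginal
and conditional R2. Then fits the day-56 single-gene GHG models.
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
pipeline.stage_models(cfg, report)

summary = pd.read_csv(f"{cfg.outdir}/model_summary.csv")
print("treatment models (random structure after deletion tests):")
print(summary[["response", "r2_marginal", "r2_conditional", "random_kept"]].round(3).to_string(index=False))

anova = pd.read_csv(f"{cfg.outdir}/model_anova.csv")
sig = anova[anova.p < 0.05]
print(f"\n{len(sig)} of {len(anova)} fixed-effect terms significant at 0.05; strongest:")
print(sig.nsmallest(6, "p")[["response", "term", "df_num", "df_den", "F", "p"]].round(4).to_string(index=False))

ghg = pd.read_csv(f"{cfg.outdir}/gene_ghg_models.csv")
print("\nday-56 single-gene GHG models:")
print(ghg[["ghg", "gene", "coef_log10_gene", "r2_marginal", "r2_conditional"]].round(3).to_string(index=False))
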