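"""Estimate CO2, CH4 and N2O fluxes from the headspace series.

OLS slope over the 0/10/20/30-minute samples, converted to
ug element g^-1 dry soil h^-1 by the ideal gas law; writes fluxes.csv and
summarizes recovery of the generator's true fluxes.
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
pipeline.stage_flux(cfg, report)

fluxes = pd.read_csv(f"{cfg.outdir}/fluxes.csv")
print("flux summary (ug element g^-1 h^-1):")
print(fluxes.groupby("species")["flux_ug_g_h"].describe()[["mean", "std", "min", "max"]].round(4))
neg = fluxes[(fluxes.species == "CH4") & (fluxes.flux_ug_g_h < 0)]
print(f"CH4 uptake (negative flux) in {len(neg)} of {int((fluxes.species == 'CH4').sum())} microcosms")
rec = report.recovery["flux"]
print(f"flux recovery: MAE {rec['mae']:.4f}, r {rec['corr']:.4f} over {rec['n']} series")
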