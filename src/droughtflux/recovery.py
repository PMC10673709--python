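"""Parameter-recovery studies: does the pipeline see what the generator put in?

These helpers run many small seeded simulations through the full measurement
chain (generator -> curve fit -> quantification -> ratios -> pairing ->
indices, or generator -> mixed model) and summarize how often the known
ground truth is recovered. They back both the test suite and the analysis
drivers.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from . import models, qpcr, resilience, synthetic

logger = logging.getLogger(__name__)


def _null_effect_config(drought_mult_pmoa: float, noise_sd: float, genes=("16S", "pmoA")) -> synthetic.EffectConfig:
    """All treatment effects off except a drought multiplier on pmoA."""
    return synthetic.EffectConfig(
        genes=genes,
        warming_mult={},
        drought_mult={"pmoA": drought_mult_pmoa},
        day56_mult={},
        vegetation_mult={},
        interactions={},
        unit_sd_log10=0.15,
        microcosm_sd_log10=noise_sd,
        cq_noise_sd=0.0,
    )


def rs_ci_calibration(
    n_runs: int = 200,
    drought_mult: float = 0.5,
    noise_sd: float = 0.1,
    n_pairs: int = 5,
    base_seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Fraction of seeded runs whose group resistance CI excludes / contains 1.

    One group of ``n_pairs`` matched pairs per run; resistance is computed on
    the pmoA:16S ratio through the full qPCR quantification chain, with
    biological noise ``noise_sd`` (log10 scale) per microcosm per gene.
    """
    cfg = _null_effect_config(drought_mult, noise_sd)
    site = synthetic.SiteConfig(
        site_id="sim", vegetation_types=("veg",), replicates_per_cell=n_pairs, pwp=9.17
    )
    design_full = synthetic.generate_design([site])
    design = design_full[design_full["warming"] == "ambient"].reset_index(drop=True)
    excludes = contains = 0
    for i in range(n_runs):
        rng = np.random.default_rng(base_seed + i)
        qpcr_df, calib_df, _ = synthetic.simulate_qpcr(design, cfg, rng)
        abund = qpcr.quantify_table(qpcr_df, calib_df, design)
        ratios = qpcr.compute_ratios(abund)
        pairs = resilience.build_pair_table(
            ratios[ratios["variable"] == "pmoA:16S"], design
        )
        rs = resilience.resistance(pairs["C0"].to_numpy(), pairs["P0"].to_numpy())
        summ = resilience.aggregate_group(rs, level=ci_level)
        if summ["contains_1"]:
            contains += 1
        else:
            excludes += 1
    return {
        "n_runs": n_runs,
        "frac_excludes_1": excludes / n_runs,
        "frac_contains_1": contains / n_runs,
    }


def variance_component_recovery(
    n_reps: int = 100,
    n_units: int = 40,
    n_per_unit: int = 5,
    var_unit: float = 1.0,
    var_resid: float = 1.0,
    base_seed: int = 0,
) -> dict:
    """Mean REML estimates of (unit, residual) variances over seeded replicates.

    Data are intercept-only with a unit random effect; the fit uses the
    package's mixed-model wrapper with a pair-level random intercept.
    """
    est_unit, est_resid = [], []
    spec = models.build_spec("y", ())
    for i in range(n_reps):
        rng = np.random.default_rng(base_seed + i)
        unit = np.repeat(np.arange(n_units), n_per_unit)
        y = (
            np.sqrt(var_unit) * rng.standard_normal(n_units)[unit]
            + np.sqrt(var_resid) * rng.standard_normal(len(unit))
        )
        df = pd.DataFrame({"y": y, "unit_id": unit.astype(str), "warming": "ambient"})
        fit = models.fit_lmm(spec, df, random=("pair",), reml=True)
        est_unit.append(fit.var_pair)
        est_resid.append(fit.var_resid)
    return {
        "n_reps": n_reps,
        "mean_var_unit": float(np.mean(est_unit)),
        "mean_var_resid": float(np.mean(est_resid)),
        "true_var_unit": var_unit,
        "true_var_resid": var_resid,
    }


def copy_number_recovery(results: dict, abundances: pd.DataFrame) -> dict:
    """Agreement between estimated and true gene copies for one simulation."""
    merged = abundances.merge(results["truth_copies"], on=["microcosm_id", "gene"])
    log_est = np.log10(merged["copies_per_g"])
    log_true = np.log10(merged["true_copies_per_g"])
    return {
        "n": len(merged),
        "log10_rmse": float(np.sqrt(np.mean((log_est - log_true) ** 2))),
        "log10_corr": float(np.corrcoef(log_est, log_true)[0, 1]),
    }


def flux_recovery(results: dict, fluxes: pd.DataFrame) -> dict:
    """Agreement between estimated and true fluxes for one simulation."""
    merged = fluxes.merge(results["truth_flux"], on=["microcosm_id", "species"])
    err = merged["flux_ug_g_h"] - merged["true_flux_ug_g_h"]
    return {
        "n": len(merged),
        "mae": float(np.abs(err).mean()),
        "corr": float(np.corrcoef(merged["flux_ug_g_h"], merged["true_flux_ug_g_h"])[0, 1]),
    }
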