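"""End-to-end orchestration: simulate -> quantify -> flux -> indices -> models.

Each stage reads its inputs from CSVs persisted by the previous stage and
writes its own outputs, so re-running a single stage from intermediates
reproduces the full-run result (stage idempotence), and a run manifest plus
seed determines every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models, qpcr, recovery, resilience, synthetic
from . import flux as fluxmod

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qpcr", "flux", "indices", "models")

GENE_VARIABLE_COLUMNS = {
    "16S": "abund_16S",
    "ITS": "abund_ITS",
    "pmoA:16S": "ratio_pmoA",
    "nosZII:16S": "ratio_nosZII",
    "acdS:16S": "ratio_acdS",
}


@dataclass
class RunConfig:
    site_configs: list = field(default_factory=synthetic.default_sites)
    effect: synthetic.EffectConfig = field(default_factory=synthetic.EffectConfig)
    seed: int = 0
    cv_threshold: float = 0.2
    r2_threshold: float = 0.9
    ci_level: float = 0.95
    outdir: str = "results/run"

    def __post_init__(self):
        if not (0 < self.ci_level < 1):
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.cv_threshold < 0 or not (0 <= self.r2_threshold <= 1):
            raise ValueError("invalid QC thresholds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sites = [synthetic.SiteConfig(**{**s, "vegetation_types": tuple(s["vegetation_types"])})
                 for s in raw.pop("site_configs", [])] or synthetic.default_sites()
        eff_raw = raw.pop("effect", None)
        if eff_raw is not None:
            if "interactions" in eff_raw:
                eff_raw["interactions"] = {
                    g: [(c, m) for c, m in pairs] for g, pairs in eff_raw["interactions"].items()
                }
            if "genes" in eff_raw:
                eff_raw["genes"] = tuple(eff_raw["genes"])
            effect = synthetic.EffectConfig(**eff_raw)
        else:
            effect = synthetic.EffectConfig()
        return cls(site_configs=sites, effect=effect, **raw)

    def to_dict(self) -> dict:
        return {
            "site_configs": [asdict(s) for s in self.site_configs],
            "effect": synthetic.effect_config_to_dict(self.effect),
            "seed": self.seed,
            "cv_threshold": self.cv_threshold,
            "r2_threshold": self.r2_threshold,
            "ci_level": self.ci_level,
            "outdir": str(self.outdir),
        }


@dataclass
class RunReport:
    stages: list = field(default_factory=list)
    qc: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # name -> sha256

    def to_dict(self) -> dict:
        return asdict(self)


def _write(df: pd.DataFrame, outdir: Path, name: str, files: dict) -> None:
    path = outdir / name
    df.to_csv(path, index=False)
    files[name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _read(outdir: Path, name: str) -> pd.DataFrame:
    return pd.read_csv(outdir / name)


def stage_simulate(config: RunConfig, report: RunReport) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = synthetic.simulate_experiment(config.site_configs, config.effect, seed=config.seed)
    for name, df in sim.items():
        _write(df, outdir, f"{name}.csv", report.files)
    n_units = sim["design"]["unit_id"].nunique()
    report.stages.append(
        {"stage": "simulate", "status": "ok", "n_units": int(n_units),
         "n_microcosms": int(len(sim["design"])), "n_qpcr_rows": int(len(sim["qpcr"])),
         "n_gas_rows": int(len(sim["headspace"]))}
    )


def stage_qpcr(config: RunConfig, report: RunReport) -> None:
    outdir = Path(config.outdir)
    design = _read(outdir, "design.csv")
    abund = qpcr.quantify_table(
        _read(outdir, "qpcr.csv"), _read(outdir, "calibration.csv"), design,
        cv_threshold=config.cv_threshold,
    )
    ratios = qpcr.compute_ratios(abund)
    _write(abund, outdir, "abundances.csv", report.files)
    _write(ratios, outdir, "ratios.csv", report.files)
    report.qc["qpcr_flagged"] = int((abund["qc_flag"] != "").sum())
    report.stages.append(
        {"stage": "qpcr", "status": "ok", "n_in": int(len(_read(outdir, "qpcr.csv"))),
         "n_abundances": int(len(abund)), "n_ratio_rows": int(len(ratios))}
    )
    truth = outdir / "truth_copies.csv"
    if truth.exists():
        report.recovery["copies"] = recovery.copy_number_recovery(
            {"truth_copies": pd.read_csv(truth)}, abund
        )


def stage_flux(config: RunConfig, report: RunReport) -> None:
    outdir = Path(config.outdir)
    design = _read(outdir, "design.csv")
    headspace = _read(outdir, "headspace.csv")
    fluxes = fluxmod.estimate_fluxes(headspace, design, r2_threshold=config.r2_threshold)
    fluxes["qc_flag"] = fluxes["qc_flag"].fillna("")
    _write(fluxes, outdir, "fluxes.csv", report.files)
    report.qc["flux_flagged"] = int((fluxes["qc_flag"] != "").sum())
    report.stages.append(
        {"stage": "flux", "status": "ok", "n_in": int(len(headspace)), "n_fluxes": int(len(fluxes))}
    )
    truth = outdir / "truth_flux.csv"
    if truth.exists():
        report.recovery["flux"] = recovery.flux_recovery(
            {"truth_flux": pd.read_csv(truth)}, fluxes
        )


def _measures_long(outdir: Path) -> pd.DataFrame:
    """Gene variables (abundances + ratios) and fluxes as one long table."""
    ratios = _read(outdir, "ratios.csv")
    fluxes = _read(outdir, "fluxes.csv")
    flux_long = fluxes.rename(columns={"flux_ug_g_h": "value"})
    flux_long["variable"] = "flux_" + flux_long["species"]
    return pd.concat(
        [ratios[["microcosm_id", "variable", "value"]],
         flux_long[["microcosm_id", "variable", "value"]]],
        ignore_index=True,
    )


def stage_indices(config: RunConfig, report: RunReport) -> None:
    outdir = Path(config.outdir)
    design = _read(outdir, "design.csv")
    measures = _measures_long(outdir)
    gene_vars = measures["variable"].isin(GENE_VARIABLE_COLUMNS)
    standardized = pd.concat(
        [resilience.standardize_table(measures[gene_vars], design), measures[~gene_vars]],
        ignore_index=True,
    )
    pairs = resilience.build_pair_table(standardized, design)
    indices = resilience.compute_indices(pairs)
    groups = resilience.aggregate_groups(indices, level=config.ci_level)
    warming = resilience.compare_warming_table(indices)
    _write(pairs, outdir, "rr_pairs.csv", report.files)
    _write(indices, outdir, "rr_indices.csv", report.files)
    _write(groups, outdir, "rr_groups.csv", report.files)
    _write(warming, outdir, "rr_warming_anova.csv", report.files)
    report.stages.append(
        {"stage": "indices", "status": "ok", "n_pairs": int(len(pairs)),
         "n_groups": int(len(groups))}
    )
    rs_pmoa = groups[(groups["variable"] == "pmoA:16S") & (groups["kind"] == "resistance")]
    if len(rs_pmoa):
        report.recovery["rs_pmoa_ratio_group_mean"] = float(rs_pmoa["mean"].mean())


def build_analysis_table(outdir: Path) -> pd.DataFrame:
    """Wide per-microcosm table: design + gene variables + fluxes."""
    design = _read(outdir, "design.csv")
    measures = _measures_long(outdir)
    measures = measures.copy()
    measures["column"] = measures["variable"].map(
        lambda v: GENE_VARIABLE_COLUMNS.get(v, v)
    )
    wide = measures.pivot(index="microcosm_id", columns="column", values="value").reset_index()
    return design.merge(wide, on="microcosm_id", validate="one_to_one")


def stage_models(config: RunConfig, report: RunReport) -> None:
    outdir = Path(config.outdir)
    data = build_analysis_table(outdir)
    _write(data, outdir, "analysis.csv", report.files)
    data = data.copy()
    responses = {}
    for col in GENE_VARIABLE_COLUMNS.values():
        logcol = f"log10_{col}"
        vals = data[col].to_numpy(dtype=float)
        data[logcol] = np.where(vals > 0, np.log10(np.where(vals > 0, vals, 1.0)), np.nan)
        responses[logcol] = col
    for col in resilience.FLUX_VARIABLES:
        responses[col] = col

    summary_rows, anova_rows = [], []
    for resp in responses:
        spec = models.build_spec(
            resp, ("harvest_day_f", "vegetation_type", "warming", "drought"), data=_with_day_factor(data)
        )
        fit, record = models.select_random_structure(spec, _with_day_factor(data))
        r2m, r2c = models.r2_nakagawa(fit)
        summary_rows.append(
            {"response": resp, "r2_marginal": r2m, "r2_conditional": r2c,
             "llf": fit.llf, "var_group": fit.var_group, "var_pair": fit.var_pair,
             "var_resid": fit.var_resid, **record}
        )
        an = fit.anova.copy()
        an.insert(0, "response", resp)
        anova_rows.append(an)
    _write(pd.DataFrame(summary_rows), outdir, "model_summary.csv", report.files)
    _write(pd.concat(anova_rows, ignore_index=True), outdir, "model_anova.csv", report.files)

    day56 = data[data["harvest_day"] == 56].reset_index(drop=True)
    ghg_rows = []
    for ghg in resilience.FLUX_VARIABLES:
        fits = models.fit_gene_ghg_models(day56, ghg)
        for gene, (fit, record) in fits.items():
            r2m, r2c = models.r2_nakagawa(fit)
            cov_term = f"log10_{gene}"
            coef = fit.params.get(cov_term, np.nan)
            ghg_rows.append(
                {"ghg": ghg, "gene": gene, "coef_log10_gene": coef,
                 "r2_marginal": r2m, "r2_conditional": r2c, **record}
            )
    _write(pd.DataFrame(ghg_rows), outdir, "gene_ghg_models.csv", report.files)
    report.stages.append(
        {"stage": "models", "status": "ok", "n_models": len(summary_rows),
         "n_gene_ghg_models": len(ghg_rows)}
    )


def _with_day_factor(data: pd.DataFrame) -> pd.DataFrame:
    out = data.copy()
    out["harvest_day_f"] = out["harvest_day"].map(lambda d: f"d{d}")
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage in order; write manifest and machine-readable report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    report = RunReport()
    stage_funcs = {
        "simulate": stage_simulate, "qpcr": stage_qpcr, "flux": stage_flux,
        "indices": stage_indices, "models": stage_models,
    }
    for name in STAGES:
        try:
            stage_funcs[name](config, report)
        except Exception:
            logger.exception("stage %r failed", name)
            report.stages.append({"stage": name, "status": "failed"})
            (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
            raise
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report


REQUIRED_COLUMNS = {
    "design": ["microcosm_id", "unit_id", "site", "vegetation_type", "warming", "replicate",
               "drought", "harvest_day", "soil_dry_mass_g", "headspace_volume_l",
               "incubation_temp_c", "whc_target_pct", "pwp_pct"],
    "qpcr": ["microcosm_id", "gene", "rep", "cq", "template_ng"],
    "calibration": ["gene", "log10_copies", "cq"],
    "headspace": ["microcosm_id", "species", "minutes", "concentration_ppm"],
}


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(tables: dict[str, pd.DataFrame]) -> ValidationReport:
    """Schema, uniqueness, pairing and time-grid checks with row diagnostics."""
    rep = ValidationReport()
    for name, cols in REQUIRED_COLUMNS.items():
        if name not in tables:
            rep.violations.append({"table": name, "error": "missing table"})
            continue
        missing = [c for c in cols if c not in tables[name].columns]
        if missing:
            rep.violations.append({"table": name, "error": f"missing columns {missing}"})
    if not rep.ok:
        return rep

    design = tables["design"]
    dup = design["microcosm_id"][design["microcosm_id"].duplicated()]
    if len(dup):
        rep.violations.append({"table": "design", "error": f"duplicate microcosm_id: {list(dup)}"})
    per_unit = design.groupby("unit_id").size()
    bad_units = per_unit[per_unit != 4]
    if len(bad_units):
        rep.violations.append(
            {"table": "design", "error": f"units without exactly 4 microcosms: {dict(bad_units)}"}
        )
    # pairing: every drought arm needs a same-unit control at the same day
    key = design.set_index(["unit_id", "drought", "harvest_day"]).index
    for _, row in design[design["drought"] == "drought"].iterrows():
        if (row["unit_id"], "control", row["harvest_day"]) not in key:
            rep.violations.append(
                {"table": "design", "row": row["microcosm_id"], "error": "unpaired drought microcosm"}
            )
    # gas time grid
    if "headspace" in tables:
        for (mid, sp), grp in tables["headspace"].groupby(["microcosm_id", "species"]):
            n = grp["minutes"].nunique()
            if n < 3:
                rep.violations.append(
                    {"table": "headspace", "row": f"{mid}/{sp}", "error": f"only {n} time points (<3)"}
                )
            elif n < 4:
                rep.warnings.append(
                    {"table": "headspace", "row": f"{mid}/{sp}", "warning": "3-point series (minute missing)"}
                )
    return rep
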