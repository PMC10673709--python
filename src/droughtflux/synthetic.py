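"""Synthetic factorial drought-incubation experiment with known ground truth.

Emulates a two-site laboratory incubation of warming-legacy soils: an
Oro-Arctic site (three vegetation types x warmed/ambient x five replicates
= 30 field samples) and an alpine site (one vegetation type x warmed/ambient
x nine replicates = 18 samples). Each field sample is split into four
microcosms — a matched drought/control pair destructively harvested at each
of day 0 (end of a five-week drought at the permanent wilting point) and
day 56 (after rewetting to 60% water-holding capacity).

Gene copy numbers are lognormal with multiplicative treatment effects
(abundances are strictly positive and analyzed as ratios, matching standard
qPCR error structure); observed Cq values follow the per-gene standard curve
plus Gaussian cycle noise. Headspace gas accumulation is linear in time; the
generator draws a true flux per microcosm and inverts the ideal-gas
conversion so the configured flux is the exact ground truth. Every draw
comes from a single seeded RNG stream, so one seed + config determines every
output byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import flux as fluxmod
from .qpcr import GENES

logger = logging.getLogger(__name__)

WARMING_LEVELS = ("ambient", "warmed")
DROUGHT_LEVELS = ("control", "drought")
HARVEST_DAYS = (0, 56)
GAS_MINUTES = (0.0, 10.0, 20.0, 30.0)
GAS_SPECIES = ("CO2", "CH4", "N2O")


@dataclass
class SiteConfig:
    """One field site feeding the incubation.

    ``pwp`` is the gravimetric moisture (%) at the permanent wilting point —
    the drought target; ``whc_target`` the gravimetric moisture (%) maintained
    in controls (60% of water-holding capacity in the emulated design).
    """

    site_id: str
    vegetation_types: tuple[str, ...]
    replicates_per_cell: int
    pwp: float
    whc_target: float = 60.0
    incubation_temp_c: float = 9.0
    soil_dry_mass_g: float = 10.0
    headspace_volume_l: float = 0.025
    pressure_kpa: float = 101.325
    dna_yield_ng: float = 500.0

    def __post_init__(self):
        if self.replicates_per_cell < 0:
            raise ValueError("replicates_per_cell must be >= 0")
        if not (0 < self.pwp < self.whc_target <= 100):
            raise ValueError(
                f"need 0 < pwp < whc_target <= 100, got pwp={self.pwp}, whc={self.whc_target}"
            )


def oro_arctic_site() -> SiteConfig:
    """Oro-Arctic default: 3 vegetation types x 5 replicates, PWP 9.17%."""
    return SiteConfig(
        site_id="oro_arctic",
        vegetation_types=("wet_meadow", "dry_heath", "tussock_tundra"),
        replicates_per_cell=5,
        pwp=9.17,
    )


def alpine_site() -> SiteConfig:
    """Alpine default: 1 vegetation type x 9 replicates, PWP 6.93%."""
    return SiteConfig(
        site_id="alpine",
        vegetation_types=("alpine",),
        replicates_per_cell=9,
        pwp=6.93,
    )


def default_sites() -> list[SiteConfig]:
    return [oro_arctic_site(), alpine_site()]


@dataclass
class EffectConfig:
    """Ground-truth effect structure for the simulated measurements.

    Gene copies (per g dry soil) are lognormal around ``baseline_copies`` with
    strictly positive multiplicative effects; noise standard deviations are on
    the log10 scale, the natural scale for qPCR. Gas fluxes are additive in
    ug element g^-1 h^-1 because CH4 uptake makes sign changes meaningful.
    ``interactions`` maps gene -> list of (condition dict, multiplier), e.g.
    ``{"pmoA": [({"drought": "drought", "harvest_day": 56}, 1.2)]}``.
    """

    genes: tuple[str, ...] = GENES
    baseline_copies: dict = field(
        default_factory=lambda: {
            "16S": 1e9, "ITS": 1e8, "pmoA": 1e6, "nosZII": 1e6, "acdS": 1e5,
        }
    )
    warming_mult: dict = field(
        default_factory=lambda: {"16S": 1.1, "ITS": 1.2, "pmoA": 1.1, "nosZII": 1.1, "acdS": 1.2}
    )
    drought_mult: dict = field(
        default_factory=lambda: {"16S": 0.9, "ITS": 1.0, "pmoA": 1.4, "nosZII": 1.0, "acdS": 1.3}
    )
    day56_mult: dict = field(
        default_factory=lambda: {"16S": 2.0, "ITS": 1.3, "pmoA": 1.2, "nosZII": 1.2, "acdS": 1.2}
    )
    vegetation_mult: dict = field(
        default_factory=lambda: {
            "16S": {"wet_meadow": 2.0, "dry_heath": 1.4, "tussock_tundra": 1.0, "alpine": 0.6},
            "nosZII": {"alpine": 2.0},
        }
    )
    interactions: dict = field(
        default_factory=lambda: {
            "pmoA": [({"drought": "drought", "harvest_day": 56}, 1.2)],
            "acdS": [({"drought": "drought", "harvest_day": 56}, 1.15)],
        }
    )
    unit_sd_log10: float = 0.15  # between field samples (shared by the 4 microcosms)
    microcosm_sd_log10: float = 0.1  # residual biological noise
    cq_noise_sd: float = 0.15  # cycles, per technical replicate
    curve_slope: dict = field(
        default_factory=lambda: {
            "16S": -3.36, "ITS": -3.45, "pmoA": -3.50, "nosZII": -3.40, "acdS": -3.32,
        }
    )
    curve_intercept: dict = field(
        default_factory=lambda: {
            "16S": 38.0, "ITS": 39.0, "pmoA": 40.0, "nosZII": 39.5, "acdS": 38.5,
        }
    )
    template_ng: dict = field(default_factory=lambda: {"pmoA": 4.0})
    template_ng_default: float = 2.0
    # --- headspace gas structure (ug element g^-1 dry soil h^-1) ---
    flux_base: dict = field(default_factory=lambda: {"CO2": 0.5, "CH4": -0.002, "N2O": 0.001})
    flux_warming_add: dict = field(default_factory=lambda: {"CO2": 0.05, "CH4": 0.001, "N2O": 0.0})
    flux_drought_add: dict = field(
        default_factory=lambda: {"CO2": -0.1, "CH4": 0.0005, "N2O": 0.0002}
    )
    flux_day56_add: dict = field(default_factory=lambda: {"CO2": 0.3, "CH4": 0.001, "N2O": 0.0005})
    flux_vegetation_add: dict = field(
        default_factory=lambda: {
            "CO2": {"dry_heath": 0.2},
            "CH4": {"wet_meadow": 0.006},
        }
    )
    flux_sd: dict = field(default_factory=lambda: {"CO2": 0.08, "CH4": 0.0008, "N2O": 0.0003})
    conc_noise_ppm: dict = field(default_factory=lambda: {"CO2": 2.0, "CH4": 0.01, "N2O": 0.005})
    ambient_ppm: dict = field(default_factory=lambda: {"CO2": 420.0, "CH4": 1.9, "N2O": 0.33})
    seed: int = 0

    def __post_init__(self):
        for gene, b in self.baseline_copies.items():
            if b <= 0:
                raise ValueError(f"baseline copies for {gene} must be positive, got {b}")
        for d in (self.warming_mult, self.drought_mult, self.day56_mult):
            for gene, m in d.items():
                if m <= 0:
                    raise ValueError(f"multiplicative effect for {gene} must be positive, got {m}")
        for sd in (self.unit_sd_log10, self.microcosm_sd_log10, self.cq_noise_sd):
            if sd < 0:
                raise ValueError(f"noise sd must be >= 0, got {sd}")

    def template_for(self, gene: str) -> float:
        return self.template_ng.get(gene, self.template_ng_default)

    def true_multiplier(self, gene: str, vegetation: str, warming: str, drought: str, day: int) -> float:
        m = 1.0
        if warming == "warmed":
            m *= self.warming_mult.get(gene, 1.0)
        if drought == "drought":
            m *= self.drought_mult.get(gene, 1.0)
        if day == 56:
            m *= self.day56_mult.get(gene, 1.0)
        m *= self.vegetation_mult.get(gene, {}).get(vegetation, 1.0)
        row = {"vegetation_type": vegetation, "warming": warming, "drought": drought, "harvest_day": day}
        for cond, mult in self.interactions.get(gene, []):
            if all(row[k] == v for k, v in cond.items()):
                m *= mult
        return m

    def true_flux_mean(self, species: str, vegetation: str, warming: str, drought: str, day: int) -> float:
        f = self.flux_base.get(species, 0.0)
        if warming == "warmed":
            f += self.flux_warming_add.get(species, 0.0)
        if drought == "drought":
            f += self.flux_drought_add.get(species, 0.0)
        if day == 56:
            f += self.flux_day56_add.get(species, 0.0)
        f += self.flux_vegetation_add.get(species, {}).get(vegetation, 0.0)
        return f


def generate_design(site_configs: list[SiteConfig]) -> pd.DataFrame:
    """Deterministic factorial design table, one row per microcosm.

    One experimental unit per site x vegetation x warming x replicate; each
    unit split into four microcosms (control/drought x harvest day 0/56).
    """
    ids = [s.site_id for s in site_configs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate site_id in configs: {ids}")
    rows = []
    for site in site_configs:
        for veg in site.vegetation_types:
            for warming in WARMING_LEVELS:
                for rep in range(1, site.replicates_per_cell + 1):
                    unit_id = f"{site.site_id}-{veg}-{warming}-r{rep}"
                    for drought in DROUGHT_LEVELS:
                        for day in HARVEST_DAYS:
                            rows.append(
                                {
                                    "microcosm_id": f"{unit_id}-{drought}-d{day}",
                                    "unit_id": unit_id,
                                    "site": site.site_id,
                                    "vegetation_type": veg,
                                    "warming": warming,
                                    "replicate": rep,
                                    "drought": drought,
                                    "harvest_day": day,
                                    "soil_dry_mass_g": site.soil_dry_mass_g,
                                    "headspace_volume_l": site.headspace_volume_l,
                                    "pressure_kpa": site.pressure_kpa,
                                    "incubation_temp_c": site.incubation_temp_c,
                                    "whc_target_pct": site.whc_target,
                                    "pwp_pct": site.pwp,
                                    "dna_yield_ng": site.dna_yield_ng,
                                }
                            )
    design = pd.DataFrame(
        rows,
        columns=[
            "microcosm_id", "unit_id", "site", "vegetation_type", "warming", "replicate",
            "drought", "harvest_day", "soil_dry_mass_g", "headspace_volume_l", "pressure_kpa",
            "incubation_temp_c", "whc_target_pct", "pwp_pct", "dna_yield_ng",
        ],
    )
    if len(design) and design["microcosm_id"].duplicated().any():
        raise ValueError("duplicate microcosm ids in design")
    return design


@dataclass
class MoistureSeries:
    """Daily gravimetric moisture trajectory for one microcosm."""

    days: np.ndarray
    moisture_pct: np.ndarray
    commencement_day: int | None  # first day at/below PWP (drought arms)
    flagged: bool = False  # PWP >= starting moisture: drought trivially satisfied


def simulate_moisture_series(
    microcosm: pd.Series,
    site: SiteConfig,
    drydown_rate: float = 1.5,
    n_days: int | None = None,
) -> MoistureSeries:
    """Deterministic moisture schedule: dry down, hold at PWP 35 d, rewet.

    Controls stay at the WHC target throughout. Drought arms lose
    ``drydown_rate`` %-points per day until the PWP, are held there for the
    five-week drought, and (day-56 arms) are restored to the WHC target after
    rewetting.
    """
    if drydown_rate <= 0:
        raise ValueError("drydown_rate must be positive")
    start = site.whc_target
    if microcosm["drought"] == "control":
        total = n_days if n_days is not None else 56
        days = np.arange(total + 1)
        return MoistureSeries(days, np.full(len(days), start, dtype=float), None)
    if site.pwp >= start:
        total = n_days if n_days is not None else 56
        days = np.arange(total + 1)
        logger.warning("PWP >= starting moisture for %s; drought trivially satisfied", microcosm["microcosm_id"])
        return MoistureSeries(days, np.full(len(days), site.pwp, dtype=float), 0, flagged=True)
    commence = int(np.ceil((start - site.pwp) / drydown_rate))
    drought_end = commence + 35  # five-week drought, harvested as "day 0"
    total = n_days if n_days is not None else (drought_end + 56 if microcosm["harvest_day"] == 56 else drought_end)
    days = np.arange(total + 1)
    m = np.maximum(start - drydown_rate * days, site.pwp)
    m[days > drought_end] = start if microcosm["harvest_day"] == 56 else site.pwp
    # held exactly at PWP between commencement and drought end
    m[(days >= commence) & (days <= drought_end)] = site.pwp
    return MoistureSeries(days, m, commence)


def simulate_qpcr(
    design: pd.DataFrame,
    cfg: EffectConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate plate Cq values, calibration points, and true copy numbers.

    Returns (qpcr, calibration, truth). True copies per microcosm are
    lognormal: baseline x treatment multipliers x 10^N(0, unit_sd) shared
    across a unit's four microcosms x 10^N(0, microcosm_sd). Two technical
    replicates per sample-gene; calibration points span 10^4..10^9 copies
    exactly on the configured curve.
    """
    units = design["unit_id"].drop_duplicates().tolist()
    qpcr_rows, truth_rows = [], []
    for gene in cfg.genes:
        slope = cfg.curve_slope[gene]
        intercept = cfg.curve_intercept[gene]
        template = cfg.template_for(gene)
        unit_eff = {u: rng.normal(0.0, cfg.unit_sd_log10) for u in units}
        for _, row in design.iterrows():
            mult = cfg.true_multiplier(
                gene, row["vegetation_type"], row["warming"], row["drought"], row["harvest_day"]
            )
            log10_copies = (
                np.log10(cfg.baseline_copies[gene] * mult)
                + unit_eff[row["unit_id"]]
                + rng.normal(0.0, cfg.microcosm_sd_log10)
            )
            true_per_g = 10.0**log10_copies
            truth_rows.append(
                {"microcosm_id": row["microcosm_id"], "gene": gene, "true_copies_per_g": true_per_g}
            )
            # invert the quantification scaling to get copies in the reaction
            copies_rxn = true_per_g * row["soil_dry_mass_g"] * template / row["dna_yield_ng"]
            true_cq = intercept + slope * np.log10(copies_rxn)
            for rep in (1, 2):
                qpcr_rows.append(
                    {
                        "microcosm_id": row["microcosm_id"],
                        "gene": gene,
                        "rep": rep,
                        "cq": true_cq + rng.normal(0.0, cfg.cq_noise_sd),
                        "template_ng": template,
                    }
                )
    calib_rows = [
        {
            "gene": gene,
            "log10_copies": float(lc),
            "cq": cfg.curve_intercept[gene] + cfg.curve_slope[gene] * lc,
        }
        for gene in cfg.genes
        for lc in range(4, 10)
    ]
    return pd.DataFrame(qpcr_rows), pd.DataFrame(calib_rows), pd.DataFrame(truth_rows)


def simulate_headspace(
    design: pd.DataFrame,
    cfg: EffectConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate headspace concentration series and true fluxes.

    The true flux per microcosm x species is the configured group mean plus
    Gaussian noise; the concentration slope is obtained by inverting the
    ideal-gas conversion, so at zero noise the flux module recovers the
    configured flux exactly. Per-point measurement noise is added on top.
    """
    gas_rows, truth_rows = [], []
    for species in GAS_SPECIES:
        for _, row in design.iterrows():
            mean_flux = cfg.true_flux_mean(
                species, row["vegetation_type"], row["warming"], row["drought"], row["harvest_day"]
            )
            true_flux = mean_flux + rng.normal(0.0, cfg.flux_sd.get(species, 0.0))
            slope = fluxmod.flux_to_slope(
                true_flux,
                species,
                headspace_volume_l=row["headspace_volume_l"],
                temperature_c=row["incubation_temp_c"],
                pressure_kpa=row["pressure_kpa"],
                soil_dry_mass_g=row["soil_dry_mass_g"],
            )
            truth_rows.append(
                {"microcosm_id": row["microcosm_id"], "species": species, "true_flux_ug_g_h": true_flux}
            )
            c0 = cfg.ambient_ppm.get(species, 0.0)
            sd = cfg.conc_noise_ppm.get(species, 0.0)
            for t in GAS_MINUTES:
                conc = c0 + slope * t + rng.normal(0.0, sd)
                gas_rows.append(
                    {
                        "microcosm_id": row["microcosm_id"],
                        "species": species,
                        "minutes": t,
                        "concentration_ppm": max(conc, 0.0),
                    }
                )
    return pd.DataFrame(gas_rows), pd.DataFrame(truth_rows)


def simulate_experiment(
    site_configs: list[SiteConfig] | None = None,
    cfg: EffectConfig | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Full simulation: design + qPCR + headspace + ground truth, one RNG stream."""
    site_configs = site_configs if site_configs is not None else default_sites()
    cfg = cfg if cfg is not None else EffectConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    design = generate_design(site_configs)
    qpcr, calibration, truth_copies = simulate_qpcr(design, cfg, rng)
    headspace, truth_flux = simulate_headspace(design, cfg, rng)
    return {
        "design": design,
        "qpcr": qpcr,
        "calibration": calibration,
        "headspace": headspace,
        "truth_copies": truth_copies,
        "truth_flux": truth_flux,
    }


def effect_config_to_dict(cfg: EffectConfig) -> dict:
    """JSON-serializable view of the effect configuration (for run manifests)."""
    d = asdict(cfg)
    d["interactions"] = {
        gene: [[cond, mult] for cond, mult in pairs] for gene, pairs in cfg.interactions.items()
    }
    return d
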