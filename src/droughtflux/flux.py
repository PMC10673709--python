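"""Static-headspace greenhouse-gas flux estimation for closed-tube incubations.

A sealed microcosm accumulates (or consumes) gas; concentrations sampled at
a handful of time points are fit with ordinary least squares, and the slope
(ppmv min^-1) is converted to a mass flux of the element of interest
(C for CO2/CH4, N for N2O) per gram dry soil per hour via the ideal gas law:

    n_air = P * V / (R * T)                       [mol air in the headspace]
    flux  = slope * 1e-6 * n_air * k * M * 60 / m  [g element g^-1 h^-1]

where ``k`` is the number of element atoms per molecule, ``M`` the element
molar mass (g mol^-1) and ``m`` the dry soil mass (g). Because ppmv carries
a factor 1e-6 and micrograms a factor 1e6, the implementation works directly
in ug element g^-1 dry soil h^-1. Negative slopes (e.g. CH4 uptake by
methanotrophs) are biologically meaningful and are retained, never clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Universal gas constant, J mol^-1 K^-1
R_GAS = 8.314

#: Element molar masses, g mol^-1
MOLAR_MASS = {"C": 12.011, "N": 14.007}

#: species -> (element, atoms of that element per molecule)
SPECIES_ELEMENT = {
    "CO2": ("C", 1),
    "CH4": ("C", 1),
    "N2O": ("N", 2),
}

#: Default tube geometry / conditions (overridable everywhere).
DEFAULT_PRESSURE_KPA = 101.325
DEFAULT_TEMPERATURE_C = 9.0

KELVIN_OFFSET = 273.15


@dataclass
class SlopeFit:
    """OLS fit of concentration (ppmv) on time (min)."""

    slope: float  # ppmv min^-1
    slope_se: float
    intercept: float
    r2: float  # squared Pearson correlation; NaN for a constant series
    n: int


@dataclass
class FluxEstimate:
    microcosm_id: str
    species: str
    slope: float
    slope_se: float
    r2: float
    flux: float  # ug element g^-1 dry soil h^-1
    qc_flags: list[str] = field(default_factory=list)

    @property
    def qc_flag(self) -> str:
        return ";".join(self.qc_flags)


def headspace_moles(pressure_kpa: float, volume_l: float, temperature_c: float) -> float:
    """Moles of air in the headspace from the ideal gas law (n = PV/RT)."""
    if volume_l <= 0:
        raise ValueError(f"headspace volume must be positive, got {volume_l}")
    t_kelvin = temperature_c + KELVIN_OFFSET
    if t_kelvin <= 0:
        raise ValueError(f"absolute temperature must be positive, got {temperature_c} degC")
    if pressure_kpa <= 0:
        raise ValueError(f"pressure must be positive, got {pressure_kpa}")
    return (pressure_kpa * 1e3) * (volume_l * 1e-3) / (R_GAS * t_kelvin)


def _validate_series(times: np.ndarray, concentrations: np.ndarray) -> None:
    if len(times) != len(concentrations):
        raise ValueError("times and concentrations must have equal length")
    if len(times) < 3:
        raise ValueError(f"need >=3 time points, got {len(times)}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be non-negative")


def fit_slope(times, concentrations) -> SlopeFit:
    """OLS of concentration on time.

    A perfectly constant series returns slope 0 with ``r2`` NaN (undefined),
    not 1 — there is no signal to explain.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    _validate_series(t, c)
    if np.ptp(c) == 0.0:
        return SlopeFit(slope=0.0, slope_se=0.0, intercept=float(c[0]), r2=float("nan"), n=len(t))
    res = stats.linregress(t, c)
    return SlopeFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(t),
    )


def slope_to_flux(
    slope: float,
    species: str,
    *,
    headspace_volume_l: float,
    temperature_c: float = DEFAULT_TEMPERATURE_C,
    pressure_kpa: float = DEFAULT_PRESSURE_KPA,
    soil_dry_mass_g: float,
) -> float:
    """Convert a concentration slope (ppmv min^-1) to ug element g^-1 h^-1."""
    if soil_dry_mass_g <= 0:
        raise ValueError(f"soil dry mass must be positive, got {soil_dry_mass_g}")
    element, atoms = SPECIES_ELEMENT[species]
    n_air = headspace_moles(pressure_kpa, headspace_volume_l, temperature_c)
    # ppmv (1e-6) and g->ug (1e6) cancel
    return slope * n_air * atoms * MOLAR_MASS[element] * 60.0 / soil_dry_mass_g


def flux_to_slope(
    flux: float,
    species: str,
    *,
    headspace_volume_l: float,
    temperature_c: float = DEFAULT_TEMPERATURE_C,
    pressure_kpa: float = DEFAULT_PRESSURE_KPA,
    soil_dry_mass_g: float,
) -> float:
    """Inverse of :func:`slope_to_flux`; used to seed simulations from a target flux."""
    element, atoms = SPECIES_ELEMENT[species]
    n_air = headspace_moles(pressure_kpa, headspace_volume_l, temperature_c)
    return flux * soil_dry_mass_g / (n_air * atoms * MOLAR_MASS[element] * 60.0)


def qc_series(
    fit: SlopeFit,
    r2_threshold: float = 0.9,
    slope_zero_tol: float = 1e-12,
) -> list[str]:
    """QC flags for a fitted headspace series.

    - ``no-signal``: slope indistinguishable from zero.
    - ``nonlinear``: nonzero slope but r2 below threshold (flagged, not corrected).
    - ``negative``: informational; uptake (e.g. CH4 oxidation) is expected biology.
    """
    flags: list[str] = []
    if abs(fit.slope) <= slope_zero_tol:
        flags.append("no-signal")
    elif np.isnan(fit.r2) or fit.r2 < r2_threshold:
        flags.append("nonlinear")
    if fit.slope < -slope_zero_tol:
        flags.append("negative")
    return flags


def estimate_fluxes(
    headspace: pd.DataFrame,
    design: pd.DataFrame,
    r2_threshold: float = 0.9,
) -> pd.DataFrame:
    """Fit and convert every microcosm x species headspace series.

    ``headspace`` is long format (microcosm_id, species, minutes,
    concentration_ppm); ``design`` supplies per-microcosm geometry
    (soil_dry_mass_g, headspace_volume_l, pressure_kpa, incubation_temp_c).
    Returns one row per series with slope, slope_se, r2, flux and qc flags.
    """
    geom = design.set_index("microcosm_id")
    rows = []
    for (mid, species), grp in headspace.groupby(["microcosm_id", "species"], sort=True):
        grp = grp.sort_values("minutes")
        fit = fit_slope(grp["minutes"].to_numpy(), grp["concentration_ppm"].to_numpy())
        g = geom.loc[mid]
        flux = slope_to_flux(
            fit.slope,
            species,
            headspace_volume_l=float(g["headspace_volume_l"]),
            temperature_c=float(g["incubation_temp_c"]),
            pressure_kpa=float(g["pressure_kpa"]),
            soil_dry_mass_g=float(g["soil_dry_mass_g"]),
        )
        flags = qc_series(fit, r2_threshold=r2_threshold)
        rows.append(
            {
                "microcosm_id": mid,
                "species": species,
                "slope_ppm_min": fit.slope,
                "slope_se": fit.slope_se,
                "r2": fit.r2,
                "flux_ug_g_h": flux,
                "qc_flag": ";".join(flags),
            }
        )
    out = pd.DataFrame(rows)
    n_flagged = int((out["qc_flag"] != "").sum()) if len(out) else 0
    logger.info("estimated %d fluxes (%d flagged)", len(out), n_flagged)
    return out
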