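"""qPCR standard-curve quantification and 16S normalization.

The quantification cycle Cq is linear in log10 template copies:

    Cq = intercept + slope * log10(copies_in_reaction),   slope < 0

so a per-gene calibration series (here 10^4..10^9 copies) fitted by OLS
gives absolute copies for unknowns, and the amplification efficiency
E = 10^(-1/slope) - 1 (E = 1 means perfect doubling per cycle, i.e.
slope = -1/log10(2) = -3.3219). Copies in the reaction are scaled to copies
per gram dry soil through the extraction yield and template mass; functional
genes (pmoA, nosZII, acdS) are then normalized as ratios to 16S rRNA copies,
while 16S and ITS are carried through as raw abundances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENES = ("16S", "ITS", "pmoA", "nosZII", "acdS")
#: Functional genes normalized against 16S rRNA gene copies.
RATIO_GENES = ("pmoA", "nosZII", "acdS")
#: Calibration range in log10 copies.
CURVE_RANGE_LOG10 = (4.0, 9.0)


@dataclass
class StandardCurve:
    gene: str
    slope: float  # Cq per log10 copies, < 0
    intercept: float  # Cq at 1 copy
    r2: float
    efficiency: float  # 10^(-1/slope) - 1
    n_points: int

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def cq_from_copies(self, copies: float) -> float:
        return self.intercept + self.slope * math.log10(copies)


@dataclass
class GeneAbundance:
    microcosm_id: str
    gene: str
    copies_in_reaction: float
    copies_per_g: float  # copies g^-1 dry soil
    copies_per_ng_dna: float
    duplicate_cv: float
    qc_flags: list[str]

    @property
    def below_curve_flag(self) -> bool:
        return "outside-curve" in self.qc_flags


def amplification_efficiency(slope: float) -> float:
    """E = 10^(-1/slope) - 1; 1.0 (100%) for the ideal slope -1/log10(2)."""
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(points: pd.DataFrame, gene: str = "") -> StandardCurve:
    """OLS of Cq on log10 copies over calibration points.

    ``points`` needs columns ``log10_copies`` and ``cq`` with at least three
    distinct copy levels. An inverted (non-negative) fitted slope is an error:
    the dilution series is unusable.
    """
    x = np.asarray(points["log10_copies"], dtype=float)
    y = np.asarray(points["cq"], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(f"need >=3 distinct calibration levels, got {len(np.unique(x))}")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(f"fitted standard curve slope is non-negative ({res.slope:.3f}); inverted curve")
    return StandardCurve(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        efficiency=amplification_efficiency(float(res.slope)),
        n_points=len(x),
    )


def average_duplicates(
    cqs,
    curve: StandardCurve,
    cv_threshold: float = 0.2,
) -> tuple[float, float, list[str]]:
    """Collapse 1-2 technical-replicate Cq values to one.

    The mean is taken on the Cq scale; the coefficient of variation is computed
    on the copy scale (where qPCR error is multiplicative). High-CV pairs are
    flagged, never dropped. Returns (mean_cq, duplicate_cv, flags).
    """
    cqs = [c for c in np.atleast_1d(np.asarray(cqs, dtype=float)) if np.isfinite(c)]
    if len(cqs) == 0:
        raise ValueError("no technical replicates supplied")
    if len(cqs) == 1:
        return float(cqs[0]), 0.0, ["single"]
    copies = np.array([curve.copies_from_cq(c) for c in cqs])
    cv = float(np.std(copies, ddof=1) / np.mean(copies))
    flags = ["high-cv"] if cv > cv_threshold else []
    return float(np.mean(cqs)), cv, flags


def quantify(
    cq: float,
    curve: StandardCurve,
    template_mass_ng: float,
    dna_yield_ng: float,
    soil_mass_g: float,
    microcosm_id: str = "",
    duplicate_cv: float = 0.0,
    extra_flags: list[str] | None = None,
) -> GeneAbundance:
    """Convert one mean Cq to absolute copies per gram dry soil.

    copies_in_reaction = 10^((cq - intercept)/slope); the reaction contains
    ``template_mass_ng`` of the extract, so per-gram copies scale by
    (dna_yield_ng / template_mass_ng) / soil_mass_g. Values outside the
    calibration range are extrapolated but flagged ``outside-curve``
    (silent truncation would bias downstream indices).
    """
    if template_mass_ng <= 0:
        raise ValueError(f"template mass must be positive, got {template_mass_ng}")
    if soil_mass_g <= 0:
        raise ValueError(f"soil mass must be positive, got {soil_mass_g}")
    copies_rxn = curve.copies_from_cq(cq)
    flags = list(extra_flags or [])
    lo, hi = CURVE_RANGE_LOG10
    if not (10.0**lo <= copies_rxn <= 10.0**hi):
        flags.append("outside-curve")
    per_ng = copies_rxn / template_mass_ng
    per_g = per_ng * dna_yield_ng / soil_mass_g
    return GeneAbundance(
        microcosm_id=microcosm_id,
        gene=curve.gene,
        copies_in_reaction=copies_rxn,
        copies_per_g=per_g,
        copies_per_ng_dna=per_ng,
        duplicate_cv=duplicate_cv,
        qc_flags=flags,
    )


def fit_all_curves(calibration: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per gene from a long calibration table."""
    return {
        gene: fit_standard_curve(grp, gene=gene)
        for gene, grp in calibration.groupby("gene", sort=True)
    }


def quantify_table(
    qpcr: pd.DataFrame,
    calibration: pd.DataFrame,
    design: pd.DataFrame,
    cv_threshold: float = 0.2,
) -> pd.DataFrame:
    """Quantify a full qPCR plate table.

    ``qpcr``: long table (microcosm_id, gene, rep, cq, template_ng);
    ``design`` supplies soil_dry_mass_g and dna_yield_ng per microcosm.
    Returns one row per microcosm x gene with copies and QC columns.
    """
    curves = fit_all_curves(calibration)
    meta = design.set_index("microcosm_id")
    rows = []
    for (mid, gene), grp in qpcr.groupby(["microcosm_id", "gene"], sort=True):
        curve = curves[gene]
        mean_cq, cv, flags = average_duplicates(grp["cq"].to_numpy(), curve, cv_threshold)
        ab = quantify(
            mean_cq,
            curve,
            template_mass_ng=float(grp["template_ng"].iloc[0]),
            dna_yield_ng=float(meta.loc[mid, "dna_yield_ng"]),
            soil_mass_g=float(meta.loc[mid, "soil_dry_mass_g"]),
            microcosm_id=mid,
            duplicate_cv=cv,
            extra_flags=flags,
        )
        rows.append(
            {
                "microcosm_id": mid,
                "gene": gene,
                "mean_cq": mean_cq,
                "copies_in_reaction": ab.copies_in_reaction,
                "copies_per_g": ab.copies_per_g,
                "copies_per_ng_dna": ab.copies_per_ng_dna,
                "duplicate_cv": cv,
                "qc_flag": ";".join(ab.qc_flags),
            }
        )
    out = pd.DataFrame(rows)
    logger.info("quantified %d microcosm x gene records", len(out))
    return out


def compute_ratios(abundances: pd.DataFrame) -> pd.DataFrame:
    """Functional-gene : 16S ratios, long format.

    Output columns: microcosm_id, variable, value. Functional genes appear as
    ``<gene>:16S`` ratios; 16S and ITS pass through as raw abundances
    (``copies_per_g``). Microcosms with missing or zero 16S are excluded from
    the ratio rows with a logged warning.
    """
    wide = abundances.pivot(index="microcosm_id", columns="gene", values="copies_per_g")
    if "16S" not in wide.columns:
        raise ValueError("16S abundances are required to compute ratios")
    rows = []
    bad_16s = wide.index[wide["16S"].isna() | (wide["16S"] <= 0)]
    if len(bad_16s):
        logger.warning(
            "excluding %d microcosms with missing/zero 16S from ratios: %s",
            len(bad_16s),
            list(bad_16s),
        )
    for mid, rec in wide.iterrows():
        for gene in ("16S", "ITS"):
            if gene in wide.columns and np.isfinite(rec[gene]):
                rows.append({"microcosm_id": mid, "variable": gene, "value": rec[gene]})
        if mid in bad_16s:
            continue
        for gene in RATIO_GENES:
            if gene in wide.columns and np.isfinite(rec[gene]):
                rows.append(
                    {"microcosm_id": mid, "variable": f"{gene}:16S", "value": rec[gene] / rec["16S"]}
                )
    return pd.DataFrame(rows)
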