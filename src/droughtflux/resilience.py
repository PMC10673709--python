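"""Orwin-Wardle resistance and resilience indices on matched drought-control pairs.

For a matched pair, with C0 and P0 the control and drought values at the end
of the drought (day 0) and Cx, Px the values after recovery (day x = 56),
D0 = P0 - C0 and Dx = Px - Cx:

    RS = 1 - 2|D0| / (C0 + |D0|)          (resistance)
    RL = 2|D0| / (|D0| + |Dx|) - 1        (resilience)

Both are bounded above by 1: RS = 1 means no immediate change, RS = 0 a 100%
change from the control, and negative values an overshoot past 100%. RL = 1
means full recovery by day x, RL = 0 no recovery relative to the initial
displacement, and negative values further divergence. Both indices are
invariant under a common positive rescaling of their inputs, so the
standardize-to-the-mean preprocessing step changes intermediate tables but
never an index value.

Group summaries are means with two-sided Student-t confidence intervals;
a group whose interval overlaps 1 is classified as not different from the
undisturbed control (full resistance/resilience not rejected).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FLUX_VARIABLES = ("flux_CO2", "flux_CH4", "flux_N2O")


def standardize_to_mean(values) -> np.ndarray:
    """Divide each value by the mean of the vector (output mean = 1)."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"standardization requires a positive mean, got {m}")
    return v / m


def resistance(c0, p0):
    """RS = 1 - 2|D0|/(C0 + |D0|); scalar or elementwise on arrays.

    Undefined (error) when C0 + |D0| = 0.
    """
    c0 = np.asarray(c0, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    d0 = np.abs(p0 - c0)
    denom = c0 + d0
    if np.any(denom == 0):
        raise ValueError("resistance undefined: C0 + |D0| = 0")
    rs = 1.0 - 2.0 * d0 / denom
    return float(rs) if rs.ndim == 0 else rs


def resilience(c0, p0, cx, px):
    """RL = 2|D0|/(|D0| + |Dx|) - 1; scalar or elementwise on arrays.

    When both displacements are zero there was no initial perturbation to
    recover from: the index is undefined and returned as NaN (flagged
    missing), never silently 0.
    """
    c0 = np.asarray(c0, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    cx = np.asarray(cx, dtype=float)
    px = np.asarray(px, dtype=float)
    d0 = np.abs(p0 - c0)
    dx = np.abs(px - cx)
    denom = d0 + dx
    undefined = denom == 0
    if np.any(undefined):
        logger.warning("resilience undefined (no initial displacement) for %d pairs", int(np.sum(undefined)))
    with np.errstate(invalid="ignore", divide="ignore"):
        rl = np.where(undefined, np.nan, 2.0 * d0 / np.where(undefined, np.nan, denom) - 1.0)
    return float(rl) if rl.ndim == 0 else rl


def standardize_table(measures: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Standardize each variable to its mean within site x vegetation.

    ``measures`` is long (microcosm_id, variable, value). Standardizing across
    both timepoints of a group keeps day-0 and day-56 values on a common
    scale, so RS and RL are exactly unchanged (positive-rescaling invariance).
    """
    merged = measures.merge(
        design[["microcosm_id", "site", "vegetation_type"]], on="microcosm_id", validate="many_to_one"
    )
    means = merged.groupby(["variable", "site", "vegetation_type"])["value"].transform("mean")
    if (means <= 0).any():
        bad = merged.loc[means <= 0, ["variable", "site", "vegetation_type"]].drop_duplicates()
        raise ValueError(f"standardization requires positive group means; offending groups:\n{bad}")
    out = merged.copy()
    out["value"] = out["value"] / means
    return out[measures.columns.tolist()].reset_index(drop=True)


def build_pair_table(measures: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Assemble (C0, P0, Cx, Px) per experimental unit x variable.

    The drought microcosm is matched to the control microcosm of the same
    unit at each harvest day. Units missing any of the four arms for a
    variable are dropped with a logged warning.
    """
    merged = measures.merge(
        design[["microcosm_id", "unit_id", "site", "vegetation_type", "warming", "drought", "harvest_day"]],
        on="microcosm_id",
        validate="many_to_one",
    )
    merged["arm"] = merged["drought"].map({"control": "C", "drought": "P"}) + merged[
        "harvest_day"
    ].map({0: "0", 56: "x"})
    wide = merged.pivot_table(
        index=["unit_id", "site", "vegetation_type", "warming", "variable"],
        columns="arm",
        values="value",
        aggfunc="first",
    ).reset_index()
    needed = ["C0", "P0", "Cx", "Px"]
    for col in needed:
        if col not in wide.columns:
            wide[col] = np.nan
    incomplete = wide[needed].isna().any(axis=1)
    if incomplete.any():
        logger.warning("dropping %d unpaired/incomplete unit x variable records", int(incomplete.sum()))
    return wide.loc[~incomplete].reset_index(drop=True)


def compute_indices(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-pair RS and RL, long format (kind in {resistance, resilience}).

    Flux variables can have non-positive control values; the 0-1 reading of
    the index assumes a positive control, so those rows are flagged.
    """
    rs = resistance(pairs["C0"].to_numpy(), pairs["P0"].to_numpy())
    rl = resilience(
        pairs["C0"].to_numpy(), pairs["P0"].to_numpy(), pairs["Cx"].to_numpy(), pairs["Px"].to_numpy()
    )
    base = pairs[["unit_id", "site", "vegetation_type", "warming", "variable"]]
    flagged = pairs["C0"].to_numpy() <= 0
    out = []
    for kind, vals in (("resistance", rs), ("resilience", rl)):
        df = base.copy()
        df["kind"] = kind
        df["value"] = vals
        df["nonpositive_control"] = flagged
        out.append(df)
    return pd.concat(out, ignore_index=True)


def aggregate_group(values, level: float = 0.95) -> dict:
    """Mean and two-sided Student-t CI (n-1 df) with classification flags.

    ``contains_1`` implements the classification rule: an interval overlapping
    1 means no detectable difference from the undisturbed control. A zero-
    variance group has a degenerate interval [v, v]. Groups with n < 2 get no
    interval and are flagged.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n == 0:
        return {"mean": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": 0,
                "contains_1": False, "contains_0": False, "overshoot": False, "flags": "empty"}
    mean = float(np.mean(v))
    if n < 2:
        return {"mean": mean, "ci_low": np.nan, "ci_high": np.nan, "n": n,
                "contains_1": False, "contains_0": False, "overshoot": mean < 0, "flags": "n<2"}
    se = float(np.std(v, ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=n - 1))
    lo, hi = mean - tcrit * se, mean + tcrit * se
    return {
        "mean": mean,
        "ci_low": lo,
        "ci_high": hi,
        "n": n,
        "contains_1": bool(lo <= 1.0 <= hi),
        "contains_0": bool(lo <= 0.0 <= hi),
        "overshoot": mean < 0,
        "flags": "",
    }


def aggregate_groups(indices: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Group summaries per site x vegetation x warming x variable x kind."""
    rows = []
    keys = ["site", "vegetation_type", "warming", "variable", "kind"]
    for key, grp in indices.groupby(keys, sort=True):
        rec = dict(zip(keys, key))
        rec.update(aggregate_group(grp["value"].to_numpy(), level=level))
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_warming(ambient_values, warmed_values) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of index values, warmed vs ambient: (F, (1, df2), p)."""
    a = np.asarray(ambient_values, dtype=float)
    w = np.asarray(warmed_values, dtype=float)
    a, w = a[np.isfinite(a)], w[np.isfinite(w)]
    if len(a) < 2 or len(w) < 2:
        raise ValueError(f"need >=2 values per group, got {len(a)} and {len(w)}")
    res = stats.f_oneway(a, w)
    f = 0.0 if np.isnan(res.statistic) and np.var(a) == np.var(w) else float(res.statistic)
    df = (1, len(a) + len(w) - 2)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return f, df, p


def compare_warming_table(indices: pd.DataFrame) -> pd.DataFrame:
    """Warmed-vs-ambient ANOVA per site x vegetation x variable x kind."""
    rows = []
    keys = ["site", "vegetation_type", "variable", "kind"]
    for key, grp in indices.groupby(keys, sort=True):
        a = grp.loc[grp["warming"] == "ambient", "value"].to_numpy()
        w = grp.loc[grp["warming"] == "warmed", "value"].to_numpy()
        a, w = a[np.isfinite(a)], w[np.isfinite(w)]
        if len(a) < 2 or len(w) < 2:
            continue
        f, df, p = compare_warming(a, w)
        rec = dict(zip(keys, key))
        rec.update({"F": f, "df1": df[0], "df2": df[1], "p": p})
        rows.append(rec)
    return pd.DataFrame(rows)
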