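"""Linear mixed models with nested random intercepts for the incubation design.

The fixed structure is the full set of main effects and two- and three-way
interactions among the design factors (four-way terms are excluded as
uninterpretable); the random structure is a matched drought-control pair
(experimental unit) intercept nested within the origin field treatment
(warmed vs ambient plots). Random-effect importance is judged by likelihood
ratio deletion tests; variance explained is partitioned into marginal
(fixed only) and conditional (fixed + random) R2 after Nakagawa &
Schielzeth:

    R2_marginal    = s2_fixed / (s2_fixed + sum s2_random + s2_resid)
    R2_conditional = (s2_fixed + sum s2_random) / (same denominator)

where s2_fixed is the variance of the fixed-effect predictions. REML is used
for reported variance components; deletion tests refit by ML so that the
no-random-effect (OLS) reduced model is comparable. Per-term F statistics
are Wald tests with residual denominator degrees of freedom (n - rank(X)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

RANDOM_TERMS = ("group", "pair")  # origin field treatment; pair nested within it


class SingularDesignError(ValueError):
    pass


@dataclass
class MixedModelSpec:
    """Fixed and random structure for one response.

    ``factors`` are categorical design columns; ``covariate`` an optional
    continuous column (e.g. a log10 gene abundance) crossed with the factors
    up to three-way terms.
    """

    response: str
    factors: tuple[str, ...]
    covariate: str | None = None
    max_order: int = 3
    group_col: str = "warming"  # origin field treatment
    pair_col: str = "unit_id"  # matched drought-control pair

    @property
    def base_terms(self) -> tuple[str, ...]:
        terms = tuple(self.factors)
        if self.covariate:
            terms += (self.covariate,)
        return terms

    @property
    def rhs_terms(self) -> list[str]:
        """Main effects plus all interactions up to ``max_order`` (no higher)."""
        base = self.base_terms
        out: list[str] = []
        for order in range(1, min(self.max_order, len(base)) + 1):
            out.extend(":".join(c) for c in combinations(base, order))
        return out

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.rhs_terms) if self.rhs_terms else "1"
        return f"{self.response} ~ {rhs}"


def build_spec(
    response: str,
    factor_set,
    gene_covariate: str | None = None,
    data: pd.DataFrame | None = None,
    **kwargs,
) -> MixedModelSpec:
    """Validated model spec; unknown columns are rejected when data is given."""
    spec = MixedModelSpec(response=response, factors=tuple(factor_set), covariate=gene_covariate, **kwargs)
    if data is not None:
        missing = [c for c in (response, *spec.base_terms) if c not in data.columns]
        if missing:
            raise ValueError(f"unknown model columns: {missing}")
    return spec


@dataclass
class MixedModelFit:
    spec: MixedModelSpec
    random: tuple[str, ...]  # subset of RANDOM_TERMS actually fitted
    reml: bool
    n: int
    rank: int
    df_resid: int
    params: pd.Series
    cov_params: pd.DataFrame
    var_group: float
    var_pair: float
    var_resid: float
    var_fixed: float
    llf: float
    fitted_fixed: np.ndarray
    anova: pd.DataFrame
    converged: bool
    term_slices: dict = field(repr=False, default_factory=dict)

    @property
    def n_random(self) -> int:
        return len(self.random)

    @property
    def var_random_total(self) -> float:
        return self.var_group + self.var_pair


def _design_matrices(spec: MixedModelSpec, data: pd.DataFrame):
    y, X = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    rank = int(np.linalg.matrix_rank(X.to_numpy()))
    if rank < X.shape[1]:
        # identify aliased columns by greedy rank growth
        aliased, keep = [], []
        M = X.to_numpy()
        for j, name in enumerate(X.columns):
            if np.linalg.matrix_rank(M[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                aliased.append(name)
        raise SingularDesignError(f"singular fixed-effect design; aliased terms: {aliased}")
    return y, X, rank


def _anova_table(params: np.ndarray, cov: np.ndarray, slices: dict, df_resid: int) -> pd.DataFrame:
    rows = []
    for term, sl in slices.items():
        if term == "Intercept":
            continue
        b = params[sl]
        V = cov[sl.start : sl.stop, sl.start : sl.stop]
        q = len(b)
        try:
            f = float(b @ np.linalg.solve(V, b) / q)
        except np.linalg.LinAlgError:
            f = np.nan
        p = float(stats.f.sf(f, q, df_resid)) if np.isfinite(f) else np.nan
        rows.append({"term": term, "df_num": q, "df_den": df_resid, "F": f, "p": p})
    return pd.DataFrame(rows)


def fit_lmm(
    spec: MixedModelSpec,
    data: pd.DataFrame,
    random: tuple[str, ...] = RANDOM_TERMS,
    reml: bool = True,
) -> MixedModelFit:
    """Fit the mixed model (or OLS when ``random`` is empty).

    ``random`` is a subset of ("group", "pair"); with both, the pair
    intercept is a variance component nested inside the origin-treatment
    grouping. With neither, the model collapses to OLS — the coefficient
    estimates then equal the ordinary least-squares solution by construction.
    """
    random = tuple(random)
    for r in random:
        if r not in RANDOM_TERMS:
            raise ValueError(f"unknown random term {r!r}")
    cols = [spec.response, *spec.base_terms]
    if random:
        cols += [spec.group_col, spec.pair_col]
    missing = [c for c in dict.fromkeys(cols) if c not in data.columns]
    if missing:
        raise ValueError(f"unknown model columns: {missing}")
    data = data.dropna(subset=list(dict.fromkeys(cols))).reset_index(drop=True)
    y, X, rank = _design_matrices(spec, data)
    n = len(y)
    df_resid = n - rank
    slices = dict(X.design_info.term_name_slices)

    if not random:
        res = sm.OLS(np.asarray(y).ravel(), X).fit()
        params = pd.Series(res.params, index=X.columns)
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        fitted = X.to_numpy() @ params.to_numpy()
        fit = MixedModelFit(
            spec=spec, random=(), reml=reml, n=n, rank=rank, df_resid=df_resid,
            params=params, cov_params=cov,
            var_group=0.0, var_pair=0.0, var_resid=float(res.scale),
            var_fixed=float(np.var(fitted, ddof=1)),
            llf=float(res.llf), fitted_fixed=fitted,
            anova=_anova_table(params.to_numpy(), cov.to_numpy(), slices, df_resid),
            converged=True, term_slices=slices,
        )
        return fit

    if random == ("pair",):
        groups = data[spec.pair_col]
        vc = None
    elif random == ("group",):
        groups = data[spec.group_col]
        vc = None
    else:  # both: pair intercept nested within origin treatment
        groups = data[spec.group_col]
        vc = {"pair": f"0 + C({spec.pair_col})"}

    if vc is not None:
        md = sm.MixedLM.from_formula(
            spec.formula, data, groups=groups, re_formula="1", vc_formula=vc
        )
    else:
        md = sm.MixedLM.from_formula(spec.formula, data, groups=groups, re_formula="1")
    # the profiled likelihood can have local optima; try several deterministic
    # optimizers and keep the best converged fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res, fallback = None, None
        for method in ("bfgs", "powell", "lbfgs"):
            try:
                cand = md.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            fallback = fallback or cand
            if cand.converged and (res is None or cand.llf > res.llf + 1e-8):
                res = cand
        res = res if res is not None else fallback
        if res is None:
            raise RuntimeError("mixed-model optimization failed for all methods")

    k_fe = len(res.fe_params)
    params = pd.Series(np.asarray(res.fe_params), index=X.columns)
    cov_all = np.asarray(res.cov_params())
    cov = pd.DataFrame(cov_all[:k_fe, :k_fe], index=X.columns, columns=X.columns)
    if random == ("group",) or random == ("pair",):
        var_intercept = float(np.asarray(res.cov_re)[0, 0])
        var_group = var_intercept if random == ("group",) else 0.0
        var_pair = var_intercept if random == ("pair",) else 0.0
    else:
        var_group = float(np.asarray(res.cov_re)[0, 0])
        var_pair = float(np.asarray(res.vcomp)[0])
    fitted = X.to_numpy() @ params.to_numpy()
    return MixedModelFit(
        spec=spec, random=random, reml=reml, n=n, rank=rank, df_resid=df_resid,
        params=params, cov_params=cov,
        var_group=var_group, var_pair=var_pair, var_resid=float(res.scale),
        var_fixed=float(np.var(fitted, ddof=1)),
        llf=float(res.llf), fitted_fixed=fitted,
        anova=_anova_table(params.to_numpy(), cov.to_numpy(), slices, df_resid),
        converged=bool(res.converged), term_slices=slices,
    )


def lrt_from_loglik(ll_full: float, ll_reduced: float, df: int) -> tuple[float, int, float]:
    """Likelihood ratio statistic 2*(ll_full - ll_reduced), floored at 0."""
    if df <= 0:
        raise ValueError("deletion test needs df >= 1")
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return stat, df, float(stats.chi2.sf(stat, df))


def lrt_random(full: MixedModelFit, reduced: MixedModelFit) -> tuple[float, int, float]:
    """Deletion test for random effects: reduced must nest inside full.

    Both fits must share the fixed formula and estimation method (use ML for
    comparisons against the OLS null, whose likelihood is ML).
    """
    if full.spec.formula != reduced.spec.formula:
        raise ValueError("deletion test requires identical fixed structures")
    if full.reml != reduced.reml:
        raise ValueError("deletion test requires the same estimation method for both fits")
    df = full.n_random - reduced.n_random
    if df <= 0:
        raise ValueError("reduced model does not nest inside full (no variance components removed)")
    if not set(reduced.random) <= set(full.random):
        raise ValueError("reduced random terms are not a subset of the full model's")
    return lrt_from_loglik(full.llf, reduced.llf, df)


def r2_from_components(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    denom = var_fixed + var_random + var_resid
    if denom <= 0:
        raise ValueError("total variance is zero; R2 undefined")
    return var_fixed / denom, (var_fixed + var_random) / denom


def r2_nakagawa(fit: MixedModelFit) -> tuple[float, float]:
    """(marginal, conditional) R2; equal when all random variances are zero."""
    return r2_from_components(fit.var_fixed, fit.var_random_total, fit.var_resid)


def select_random_structure(
    spec: MixedModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[MixedModelFit, dict]:
    """Backward deletion of random effects by ML likelihood ratio tests.

    Starting from the full nested structure (pair intercept within origin
    field treatment), first test dropping the origin-treatment intercept
    (which is confounded with the fixed warming term and rarely identified),
    then the pair intercept. Components that do not improve fit (p > alpha)
    are removed; the retained structure is refit by REML. When everything is
    dropped the model is OLS and marginal and conditional R2 coincide.
    Fixed structure is never pruned.
    """
    fits_ml = {r: fit_lmm(spec, data, random=r, reml=False)
               for r in (RANDOM_TERMS, ("pair",), ())}
    record: dict = {}
    kept = RANDOM_TERMS
    stat, df, p = lrt_random(fits_ml[RANDOM_TERMS], fits_ml[("pair",)])
    record["lrt_group_stat"], record["lrt_group_p"] = stat, p
    if p > alpha:
        kept = ("pair",)
        stat, df, p = lrt_random(fits_ml[("pair",)], fits_ml[()])
        record["lrt_pair_stat"], record["lrt_pair_p"] = stat, p
        if p > alpha:
            kept = ()
    record["random_kept"] = list(kept)
    final = fit_lmm(spec, data, random=kept, reml=True) if kept else fits_ml[()]
    return final, record


#: Gene predictors entering the day-56 single-gene GHG models. Functional
#: genes enter as their 16S ratios; for N2O the pmoA ratio is replaced by the
#: nosZII ratio (the N2O-reducing gene).
GHG_GENE_SETS = {
    "flux_CO2": ("abund_16S", "abund_ITS", "ratio_pmoA", "ratio_acdS"),
    "flux_CH4": ("abund_16S", "abund_ITS", "ratio_pmoA", "ratio_acdS"),
    "flux_N2O": ("abund_16S", "abund_ITS", "ratio_nosZII", "ratio_acdS"),
}


def fit_gene_ghg_models(
    day56_data: pd.DataFrame,
    ghg: str,
    gene_list: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> dict[str, tuple[MixedModelFit, dict]]:
    """One day-56 model per gene: GHG ~ (vegetation + warming + drought + log10 gene)**3.

    Continuous gene covariates are log10-transformed (lognormal abundance
    scale) before entering the model. Returns {gene_column: (fit, lrt record)}.
    """
    genes = gene_list if gene_list is not None else GHG_GENE_SETS[ghg]
    out = {}
    for gene in genes:
        if gene not in day56_data.columns:
            raise ValueError(f"missing gene column {gene!r}")
        df = day56_data.copy()
        logcol = f"log10_{gene}"
        vals = df[gene].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            df[logcol] = np.where(vals > 0, np.log10(np.where(vals > 0, vals, 1.0)), np.nan)
        n_dropped = int(np.sum(~(vals > 0)))
        if n_dropped:
            logger.warning("%s: dropping %d non-positive values before log10", gene, n_dropped)
        spec = build_spec(
            ghg, ("vegetation_type", "warming", "drought"), gene_covariate=logcol, data=df
        )
        out[gene] = select_random_structure(spec, df, alpha=alpha)
    return out


def tukey_hsd(data: pd.DataFrame, response: str, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Tukey HSD contrasts (delegated to statsmodels)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = data.dropna(subset=[response, factor])
    res = pairwise_tukeyhsd(sub[response], sub[factor], alpha=alpha)
    return pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
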