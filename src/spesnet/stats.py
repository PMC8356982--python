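"""Group-level statistics for SPES network metrics.

Two analysis styles, matching how each metric is sampled:

* pooled node/connection values (one row per significant response or per
  stimulated node) — grouped Kruskal–Wallis simple-effect tests followed by
  Dunn's pairwise rank tests;
* per-patient summary values (densities, per-location mean centralities) —
  linear mixed-effects models with a patient random intercept, effects
  tested by likelihood-ratio tests of full vs reduced ML fits, residual
  normality checked by Shapiro–Wilk, and post hoc pairwise two-tailed
  t-tests using the model's pooled standard error with containment degrees
  of freedom.

All p-values are Benjamini–Hochberg FDR adjusted within their analysis
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .types import StatResult


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: list[StatResult]) -> list[StatResult]:
    """Fill ``p_fdr`` within each FDR family of a result list."""
    by_family: dict[str, list[StatResult]] = {}
    for r in results:
        by_family.setdefault(r.family_id, []).append(r)
    for members in by_family.values():
        adj = fdr_adjust([m.p_raw for m in members])
        for m, q in zip(members, adj):
            m.p_fdr = float(q)
    return results


def kruskal_wallis(values, groups, family_id: str = "kw") -> StatResult:
    """Kruskal–Wallis H (tie-corrected) across group labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2 or values.size < 2:
        raise ValueError("need at least two groups and two observations")
    samples = [values[groups == g] for g in levels]
    h, p = sps.kruskal(*samples)
    return StatResult(
        test="kruskal_wallis",
        statistic=float(h),
        df=float(len(levels) - 1),
        p_raw=float(p),
        comparison="|".join(str(g) for g in levels),
        family_id=family_id,
    )


def dunn_posthoc(values, groups, family_id: str = "dunn") -> list[StatResult]:
    """Dunn's pairwise rank tests with tie-corrected pooled variance.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie
    term T = Σ(t³−t)/(12(N−1)); two-sided normal p-values, BH-adjusted
    within the pairwise family.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = values.size
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    pooled_var = n * (n + 1) / 12.0 - tie_term
    levels = list(pd.unique(groups))
    mean_ranks = {g: ranks[groups == g].mean() for g in levels}
    counts = {g: int((groups == g).sum()) for g in levels}
    out = []
    for g1, g2 in combinations(levels, 2):
        se = np.sqrt(pooled_var * (1.0 / counts[g1] + 1.0 / counts[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        out.append(
            StatResult(
                test="dunn",
                statistic=float(z),
                df=float("inf"),
                p_raw=float(2 * sps.norm.sf(abs(z))),
                comparison=f"{g1} vs {g2}",
                family_id=family_id,
            )
        )
    return adjust_family(out)


def fisher_chi2_tests(
    table, mode: str = "fisher", family_id: str = "counts"
) -> StatResult:
    """Fisher's exact test (2×2, two-sided hypergeometric) or chi-squared
    (r×c, no continuity correction) on a count table."""
    table = np.asarray(table, dtype=int)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if mode == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return StatResult(
            test="fisher_exact",
            statistic=float(odds),
            df=1.0,
            p_raw=float(p),
            comparison="2x2",
            family_id=family_id,
        )
    if mode == "chi2":
        chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
        return StatResult(
            test="chi_squared",
            statistic=float(chi2),
            df=float(df),
            p_raw=float(p),
            comparison=f"{table.shape[0]}x{table.shape[1]}",
            family_id=family_id,
        )
    raise ValueError("mode must be 'fisher' or 'chi2'")


# --- linear mixed-effects analysis ----------------------------------------


@dataclass
class LMEResult:
    """Fitted mixed-model analysis of one per-patient metric."""

    data: pd.DataFrame
    response: str
    between: str
    within: str | None
    patient_col: str
    lrt_results: list[StatResult]
    shapiro: StatResult
    ml_fit: object
    reml_fit: object
    singular: bool = False

    @property
    def n_patients(self) -> int:
        return self.data[self.patient_col].nunique()


def _formula(response: str, terms: list[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _fit_ml(formula: str, data: pd.DataFrame, patient_col: str, reml: bool = False):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, data=data, groups=data[patient_col])
        try:
            fit = model.fit(reml=reml, method="lbfgs", maxiter=200)
        except Exception:
            fit = model.fit(reml=reml, method="powell", maxiter=500)
    return fit


def fit_lme(
    data: pd.DataFrame,
    response: str,
    between: str,
    within: str | None = None,
    patient_col: str = "patient_id",
    family_id: str = "lme",
) -> LMEResult:
    """Fit the full mixed model and run the likelihood-ratio test battery.

    Fixed effects: ``between`` (a between-patient factor such as patient
    group) crossed with ``within`` (a within-patient factor such as
    connection type or electrode location); random intercept per patient.
    LRTs compare full vs reduced maximum-likelihood fits: the interaction
    (full vs additive) and each factor's simple effect (additive vs the
    model without it) — the simple effects are always tested, whether or not
    the interaction is significant. Residual normality of the full model is
    assessed with Shapiro–Wilk. REML estimates are kept for post hoc
    contrasts.
    """
    data = data.dropna(subset=[response]).copy()
    if data[patient_col].nunique() < 2:
        raise ValueError("mixed model requires at least two patients")
    b, w = f"C({between})", f"C({within})" if within else None
    terms_full = [f"{b}*{w}"] if within else [b]
    terms_add = [b, w] if within else [b]
    full = _fit_ml(_formula(response, terms_full), data, patient_col)
    additive = _fit_ml(_formula(response, terms_add), data, patient_col)
    singular = bool(np.asarray(full.cov_re).ravel()[0] < 1e-8)

    results: list[StatResult] = []

    def _lrt(big, small, label: str) -> None:
        stat = 2.0 * (big.llf - small.llf)
        df = int(big.df_modelwc - small.df_modelwc)
        stat = max(stat, 0.0)
        results.append(
            StatResult(
                test="lme_lrt",
                statistic=float(stat),
                df=float(df),
                p_raw=float(sps.chi2.sf(stat, df)) if df > 0 else 1.0,
                comparison=label,
                family_id=family_id,
            )
        )

    if within:
        _lrt(full, additive, f"{between}:{within} interaction")
        no_within = _fit_ml(_formula(response, [b]), data, patient_col)
        no_between = _fit_ml(_formula(response, [w]), data, patient_col)
        _lrt(additive, no_within, f"{within} effect")
        _lrt(additive, no_between, f"{between} effect")
    else:
        null = _fit_ml(_formula(response, []), data, patient_col)
        _lrt(full, null, f"{between} effect")

    reml = _fit_ml(_formula(response, terms_full), data, patient_col, reml=True)
    try:
        resid = np.asarray(full.resid, dtype=float)
    except Exception:
        # singular random-effect covariance: fall back to marginal residuals
        resid = np.asarray(
            full.model.endog - full.model.exog @ np.asarray(full.fe_params),
            dtype=float,
        )
    if resid.size >= 3 and np.ptp(resid) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_stat, sw_p = sps.shapiro(resid)
    else:
        sw_stat, sw_p = (np.nan, np.nan)
    shapiro = StatResult(
        test="shapiro_wilk",
        statistic=float(sw_stat),
        df=float(resid.size),
        p_raw=float(sw_p),
        comparison="full-model residuals",
        family_id=f"{family_id}:diagnostics",
    )
    adjust_family(results)
    return LMEResult(
        data=data,
        response=response,
        between=between,
        within=within,
        patient_col=patient_col,
        lrt_results=results,
        shapiro=shapiro,
        ml_fit=full,
        reml_fit=reml,
        singular=singular,
    )


def containment_df(result: LMEResult, factor: str) -> float:
    """Containment degrees of freedom for contrasts of ``factor``.

    A between-patient factor is contained by the patient grouping, so its
    contrasts get df = n_patients − n_levels(between). A within-patient
    factor uses the observation-level residual df,
    N − n_patients − n_levels(between)·(n_levels(within) − 1).
    """
    n_pat = result.n_patients
    k_b = result.data[result.between].nunique()
    if factor == result.between:
        return float(n_pat - k_b)
    if factor == result.within:
        k_w = result.data[result.within].nunique()
        return float(len(result.data) - n_pat - k_b * (k_w - 1))
    raise ValueError(f"{factor!r} is not a factor of this model")


def _marginal_design_row(result: LMEResult, factor: str, level) -> np.ndarray:
    """Average fixed-effects design row for one factor level, marginal over
    the other factor's levels."""
    design_info = result.reml_fit.model.data.design_info
    other = result.within if factor == result.between else result.between
    if other is None:
        grid = pd.DataFrame({factor: [level]})
    else:
        grid = pd.DataFrame(
            {
                factor: level,
                other: pd.unique(result.data[other]),
            }
        )
    rows = np.asarray(patsy.dmatrix(design_info, grid, return_type="matrix"))
    return rows.mean(axis=0)


def posthoc_pairwise_t(
    result: LMEResult, factor: str, family_id: str | None = None
) -> list[StatResult]:
    """Two-tailed pairwise t-tests on marginal means of ``factor``.

    The contrast standard error pools the full (REML) model's fixed-effect
    covariance; degrees of freedom follow the containment rule. BH-adjusted
    within the pairwise family.
    """
    family_id = family_id or f"posthoc:{factor}"
    levels = list(pd.unique(result.data[factor]))
    beta = np.asarray(result.reml_fit.fe_params)
    vcov = np.asarray(result.reml_fit.cov_params())[: beta.size, : beta.size]
    df = containment_df(result, factor)
    out = []
    for l1, l2 in combinations(levels, 2):
        c = _marginal_design_row(result, factor, l1) - _marginal_design_row(
            result, factor, l2
        )
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ vcov @ c, 0.0)))
        t = est / se if np.isfinite(se) and se > 0 else 0.0
        out.append(
            StatResult(
                test="posthoc_t",
                statistic=float(t),
                df=df,
                p_raw=float(2 * sps.t.sf(abs(t), df)),
                comparison=f"{l1} vs {l2}",
                family_id=family_id,
            )
        )
    return adjust_family(out)


def results_table(results: list[StatResult]) -> pd.DataFrame:
    """Tidy TSV-ready table of test results."""
    return pd.DataFrame(
        [
            {
                "test": r.test,
                "comparison": r.comparison,
                "statistic": r.statistic,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "family_id": r.family_id,
            }
            for r in results
        ]
    )
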