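"""Factorial inference layer: type-III ANOVA/ANCOVA, LSD pairwise tests,
assumption checks, significance-pattern comparison and variation metrics.

The factorial design crosses a two-level seawater-pCO2 factor with a
three-level temperature factor.  Models are fitted with sum-to-zero factor
coding so that type-III (partial) sums of squares reproduce the convention
of mainstream commercial ANOVA software.  Pairwise comparisons use
estimated marginal means with Fisher's least significant difference, i.e.
unadjusted t tests on the pooled error mean square.  Covariates, when
supplied, are screened first and dropped if nonsignificant, turning the
ANCOVA back into a plain ANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaResult",
    "EMMResult",
    "AssumptionReport",
    "VariationSummary",
    "SignificancePattern",
    "StatsError",
    "two_way_anova_type3",
    "emm_lsd_pairwise",
    "check_assumptions",
    "residual_factor_check",
    "percent_range_variation",
    "mortality_chi_square",
    "significance_pattern",
]

DEFAULT_FACTORS = ("pco2_level", "temperature_c")
FACTOR_LABELS = {"pco2_level": "pCO2", "temperature_c": "Temperature"}


class StatsError(ValueError):
    """Raised for designs or inputs a fit cannot support."""


@dataclass
class AnovaResult:
    """A tidy type-III ANOVA table plus the fitted model behind it.

    ``table`` has rows pCO2, Temperature, Interaction, any retained
    covariates, Error, and Total (corrected), with columns source,
    ss_type3, df, ms, f, p.
    """

    table: pd.DataFrame
    response: str
    transform: str
    adj_r2: float
    model: object
    data: pd.DataFrame
    factors: tuple[str, str]
    dropped_covariates: list[str] = field(default_factory=list)

    def p_value(self, term: str) -> float:
        row = self.table.loc[self.table["source"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in ANOVA table")
        return float(row["p"].iloc[0])


def _term_name(factor: str) -> str:
    return f"C({factor}, Sum)"


def _tidy_anova(
    a3: pd.DataFrame, factors: tuple[str, str], covariates: Sequence[str]
) -> pd.DataFrame:
    fa, fb = (_term_name(f) for f in factors)
    label = {
        fa: FACTOR_LABELS.get(factors[0], factors[0]),
        fb: FACTOR_LABELS.get(factors[1], factors[1]),
        f"{fa}:{fb}": "Interaction",
        "Residual": "Error",
    }
    label.update({c: c for c in covariates})
    rows = []
    err_ss = float(a3.loc["Residual", "sum_sq"])
    err_df = float(a3.loc["Residual", "df"])
    total = float(a3.drop(index="Intercept", errors="ignore")["sum_sq"].sum())
    # a numerically perfect fit leaves rounding dust in the error SS
    if err_ss <= 1e-12 * max(total, 1.0):
        err_ss = 0.0
    for idx, r in a3.iterrows():
        if idx == "Intercept":
            continue
        ss, df = float(r["sum_sq"]), float(r["df"])
        if idx == "Residual":
            ss = err_ss
            f = p = np.nan
        elif err_ss <= 0 or err_df <= 0:
            # saturated / zero-error fit: any nonzero effect is infinitely
            # unlikely under the null, so guard F and report p = 0
            f, p = (np.inf, 0.0) if ss > 0 else (0.0, 1.0)
        else:
            f = float(r["F"])
            p = float(r["PR(>F)"])
        ms = ss / df if df > 0 else np.nan
        rows.append(
            {"source": label.get(idx, idx), "ss_type3": ss, "df": df, "ms": ms,
             "f": f, "p": p}
        )
    return pd.DataFrame(rows)


def two_way_anova_type3(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str] | None = None,
    factors: tuple[str, str] = DEFAULT_FACTORS,
    alpha: float = 0.05,
    transform: str = "none",
) -> AnovaResult:
    """Two-way type-III ANOVA (optionally ANCOVA with covariate screening).

    The model is ``response ~ A * B`` with sum-to-zero contrasts.  When
    covariates are supplied they enter additively and are screened: any
    covariate whose type-III F-test has p > ``alpha`` is dropped and the
    model refitted without it.  ``transform='log10'`` fits log10(response),
    which requires strictly positive values.
    """
    data = data.copy()
    if response not in data.columns:
        raise StatsError(f"response column {response!r} not in data")
    fa, fb = factors
    cells = data.groupby([fa, fb], observed=True).size()
    levels_a = data[fa].nunique()
    levels_b = data[fb].nunique()
    if len(cells) < levels_a * levels_b:
        raise StatsError(
            f"design has empty cells: found {len(cells)} of "
            f"{levels_a * levels_b} crossings of {fa} x {fb}"
        )
    if (cells < 2).any():
        raise StatsError("every design cell needs at least 2 observations")

    ycol = response
    if transform == "log10":
        if (data[response] <= 0).any():
            raise StatsError(
                f"log10 transform of {response!r} requires positive values"
            )
        ycol = f"log10_{response}"
        data[ycol] = np.log10(data[response])
    elif transform != "none":
        raise StatsError(f"unknown transform {transform!r}")

    covariates = list(covariates or [])
    dropped: list[str] = []

    def _fit(covs: Sequence[str]):
        rhs = f"{_term_name(fa)} * {_term_name(fb)}"
        for c in covs:
            rhs += f" + {c}"
        fit = smf.ols(f"Q('{ycol}') ~ {rhs}", data=data).fit()
        if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
            raise StatsError("singular model matrix; design not full rank")
        return fit

    kept = covariates
    if covariates:
        fit0 = _fit(covariates)
        a0 = anova_lm(fit0, typ=3)
        kept = [c for c in covariates if float(a0.loc[c, "PR(>F)"]) <= alpha]
        dropped = [c for c in covariates if c not in kept]

    fit = _fit(kept)
    a3 = anova_lm(fit, typ=3)
    table = _tidy_anova(a3, factors, kept)
    y = data[ycol].to_numpy(float)
    total_corr = float(np.sum((y - y.mean()) ** 2))
    table = pd.concat(
        [
            table,
            pd.DataFrame(
                [{"source": "Total corrected", "ss_type3": total_corr,
                  "df": float(len(y) - 1), "ms": np.nan, "f": np.nan, "p": np.nan}]
            ),
        ],
        ignore_index=True,
    )
    return AnovaResult(
        table=table,
        response=response,
        transform=transform,
        adj_r2=float(fit.rsquared_adj),
        model=fit,
        data=data,
        factors=factors,
        dropped_covariates=dropped,
    )


# ---------------------------------------------------------------------------
# Estimated marginal means + Fisher LSD

@dataclass
class EMMResult:
    """Estimated marginal means of one factor with LSD pairwise tests."""

    factor: str
    means: pd.DataFrame       # level, emm, se, n_cells
    pairwise: pd.DataFrame    # level_a, level_b, estimate, se, t, df, p
    letters: dict             # level -> compact letter display


def _error_stats(result: AnovaResult) -> tuple[float, float]:
    err = result.table.loc[result.table["source"] == "Error"].iloc[0]
    return float(err["ms"]), float(err["df"])


def emm_lsd_pairwise(result: AnovaResult, factor: str) -> EMMResult:
    """Marginal means for one factor with unadjusted (LSD) pairwise t tests.

    The marginal mean of a level is the unweighted average of its cell means
    over the other factor; its variance is MSE/K^2 * sum(1/n_cell).  Pairwise
    differences are tested against t with the error degrees of freedom, with
    no multiplicity adjustment (Fisher's LSD).
    """
    if factor not in result.factors:
        raise StatsError(f"factor {factor!r} was not in the fitted model")
    other = [f for f in result.factors if f != factor][0]
    ycol = result.response if result.transform == "none" else f"log10_{result.response}"
    mse, dfe = _error_stats(result)
    cells = (
        result.data.groupby([factor, other], observed=True)[ycol]
        .agg(["mean", "size"])
        .reset_index()
    )
    rows = []
    for level, grp in cells.groupby(factor, observed=True):
        k = len(grp)
        emm = float(grp["mean"].mean())
        var = mse / k**2 * float((1.0 / grp["size"]).sum())
        rows.append({"level": level, "emm": emm, "se": math.sqrt(max(var, 0.0)),
                     "n_cells": k, "_var": var})
    means = pd.DataFrame(rows).sort_values("emm", ascending=False).reset_index(drop=True)

    pw = []
    for i, j in itertools.combinations(range(len(means)), 2):
        a, b = means.iloc[i], means.iloc[j]
        est = float(a["emm"] - b["emm"])
        se = math.sqrt(a["_var"] + b["_var"])
        if est == 0.0:
            t, p = 0.0, 1.0
        elif se == 0.0:
            t, p = math.inf, 0.0
        else:
            t = est / se
            p = float(2 * sps.t.sf(abs(t), dfe))
        pw.append({"level_a": a["level"], "level_b": b["level"], "estimate": est,
                   "se": se, "t": t, "df": dfe, "p": p})
    pairwise = pd.DataFrame(pw)

    letters = _compact_letters(means["level"].tolist(), pairwise)
    means = means.drop(columns="_var")
    return EMMResult(factor=factor, means=means, pairwise=pairwise, letters=letters)


def _compact_letters(
    levels_by_mean: list, pairwise: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Greedy compact-letter display: levels sharing a letter do not differ."""
    nonsig = {
        frozenset((r.level_a, r.level_b)) for r in pairwise.itertuples() if r.p > alpha
    }
    groups: list[set] = []
    for lv in levels_by_mean:
        placed = False
        for g in groups:
            if all(frozenset((lv, m)) in nonsig for m in g):
                g.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    # absorb redundant subsets
    groups = [g for g in groups if not any(g < h for h in groups if h is not g)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {
        lv: "".join(alphabet[i] for i, g in enumerate(groups) if lv in g)
        for lv in levels_by_mean
    }


# ---------------------------------------------------------------------------
# Assumption checks

@dataclass
class AssumptionReport:
    """Normality and homoscedasticity diagnostics and the transform verdict.

    ``recommendation`` follows a raw-first flow: keep the raw scale when it
    passes both checks; otherwise accept log10 when that passes; otherwise
    proceed on the raw scale, leaning on the robustness of well-replicated
    balanced factorial designs to moderate assumption violations.
    """

    response: str
    shapiro_stat: float
    shapiro_p: float
    levene_stat: float
    levene_p: float
    log10_shapiro_p: float | None
    log10_levene_p: float | None
    recommendation: str
    degenerate: bool = False


def _fit_cells(data, response, factors):
    fit = smf.ols(
        f"Q('{response}') ~ C({factors[0]}) * C({factors[1]})", data=data
    ).fit()
    groups = [
        g[response].to_numpy(float)
        for _, g in data.groupby(list(factors), observed=True)
    ]
    return fit.resid.to_numpy(), groups


def check_assumptions(
    data: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = DEFAULT_FACTORS,
    alpha: float = 0.05,
) -> AssumptionReport:
    """Shapiro-Wilk on cell-model residuals and median-centred Levene across cells."""
    counts = data.groupby(list(factors), observed=True).size()
    if (counts < 3).any():
        raise StatsError("assumption checks need >=3 observations per cell")
    y = data[response].to_numpy(float)
    if np.ptp(y) == 0:
        return AssumptionReport(
            response=response, shapiro_stat=np.nan, shapiro_p=np.nan,
            levene_stat=0.0, levene_p=1.0, log10_shapiro_p=None,
            log10_levene_p=None, recommendation="none", degenerate=True,
        )
    resid, groups = _fit_cells(data, response, factors)
    if np.ptp(resid) <= 1e-10 * max(float(np.ptp(y)), 1.0):
        # cell-saturated data: residuals identically zero, normality moot
        return AssumptionReport(
            response=response, shapiro_stat=np.nan, shapiro_p=np.nan,
            levene_stat=0.0, levene_p=1.0, log10_shapiro_p=None,
            log10_levene_p=None, recommendation="none", degenerate=True,
        )
    sw = sps.shapiro(resid)
    lv = sps.levene(*groups, center="median")
    raw_ok = sw.pvalue > alpha and lv.pvalue > alpha

    log_sw_p = log_lv_p = None
    rec = "none"
    if not raw_ok:
        if (y <= 0).any():
            rec = "proceed_anyway"
        else:
            d2 = data.copy()
            col = f"__log10_{response}"
            d2[col] = np.log10(d2[response])
            resid2, groups2 = _fit_cells(d2, col, factors)
            log_sw_p = float(sps.shapiro(resid2).pvalue)
            log_lv_p = float(sps.levene(*groups2, center="median").pvalue)
            rec = "log10" if (log_sw_p > alpha and log_lv_p > alpha) else "proceed_anyway"
    return AssumptionReport(
        response=response,
        shapiro_stat=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        levene_stat=float(lv.statistic),
        levene_p=float(lv.pvalue),
        log10_shapiro_p=log_sw_p,
        log10_levene_p=log_lv_p,
        recommendation=rec,
    )


def residual_factor_check(
    result: AnovaResult, factors: Sequence[str] | None = None
) -> pd.DataFrame:
    """One-way ANOVA of the model's unstandardised residuals on each factor.

    A solid design leaves residuals unrelated to the factors (F near 0 for
    factors in the model); a significant relationship flags structure the
    model missed.  ``factors`` defaults to the modelled design factors but
    may name any other grouping column present in the data.
    """
    resid = np.asarray(result.model.resid, float)
    rows = []
    for factor in factors if factors is not None else result.factors:
        if factor not in result.data.columns:
            raise StatsError(f"no column {factor!r} in the model data")
        groups = [
            resid[result.data[factor].to_numpy() == lv]
            for lv in pd.unique(result.data[factor])
        ]
        if np.allclose(resid, 0):
            rows.append({"factor": factor, "f": 0.0, "p": 1.0, "degenerate": True})
            continue
        f, p = sps.f_oneway(*groups)
        rows.append({"factor": factor, "f": float(f), "p": float(p),
                     "degenerate": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scalar summaries

@dataclass(frozen=True)
class VariationSummary:
    """Relative range and coefficient of variation of a group of values."""

    label: str
    n: int
    min: float
    max: float
    percent_range: float
    cv: float


def percent_range_variation(values, label: str = "") -> VariationSummary:
    """Spread of a positive-valued trait as (max - min)/min * 100.

    Also reports the coefficient of variation (sample SD / mean * 100).
    Both are rounded to 2 decimals for display.
    """
    v = np.asarray(list(values), float)
    if v.size < 2:
        raise StatsError("need at least 2 values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin <= 0:
        raise StatsError("relative range undefined for nonpositive minimum")
    pr = (vmax - vmin) / vmin * 100.0
    cv = float(v.std(ddof=1) / v.mean() * 100.0)
    return VariationSummary(
        label=label, n=int(v.size), min=vmin, max=vmax,
        percent_range=round(pr, 2), cv=round(cv, 2),
    )


def mortality_chi_square(counts) -> tuple[float, int, float]:
    """Pearson chi-square of independence on an alive/dead contingency table.

    No continuity correction; df = (rows-1)(cols-1).
    """
    table = np.asarray(counts, float)
    if table.ndim != 2:
        raise StatsError("contingency table must be 2-dimensional")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise StatsError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("contingency table has an all-zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cross-approach significance patterns

@dataclass
class SignificancePattern:
    """Boolean significance grid per (approach, response, term) and its diffs.

    ``diff`` lists every (response, term) whose significance verdict is not
    unanimous across approaches -- the quantitative core of the claim that
    the pK'1 sourcing strategy changes the inferred drivers.
    """

    alpha: float
    pattern: pd.DataFrame   # approach, response, term, p, significant
    diff: pd.DataFrame      # response, term, verdicts per approach


def significance_pattern(
    pvalues: pd.DataFrame, alpha: float = 0.05
) -> SignificancePattern:
    """Derive and compare term-significance verdicts across approaches.

    ``pvalues`` must have columns approach, response, term, p, with every
    approach covering the same (response, term) grid.
    """
    required = {"approach", "response", "term", "p"}
    if not required.issubset(pvalues.columns):
        raise StatsError(f"p-value table needs columns {sorted(required)}")
    approaches = sorted(pvalues["approach"].unique())
    grids = {
        a: frozenset(
            map(tuple, pvalues.loc[pvalues["approach"] == a, ["response", "term"]].values)
        )
        for a in approaches
    }
    if len(set(grids.values())) != 1:
        raise StatsError("approaches do not share the same (response, term) grid")
    pattern = pvalues.copy()
    pattern["significant"] = pattern["p"] < alpha

    wide = pattern.pivot(
        index=["response", "term"], columns="approach", values="significant"
    )
    disagree = wide[wide.nunique(axis=1) > 1].reset_index()
    return SignificancePattern(alpha=alpha, pattern=pattern, diff=disagree)
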