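"""End-to-end orchestration: tonometry -> pK' tables -> acid-base results ->
factorial inference -> cross-approach significance comparison.

The canonical run analyses five responses (pH, log10 TCO2, pK'1, log10
pCO2, log10 [HCO3-]) under each pK'1 sourcing strategy.  pH, TCO2 and pK'1
are strategy-invariant by construction (the strategy only changes the
constant used to *calculate* pCO2 and [HCO3-]), so their tables repeat
across approaches; they are kept so that every approach's report is
self-contained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import approaches as ap
from . import stats as st
from . import tonometry as tm
from .chemistry import SolubilityTable
from .io import write_csv

__all__ = ["RunResult", "PipelineError", "run_all", "write_outputs",
           "mortality_table"]

log = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


#: (result column, display label, transform) analysed per approach
RESPONSES = [
    ("ph_cf", "pH", "none"),
    ("tco2_cf_mmol_l", "TCO2", "log10"),
    ("pk1", "pK1", "none"),
    ("pco2_kpa", "pCO2", "log10"),
    ("hco3_mmol_l", "HCO3", "log10"),
]


@dataclass
class RunResult:
    pk_df: pd.DataFrame
    nbb_df: pd.DataFrame
    pk_tables: dict
    results: pd.DataFrame
    comparison: ap.ApproachComparison
    anovas: dict
    emms: dict
    assumptions: dict
    residual_checks: dict
    pattern: st.SignificancePattern
    variation: list
    mortality: tuple | None
    alpha: float
    report: str = ""


def mortality_table(
    individuals: pd.DataFrame, drop_zero_death_groups: bool = True
) -> pd.DataFrame:
    """Alive/dead counts per treatment cell.

    By default treatments without any death are dropped, approximating the
    convention of testing mortality only across the mortality-bearing
    groups (the exact grouping behind published echinoderm survival tests
    is rarely stated; the chi-square itself accepts any contingency table).
    """
    counts = (
        individuals.groupby(["pco2_level", "temperature_c"])["alive"]
        .agg(alive="sum", dead=lambda s: int((~s).sum()))
        .reset_index()
    )
    if drop_zero_death_groups:
        counts = counts[counts["dead"] > 0].reset_index(drop=True)
    return counts


def run_all(
    individuals: pd.DataFrame,
    tonometry: pd.DataFrame,
    alpha: float = 0.05,
    solubility: SolubilityTable | None = None,
    covariates: tuple = ("volume_cm3", "wet_mass_g"),
) -> RunResult:
    """Run the complete analysis on an individuals + tonometry dataset."""
    if solubility is None:
        solubility = SolubilityTable.default()
    alive = individuals.loc[individuals["alive"]].copy()
    alive["individual_id"] = alive["individual_id"].astype(str)
    if alive.empty:
        raise PipelineError("no surviving individuals to analyse")

    tono_ids = set(tonometry["individual_id"].astype(str))
    missing = sorted(set(alive["individual_id"]) - tono_ids)
    if missing:
        raise PipelineError(
            "individual pK'1 strategy requested but these individuals have no "
            f"tonometry series: {missing}"
        )
    tono = tonometry.loc[
        tonometry["individual_id"].astype(str).isin(set(alive["individual_id"]))
    ]

    pk_df = tm.estimate_all(tono, solubility)
    nbb_df = tm.fit_all_nbb(tono, solubility)

    pk_tables = {
        ap.PKSource.INDIVIDUAL: ap.individual_pk_table(pk_df),
        ap.PKSource.SPECIES_MEAN: ap.build_species_mean_table(pk_df, alive),
        ap.PKSource.CROSS_SPECIES: ap.cmaenas_pk_table(),
    }
    results = ap.compute_all(alive, pk_tables, solubility=solubility)
    comparison = ap.compare_approaches(results)

    covs = [
        c for c in covariates
        if c in alive.columns and alive[c].notna().all()
    ]

    anovas, emms, assumptions, residual_checks = {}, {}, {}, {}
    pattern_rows = []
    for source in ap.PKSource:
        res_s = results.loc[results["source"] == source.value]
        frame = alive.merge(
            res_s[["individual_id", "pco2_kpa", "hco3_mmol_l"]], on="individual_id"
        ).merge(pk_df[["individual_id", "pk1"]], on="individual_id")
        for column, label, transform in RESPONSES:
            key = (source.value, label)
            assumptions[key] = st.check_assumptions(frame, column, alpha=alpha)
            anova = st.two_way_anova_type3(
                frame, column, covariates=covs, alpha=alpha, transform=transform
            )
            if anova.dropped_covariates:
                log.warning(
                    "%s/%s: dropped nonsignificant covariate(s) %s",
                    source.value, label, anova.dropped_covariates,
                )
            anovas[key] = anova
            residual_checks[key] = st.residual_factor_check(anova)
            emms[key] = {
                factor: st.emm_lsd_pairwise(anova, factor)
                for factor in anova.factors
            }
            for term in ("pCO2", "Temperature", "Interaction"):
                pattern_rows.append(
                    {"approach": source.value, "response": label, "term": term,
                     "p": anova.p_value(term)}
                )

    pattern = st.significance_pattern(pd.DataFrame(pattern_rows), alpha=alpha)

    variation = [st.percent_range_variation(pk_df["pk1"], label="pK1 overall")]
    for temp, grp in pk_df.groupby("temperature_c"):
        variation.append(
            st.percent_range_variation(grp["pk1"], label=f"pK1 at {temp:g}C")
        )

    mortality = None
    mt = mortality_table(individuals)
    if len(mt) >= 2 and mt["dead"].sum() > 0 and mt["alive"].sum() > 0:
        chi2, dof, p = st.mortality_chi_square(mt[["alive", "dead"]].to_numpy())
        mortality = (chi2, dof, p)

    result = RunResult(
        pk_df=pk_df, nbb_df=nbb_df, pk_tables=pk_tables, results=results,
        comparison=comparison, anovas=anovas, emms=emms, assumptions=assumptions,
        residual_checks=residual_checks, pattern=pattern, variation=variation,
        mortality=mortality, alpha=alpha,
    )
    result.report = _render_report(result)
    return result


def _render_report(r: RunResult) -> str:
    lines = []
    w = lines.append
    w("Coelomic-fluid acid-base analysis report")
    w("=" * 41)
    w("")
    w(f"Individuals analysed: {r.pk_df.shape[0]}   alpha = {r.alpha}")
    w("")
    w("Apparent pK'1 variation")
    w("-----------------------")
    for v in r.variation:
        w(
            f"  {v.label}: n={v.n} range [{v.min:.3f}, {v.max:.3f}] "
            f"spread {v.percent_range:.2f}% (CV {v.cv:.2f}%)"
        )
    w("")
    w("Calculated pCO2 / [HCO3-] ranges by pK'1 strategy (overall)")
    w("-----------------------------------------------------------")
    overall = r.comparison.summary.loc[r.comparison.summary["pco2_level"] == "all"]
    for row in overall.itertuples():
        w(
            f"  {row.source:>13}: pCO2 [{row.pco2_kpa_min:.2f}, {row.pco2_kpa_max:.2f}] kPa"
            f"   HCO3 [{row.hco3_mmol_l_min:.2f}, {row.hco3_mmol_l_max:.2f}] mmol/L"
        )
    for source, wider in r.comparison.wider_range.items():
        verdict = "wider" if wider else "not wider"
        w(f"  individual-strategy pCO2 span is {verdict} than {source}")
    w("")
    w("Type-III ANOVA significance patterns (p < alpha)")
    w("------------------------------------------------")
    pat = r.pattern.pattern
    for (approach, response), grp in pat.groupby(["approach", "response"], sort=False):
        terms = ", ".join(
            f"{t.term}={'*' if t.significant else 'ns'} (p={t.p:.4g})"
            for t in grp.itertuples()
        )
        adj = r.anovas[(approach, response)].adj_r2
        w(f"  {approach:>13} / {response:<5} adjR2={adj:6.3f}  {terms}")
    w("")
    w("Cross-approach significance differences")
    w("---------------------------------------")
    if r.pattern.diff.empty:
        w("  none: all approaches agree on every term")
    else:
        for row in r.pattern.diff.itertuples(index=False):
            w(f"  {row.response} / {row.term}: verdicts differ across approaches")
    w("")
    if r.mortality is not None:
        chi2, dof, p = r.mortality
        w(f"Mortality: chi2 = {chi2:.3f}, df = {dof}, p = {p:.3f}")
    else:
        w("Mortality: not testable (no deaths or a degenerate table)")
    w("")
    return "\n".join(lines)


def anova_frame(r: RunResult) -> pd.DataFrame:
    """All ANOVA tables concatenated into one tidy frame."""
    parts = []
    for (approach, response), a in r.anovas.items():
        t = a.table.copy()
        t.insert(0, "response", response)
        t.insert(0, "approach", approach)
        t["transform"] = a.transform
        t["adj_r2"] = a.adj_r2
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def write_outputs(r: RunResult, out_dir) -> list[Path]:
    """Write every table plus the plain-text report; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [
        write_csv(r.pk_df, out / "pk.csv"),
        write_csv(r.nbb_df, out / "nbb.csv"),
        write_csv(r.results, out / "results.csv"),
        write_csv(r.comparison.summary, out / "comparison_summary.csv"),
        write_csv(r.comparison.deltas, out / "deltas.csv"),
        write_csv(anova_frame(r), out / "anova.csv"),
        write_csv(
            r.pattern.pattern[["response", "approach", "term", "p", "significant"]],
            out / "pattern.csv",
        ),
        write_csv(
            pd.DataFrame([vars(v) for v in r.variation]), out / "variation.csv"
        ),
    ]
    report_path = out / "report.txt"
    report_path.write_text(r.report)
    paths.append(report_path)
    return paths
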