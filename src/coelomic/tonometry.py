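"""Per-individual apparent pK'1 estimation and non-bicarbonate buffer lines.

A tonometry series equilibrates one individual's fluid sample against a
ladder of known CO2 tensions at the individual's own exposure temperature,
measuring pH and TCO2 at each tension.  Each step yields an apparent pK'1
via the Henderson-Hasselbalch point formula; the individual's pK'1 is the
arithmetic mean of the per-step values (the per-step vector and its SD are
retained for auditing).  Plotting derived [HCO3-] against pH along the same
titration and fitting ordinary least squares gives the in-vitro
non-bicarbonate buffer (NBB) line, whose slope summarises buffering by
proteins and other non-bicarbonate buffers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chemistry import (
    ChemistryError,
    GasTension,
    SolubilityTable,
    hco3_from_tco2,
    pk1_from_point,
)

__all__ = [
    "TonometryStep",
    "TonometrySeries",
    "IndividualPK",
    "NBBLine",
    "TonometryError",
    "estimate_individual_pk",
    "fit_nbb_line",
    "series_from_frame",
    "estimate_all",
    "fit_all_nbb",
]

log = logging.getLogger(__name__)


class TonometryError(ValueError):
    """Raised when a series cannot support estimation."""


@dataclass(frozen=True)
class TonometryStep:
    """One equilibration step: set tension, measured pH, measured TCO2."""

    set_tension: GasTension
    measured_ph: float
    measured_tco2: float

    def __post_init__(self) -> None:
        if self.measured_tco2 <= 0:
            raise ValueError("measured TCO2 must be positive")


@dataclass
class TonometrySeries:
    """All equilibration steps for one individual at its exposure temperature."""

    individual_id: str
    temperature: float
    steps: list[TonometryStep]

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise ValueError(
                f"series for {self.individual_id!r} needs at least 2 steps"
            )


@dataclass(frozen=True)
class IndividualPK:
    """An individual's apparent pK'1 with its per-step provenance."""

    individual_id: str
    pk1: float
    per_step_pk: tuple
    sd: float
    n_used: int
    n_excluded: int


@dataclass(frozen=True)
class NBBLine:
    """OLS fit of [HCO3-] (mmol/L) on pH along a CO2 titration."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def _valid_steps(
    series: TonometrySeries, table: SolubilityTable | None
) -> tuple[float, list[TonometryStep], int]:
    """Split a series into usable steps and the count of excluded ones.

    A step is usable when its measured TCO2 exceeds the dissolved CO2 at the
    set tension, so the bicarbonate ratio is strictly positive.  The set
    tension (the gas-mixing pump's nominal value) is taken as the true pCO2.
    """
    if table is None:
        table = SolubilityTable.default()
    alpha = table.alpha_at(series.temperature)
    good, excluded = [], 0
    for step in series.steps:
        if step.measured_tco2 > alpha * step.set_tension.mmhg:
            good.append(step)
        else:
            excluded += 1
    if excluded:
        log.warning(
            "individual %s: excluded %d tonometry step(s) with TCO2 <= alpha*pCO2",
            series.individual_id,
            excluded,
        )
    return alpha, good, excluded


def estimate_individual_pk(
    series: TonometrySeries, table: SolubilityTable | None = None
) -> IndividualPK:
    """Estimate one individual's apparent pK'1 from its tonometry series.

    Per-step pK' values come from :func:`coelomic.chemistry.pk1_from_point`;
    the aggregate is their arithmetic mean and ``sd`` the sample standard
    deviation.  Steps violating TCO2 > alpha*pCO2 are excluded (and counted)
    rather than failing the whole series; fewer than two usable steps is an
    error naming the individual.
    """
    alpha, good, excluded = _valid_steps(series, table)
    if len(good) < 2:
        raise TonometryError(
            f"individual {series.individual_id!r}: only {len(good)} valid "
            "tonometry step(s) after exclusions; at least 2 are required"
        )
    pks = np.array(
        [
            pk1_from_point(s.measured_ph, s.measured_tco2, s.set_tension, alpha)
            for s in good
        ]
    )
    return IndividualPK(
        individual_id=series.individual_id,
        pk1=float(pks.mean()),
        per_step_pk=tuple(float(x) for x in pks),
        sd=float(pks.std(ddof=1)),
        n_used=len(good),
        n_excluded=excluded,
    )


def fit_nbb_line(
    series: TonometrySeries, table: SolubilityTable | None = None
) -> NBBLine:
    """Fit the in-vitro non-bicarbonate buffer line for one individual.

    Per-step [HCO3-] is TCO2 minus dissolved CO2 at the set tension; the
    line is the OLS regression of [HCO3-] (response) on pH (predictor).
    Along a CO2 titration [HCO3-] rises as pH falls, so the slope is
    conventionally negative.
    """
    if table is None:
        table = SolubilityTable.default()
    alpha = table.alpha_at(series.temperature)
    # hco3 >= 0 is enough for the regression, so tco2 == alpha*p is usable here
    usable = [
        s
        for s in series.steps
        if s.measured_tco2 >= alpha * s.set_tension.mmhg
    ]
    if len(usable) < 3:
        raise TonometryError(
            f"individual {series.individual_id!r}: NBB fit needs >=3 valid points, "
            f"got {len(usable)}"
        )
    ph = np.array([s.measured_ph for s in usable])
    hco3 = np.array(
        [hco3_from_tco2(s.measured_tco2, s.set_tension, alpha) for s in usable]
    )
    if np.ptp(ph) == 0:
        raise TonometryError(
            f"individual {series.individual_id!r}: all steps at identical pH; "
            "NBB slope undefined"
        )
    fit = sps.linregress(ph, hco3)
    return NBBLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(usable),
    )


# ---------------------------------------------------------------------------
# Frame-level conveniences (schema: individual_id, temperature_c,
# set_tension_kpa, ph, tco2_mmol_l -- one row per step)

def series_from_frame(df: pd.DataFrame) -> list[TonometrySeries]:
    """Build TonometrySeries objects from a long-format tonometry table."""
    out = []
    for ind, grp in df.groupby("individual_id", sort=True):
        temps = grp["temperature_c"].unique()
        if len(temps) != 1:
            raise TonometryError(
                f"individual {ind!r}: tonometry steps span several temperatures "
                f"{sorted(temps)}; all steps must share the exposure temperature"
            )
        steps = [
            TonometryStep(
                GasTension(float(r.set_tension_kpa), "kPa"),
                float(r.ph),
                float(r.tco2_mmol_l),
            )
            for r in grp.itertuples()
        ]
        out.append(TonometrySeries(str(ind), float(temps[0]), steps))
    return out


def estimate_all(
    df: pd.DataFrame, table: SolubilityTable | None = None
) -> pd.DataFrame:
    """Estimate pK'1 for every individual in a tonometry table."""
    rows = []
    for series in series_from_frame(df):
        pk = estimate_individual_pk(series, table)
        rows.append(
            {
                "individual_id": pk.individual_id,
                "temperature_c": series.temperature,
                "pk1": pk.pk1,
                "sd": pk.sd,
                "n_used": pk.n_used,
                "n_excluded": pk.n_excluded,
            }
        )
    return pd.DataFrame(rows)


def fit_all_nbb(
    df: pd.DataFrame, table: SolubilityTable | None = None
) -> pd.DataFrame:
    """Fit the NBB line for every individual in a tonometry table."""
    rows = []
    for series in series_from_frame(df):
        line = fit_nbb_line(series, table)
        rows.append(
            {
                "individual_id": series.individual_id,
                "temperature_c": series.temperature,
                "slope": line.slope,
                "intercept": line.intercept,
                "r_squared": line.r_squared,
                "n": line.n,
            }
        )
    return pd.DataFrame(rows)
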