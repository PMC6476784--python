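"""In-vivo acid-base variables under three pK'1 sourcing strategies.

The same measured in-vivo pH and TCO2 yield different calculated pCO2 and
[HCO3-] depending on which apparent dissociation constant is plugged into
the Henderson-Hasselbalch equation:

* ``INDIVIDUAL`` -- each animal's own tonometry-derived pK'1;
* ``SPECIES_MEAN`` -- the mean pK'1 of conspecifics in the same treatment
  cell (temperature x seawater-pCO2 level);
* ``CROSS_SPECIES`` -- published constants from another species
  (*Carcinus maenas* hemolymph), keyed by temperature only.

The point of running all three is to quantify how much the sourcing choice
changes both the spread of the calculated variables and the factorial
inference built on them.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .chemistry import (
    GasTension,
    SolubilityTable,
    _load_table,
    hco3_from_tco2,
    pco2_from_state,
)

__all__ = [
    "PKSource",
    "PKTable",
    "AcidBaseResult",
    "ApproachComparison",
    "ApproachError",
    "cmaenas_pk_table",
    "individual_pk_table",
    "build_species_mean_table",
    "compute_acid_base",
    "compute_all",
    "compare_approaches",
]


class ApproachError(ValueError):
    """Raised when a pK' cannot be resolved or result sets are inconsistent."""


class PKSource(enum.Enum):
    INDIVIDUAL = "individual"
    SPECIES_MEAN = "species-mean"
    CROSS_SPECIES = "cross-species"


@dataclass(frozen=True)
class PKTable:
    """pK'1 constants keyed according to their sourcing strategy.

    Keys are individual ids for ``INDIVIDUAL``, ``(pco2_level, temperature)``
    tuples for ``SPECIES_MEAN`` and temperatures for ``CROSS_SPECIES``.
    """

    source: PKSource
    entries: Mapping


def cmaenas_pk_table() -> PKTable:
    """The shipped cross-species constants (decapod hemolymph, by temperature)."""
    return PKTable(
        PKSource.CROSS_SPECIES, dict(_load_table("pk_cmaenas.csv"))
    )


def individual_pk_table(pk_df: pd.DataFrame) -> PKTable:
    """Key each individual's own estimated pK'1 by its id."""
    return PKTable(
        PKSource.INDIVIDUAL,
        dict(zip(pk_df["individual_id"].astype(str), pk_df["pk1"].astype(float))),
    )


def build_species_mean_table(
    pk_df: pd.DataFrame, individuals: pd.DataFrame
) -> PKTable:
    """Average individual pK'1 values within each treatment cell.

    ``pk_df`` carries one estimated pK'1 per individual; ``individuals``
    supplies each individual's treatment assignment (``pco2_level``,
    ``temperature_c``).  Every design cell must contain at least one
    individual with an estimate.
    """
    merged = pk_df.merge(
        individuals[["individual_id", "pco2_level", "temperature_c"]],
        on="individual_id",
        how="left",
        suffixes=("", "_assign"),
    )
    if merged["pco2_level"].isna().any():
        missing = merged.loc[merged["pco2_level"].isna(), "individual_id"].tolist()
        raise ApproachError(f"no treatment assignment for individuals {missing}")
    entries = {}
    for (level, temp), grp in merged.groupby(["pco2_level", "temperature_c"]):
        entries[(str(level), float(temp))] = float(grp["pk1"].mean())
    # verify completeness of the crossing actually present in the design
    levels = sorted(individuals["pco2_level"].astype(str).unique())
    temps = sorted(individuals["temperature_c"].astype(float).unique())
    for cell in itertools.product(levels, temps):
        if cell not in entries:
            raise ApproachError(
                f"design cell {cell} has no individual pK'1 estimate"
            )
    return PKTable(PKSource.SPECIES_MEAN, entries)


def resolve_pk(
    record: Mapping, source: PKSource, pk_tables: Mapping[PKSource, PKTable]
) -> float:
    """Pick the pK'1 a given strategy assigns to one individual record."""
    if source not in pk_tables:
        raise ApproachError(f"no pK' table supplied for source {source}")
    table = pk_tables[source]
    if source is PKSource.INDIVIDUAL:
        key = str(record["individual_id"])
    elif source is PKSource.SPECIES_MEAN:
        key = (str(record["pco2_level"]), float(record["temperature_c"]))
    else:
        key = float(record["temperature_c"])
    try:
        return float(table.entries[key])
    except KeyError:
        raise ApproachError(
            f"{source.value} pK' table has no entry for key {key!r} "
            f"(individual {record['individual_id']!r})"
        ) from None


@dataclass(frozen=True)
class AcidBaseResult:
    """Calculated in-vivo pCO2 and [HCO3-] for one individual, one strategy."""

    individual_id: str
    source: PKSource
    pk_used: float
    pco2_kpa: float
    hco3_mmol_l: float

    def __post_init__(self) -> None:
        if self.pco2_kpa <= 0:
            raise ValueError("calculated pCO2 must be positive")
        if self.hco3_mmol_l < 0:
            raise ValueError("calculated [HCO3-] must be nonnegative")


def compute_acid_base(
    record: Mapping,
    source: PKSource,
    pk_tables: Mapping[PKSource, PKTable],
    solubility: SolubilityTable | None = None,
) -> AcidBaseResult:
    """Calculate one individual's in-vivo pCO2 (kPa) and [HCO3-] (mmol/L).

    The record's measured pH and TCO2 are never altered by the strategy;
    only the pK'1 plugged into the equilibrium differs.
    """
    if solubility is None:
        solubility = SolubilityTable.default()
    pk = resolve_pk(record, source, pk_tables)
    alpha = solubility.alpha_at(float(record["temperature_c"]))
    tco2 = float(record["tco2_cf_mmol_l"])
    ph = float(record["ph_cf"])
    pco2 = pco2_from_state(tco2, ph, pk, alpha)
    hco3 = hco3_from_tco2(tco2, pco2, alpha)
    return AcidBaseResult(
        individual_id=str(record["individual_id"]),
        source=source,
        pk_used=pk,
        pco2_kpa=pco2.kpa,
        hco3_mmol_l=hco3,
    )


def compute_all(
    individuals: pd.DataFrame,
    pk_tables: Mapping[PKSource, PKTable],
    sources: tuple[PKSource, ...] = tuple(PKSource),
    solubility: SolubilityTable | None = None,
) -> pd.DataFrame:
    """Acid-base results for every individual under every requested strategy.

    Returns a long table with columns individual_id, source, pk_used,
    pco2_kpa, hco3_mmol_l, temperature_c, pco2_level.
    """
    rows = []
    for rec in individuals.to_dict("records"):
        for source in sources:
            res = compute_acid_base(rec, source, pk_tables, solubility)
            rows.append(
                {
                    "individual_id": res.individual_id,
                    "source": source.value,
                    "pk_used": res.pk_used,
                    "pco2_kpa": res.pco2_kpa,
                    "hco3_mmol_l": res.hco3_mmol_l,
                    "temperature_c": float(rec["temperature_c"]),
                    "pco2_level": str(rec["pco2_level"]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ApproachComparison:
    """Cross-strategy divergence summary.

    ``summary`` holds per-source min/max/mean/SD of pCO2 and [HCO3-] per
    treatment cell and overall; ``deltas`` per-individual pairwise
    differences between sources; ``wider_range`` flags, for each mean-based
    source, whether the individual-strategy pCO2 span exceeds that source's
    span.
    """

    summary: pd.DataFrame
    deltas: pd.DataFrame
    wider_range: dict


def compare_approaches(results: pd.DataFrame) -> ApproachComparison:
    """Summarise how the pK'1 sourcing strategies diverge."""
    sources = sorted(results["source"].unique())
    if len(sources) < 2:
        raise ApproachError("comparison needs results from at least 2 sources")
    id_sets = {
        s: frozenset(results.loc[results["source"] == s, "individual_id"])
        for s in sources
    }
    if len(set(id_sets.values())) != 1:
        raise ApproachError(
            "sources cover different individual sets; cannot compare: "
            + ", ".join(f"{s}: n={len(ids)}" for s, ids in id_sets.items())
        )

    def _describe(grp: pd.DataFrame) -> pd.Series:
        out = {}
        for var in ("pco2_kpa", "hco3_mmol_l"):
            v = grp[var]
            out.update(
                {
                    f"{var}_min": v.min(),
                    f"{var}_max": v.max(),
                    f"{var}_mean": v.mean(),
                    f"{var}_sd": v.std(ddof=1),
                }
            )
        out["n"] = len(grp)
        return pd.Series(out)

    per_cell = (
        results.groupby(["source", "pco2_level", "temperature_c"])
        .apply(_describe, include_groups=False)
        .reset_index()
    )
    overall = results.groupby("source").apply(_describe, include_groups=False).reset_index()
    overall["pco2_level"] = "all"
    overall["temperature_c"] = np.nan
    summary = pd.concat([per_cell, overall], ignore_index=True)

    wide = results.pivot(
        index="individual_id", columns="source", values=["pco2_kpa", "hco3_mmol_l"]
    )
    delta_rows = []
    for a, b in itertools.combinations(sources, 2):
        d = pd.DataFrame(
            {
                "individual_id": wide.index,
                "source_a": a,
                "source_b": b,
                "delta_pco2_kpa": (wide[("pco2_kpa", a)] - wide[("pco2_kpa", b)]).values,
                "delta_hco3_mmol_l": (
                    wide[("hco3_mmol_l", a)] - wide[("hco3_mmol_l", b)]
                ).values,
            }
        )
        delta_rows.append(d)
    deltas = pd.concat(delta_rows, ignore_index=True)

    wider = {}
    ind = PKSource.INDIVIDUAL.value
    if ind in sources:
        ind_span = (
            results.loc[results["source"] == ind, "pco2_kpa"].max()
            - results.loc[results["source"] == ind, "pco2_kpa"].min()
        )
        for s in sources:
            if s == ind:
                continue
            span = (
                results.loc[results["source"] == s, "pco2_kpa"].max()
                - results.loc[results["source"] == s, "pco2_kpa"].min()
            )
            wider[s] = bool(ind_span > span)
    return ApproachComparison(summary=summary, deltas=deltas, wider_range=wider)
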