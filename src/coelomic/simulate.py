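"""Synthetic study generator for the crossed temperature x pCO2 design.

Emulates a factorial exposure of ~21 sea urchins per cell to three seawater
temperatures (10, 15, 20 degC) crossed with two seawater pCO2 levels
(ambient ~380-390 uatm, elevated ~1000 uatm), producing per-individual
in-vivo acid-base records plus an in-vitro tonometry series per survivor,
so every pipeline stage is testable without external data.

Generative model, per individual in a design cell:

* an apparent dissociation constant ``true_pk1 ~ Normal(mu_pk[cell],
  sigma_pk)`` truncated to a plausible envelope -- this is the in-vitro
  constant the tonometry series is built from and that pK' estimation
  should recover;
* a physiologically structured state: true [HCO3-] carries the
  seawater-pCO2 main effect (plus optional temperature/interaction terms)
  and true pCO2 the temperature main effect, with multiplicative
  log-normal noise on pCO2 and additive noise on [HCO3-];
* the recorded in-vivo pH closes the Henderson-Hasselbalch equilibrium and
  TCO2 = [HCO3-] + alpha*pCO2.

Which pK' the in-vivo pH is closed with is configurable
(``pk_in_vivo``).  The default, ``"treatment_mean"``, closes it with the
cell-mean constant: the individual spread in the apparent constant is then
an in-vitro phenomenon not mirrored in the in-vivo chemistry, which is the
regime under which calculating pCO2 with each individual's own constant
yields a wider spread than mean-constant strategies -- the ordering
observed in real urchin data.  ``"individual"`` closes the equilibrium with
the individual's own constant instead, making every record exactly
round-trip consistent with its ``true_pk1`` (useful for end-to-end
recovery tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .chemistry import (
    MMHG_PER_KPA,
    GasTension,
    SolubilityTable,
    pco2_from_state,
)
from .tonometry import TonometrySeries, TonometryStep

__all__ = ["SimConfig", "IndividualRecord", "SimulationError",
           "generate_study", "generate_tonometry"]


class SimulationError(RuntimeError):
    """Raised when the generator cannot satisfy its envelopes."""


def _default_mu_pk() -> dict:
    return {
        ("ambient", 10.0): 6.445, ("ambient", 15.0): 6.256, ("ambient", 20.0): 6.158,
        ("elevated", 10.0): 6.466, ("elevated", 15.0): 6.281, ("elevated", 20.0): 6.069,
    }


def _default_mortality() -> dict:
    # deaths occurred in four of the six treatments; none in the two
    # ambient-pCO2 warmed treatments
    return {
        ("ambient", 10.0): 0.09, ("ambient", 15.0): 0.0, ("ambient", 20.0): 0.0,
        ("elevated", 10.0): 0.09, ("elevated", 15.0): 0.09, ("elevated", 20.0): 0.09,
    }


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic generator.

    Defaults encode the study conditions the package targets: 21
    individuals per cell (design range 19-23), cell-mean apparent constants
    matching the six treatment means, individual pK' spread wide enough to
    span roughly 5.5-7.5 across the study, tonometry tensions within
    0.04-1.01 kPa, and a negative decrease of true pCO2 at the warmest
    temperature with a positive seawater-pCO2 effect on true [HCO3-].
    """

    n_per_cell: int = 21
    temperatures: tuple = (10.0, 15.0, 20.0)
    pco2_levels: tuple = ("ambient", "elevated")
    mu_pk: Mapping = field(default_factory=_default_mu_pk)
    sigma_pk: float = 0.35
    pk_envelope: tuple = (5.50, 7.51)
    # true physiology: temperature main effect on pCO2 (kPa), seawater-pCO2
    # main effect on [HCO3-] (mmol/L)
    mu_pco2_kpa: Mapping = field(
        default_factory=lambda: {10.0: 0.90, 15.0: 0.85, 20.0: 0.40}
    )
    pco2_level_effect: Mapping = field(
        default_factory=lambda: {"ambient": 1.0, "elevated": 1.0}
    )
    sigma_log10_pco2: float = 0.18
    mu_hco3: Mapping = field(
        default_factory=lambda: {10.0: 4.6, 15.0: 5.0, 20.0: 3.8}
    )
    hco3_elevated_delta: float = 1.4
    hco3_interaction: Mapping | None = None
    sigma_hco3: float = 0.8
    # recorded-value envelopes (redraw until satisfied)
    ph_envelope: tuple = (6.05, 8.07)
    tco2_envelope: tuple = (1.4, 8.8)
    # tonometry
    tensions_kpa: tuple = (0.04, 0.234, 0.428, 0.622, 0.816, 1.01)
    sigma_ph: float = 0.02
    sigma_tco2: float = 0.05
    nbb_slope: float = -2.0
    pk_in_vivo: str = "treatment_mean"
    mortality_p: Mapping | float = field(default_factory=_default_mortality)
    seed: int | None = None
    max_redraws: int = 100

    def validate(self) -> None:
        for name in ("sigma_pk", "sigma_log10_pco2", "sigma_hco3",
                     "sigma_ph", "sigma_tco2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be at least 1")
        if self.pk_in_vivo not in ("treatment_mean", "individual"):
            raise ValueError(
                f"pk_in_vivo must be 'treatment_mean' or 'individual', "
                f"got {self.pk_in_vivo!r}"
            )
        for t in self.tensions_kpa:
            if not (0.04 <= t <= 1.01):
                raise ValueError(
                    f"tonometry tension {t} kPa outside the supported "
                    "range [0.04, 1.01]"
                )
        for lvl in self.pco2_levels:
            for t in self.temperatures:
                if (lvl, float(t)) not in _as_cell_map(self.mu_pk, self):
                    raise ValueError(f"mu_pk missing design cell {(lvl, t)}")

    def cells(self) -> list[tuple[str, float]]:
        return [
            (lvl, float(t)) for lvl in self.pco2_levels for t in self.temperatures
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("mu_pk", "hco3_interaction", "mortality_p"):
            val = d[key]
            if isinstance(val, dict):
                d[key] = {f"{k[0]}@{k[1]:g}": v for k, v in val.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("mu_pk", "hco3_interaction", "mortality_p"):
            val = d.get(key)
            if isinstance(val, Mapping):
                parsed = {}
                for k, v in val.items():
                    if isinstance(k, str) and "@" in k:
                        lvl, t = k.split("@")
                        parsed[(lvl, float(t))] = float(v)
                    else:
                        parsed[k] = v
                d[key] = parsed
        for key in ("temperatures", "pco2_levels", "tensions_kpa",
                    "pk_envelope", "ph_envelope", "tco2_envelope"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        for key in ("mu_pco2_kpa", "mu_hco3"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = {float(k): float(v) for k, v in d[key].items()}
        return cls(**d)


def _as_cell_map(m, config) -> Mapping:
    if isinstance(m, Mapping):
        return {(str(k[0]), float(k[1])): float(v) for k, v in m.items()}
    return {cell: float(m) for cell in config.cells()}


@dataclass(frozen=True)
class IndividualRecord:
    """One urchin: treatment, simulation truth, in-vivo state, morphometrics."""

    individual_id: str
    temperature_c: float
    pco2_level: str
    true_pk1: float
    ph_cf: float
    tco2_cf_mmol_l: float
    test_height_mm: float
    test_diameter_mm: float
    volume_cm3: float
    wet_mass_g: float
    alive: bool


def spheroid_volume_cm3(diameter_mm: float, height_mm: float) -> float:
    """Oblate-spheroid test volume, equatorial axis = diameter, polar = height."""
    d, h = diameter_mm / 10.0, height_mm / 10.0
    return (4.0 / 3.0) * math.pi * (d / 2.0) ** 2 * (h / 2.0)


def _draw_individual(
    rng: np.random.Generator,
    config: SimConfig,
    cell: tuple[str, float],
    alpha: float,
    ident: str,
) -> IndividualRecord:
    level, temp = cell
    mu_pk = _as_cell_map(config.mu_pk, config)[cell]
    inter = 0.0
    if config.hco3_interaction:
        inter = _as_cell_map(config.hco3_interaction, config).get(cell, 0.0)
    mort = _as_cell_map(config.mortality_p, config)[cell]

    for _ in range(config.max_redraws):
        pk = rng.normal(mu_pk, config.sigma_pk)
        pco2_kpa = (
            config.mu_pco2_kpa[temp]
            * config.pco2_level_effect[level]
            * 10.0 ** rng.normal(0.0, config.sigma_log10_pco2)
        )
        hco3 = (
            config.mu_hco3[temp]
            + (config.hco3_elevated_delta if level == "elevated" else 0.0)
            + inter
            + rng.normal(0.0, config.sigma_hco3)
        )
        height = rng.normal(22.0, 2.5)
        diameter = rng.normal(45.0, 4.0)
        alive = bool(rng.random() >= mort)
        if hco3 <= 0.2 or height <= 10 or diameter <= 20:
            continue
        if not (config.pk_envelope[0] <= pk <= config.pk_envelope[1]):
            continue
        aco2 = alpha * pco2_kpa * MMHG_PER_KPA
        tco2 = hco3 + aco2
        pk_eff = pk if config.pk_in_vivo == "individual" else mu_pk
        ph = pk_eff + math.log10(hco3 / aco2)
        if not (config.ph_envelope[0] <= ph <= config.ph_envelope[1]):
            continue
        if not (config.tco2_envelope[0] <= tco2 <= config.tco2_envelope[1]):
            continue
        volume = spheroid_volume_cm3(diameter, height)
        mass = max(rng.normal(1.08 * volume, 2.0), 1.0)
        return IndividualRecord(
            individual_id=ident,
            temperature_c=temp,
            pco2_level=level,
            true_pk1=float(pk),
            ph_cf=float(ph),
            tco2_cf_mmol_l=float(tco2),
            test_height_mm=float(height),
            test_diameter_mm=float(diameter),
            volume_cm3=float(volume),
            wet_mass_g=float(mass),
            alive=alive,
        )
    raise SimulationError(
        f"could not draw an individual within the configured envelopes for "
        f"cell {cell} after {config.max_redraws} attempts; widen the envelopes "
        "or reduce the noise parameters"
    )


def generate_tonometry(
    record: IndividualRecord,
    config: SimConfig,
    rng: np.random.Generator,
    table: SolubilityTable | None = None,
) -> TonometrySeries:
    """Simulate one individual's tonometry series.

    Each configured tension yields the exact (pH, TCO2) point consistent
    with the individual's ``true_pk1`` and a non-bicarbonate buffer line of
    configured slope anchored at the individual's in-vitro state, then
    Gaussian measurement noise (``sigma_ph``, ``sigma_tco2``) is added.
    """
    if not record.alive:
        raise SimulationError(
            f"individual {record.individual_id} did not survive; no tonometry"
        )
    if table is None:
        table = SolubilityTable.default()
    try:
        alpha = table.alpha_at(record.temperature_c)
    except KeyError as exc:
        raise SimulationError(
            f"tonometry temperature {record.temperature_c} not covered by the "
            "solubility table"
        ) from exc

    # anchor the buffer line at the sample's own consistent decomposition
    pco2_iv = pco2_from_state(
        record.tco2_cf_mmol_l, record.ph_cf, record.true_pk1, alpha
    ).mmhg
    hco3_iv = record.tco2_cf_mmol_l - alpha * pco2_iv
    s = config.nbb_slope
    c = hco3_iv - s * record.ph_cf
    pk = record.true_pk1

    steps = []
    for tension in config.tensions_kpa:
        p = tension * MMHG_PER_KPA
        aco2 = alpha * p

        def _gap(h: float) -> float:
            return c + s * (pk + math.log10(h / aco2)) - h

        hco3 = brentq(_gap, 1e-9, 1e4)
        # define pH from the root so the step is exactly equilibrium-consistent
        ph = pk + math.log10(hco3 / aco2)
        tco2 = hco3 + aco2
        steps.append(
            TonometryStep(
                set_tension=GasTension(tension, "kPa"),
                measured_ph=float(ph + rng.normal(0.0, config.sigma_ph)),
                measured_tco2=float(
                    max(tco2 + rng.normal(0.0, config.sigma_tco2), 1e-6)
                ),
            )
        )
    return TonometrySeries(record.individual_id, record.temperature_c, steps)


def generate_study(
    config: SimConfig | None = None,
    seed: int | None = None,
    table: SolubilityTable | None = None,
) -> tuple[list[IndividualRecord], list[TonometrySeries]]:
    """Generate a full synthetic study: records plus tonometry for survivors.

    Deterministic given the seed (taken from the argument, falling back to
    ``config.seed``; one of the two is required).
    """
    if config is None:
        config = SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    rng = np.random.default_rng(seed)
    if table is None:
        table = SolubilityTable.default()

    records: list[IndividualRecord] = []
    series: list[TonometrySeries] = []
    for level, temp in config.cells():
        alpha = table.alpha_at(temp)
        for i in range(config.n_per_cell):
            ident = f"{level[:3]}{temp:g}_{i + 1:02d}"
            rec = _draw_individual(rng, config, (level, temp), alpha, ident)
            records.append(rec)
            if rec.alive:
                series.append(generate_tonometry(rec, config, rng, table))
    return records, series
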