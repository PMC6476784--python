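"""Carbonate chemistry of extracellular body fluids.

The CO2/bicarbonate system in a biological fluid is summarised by the
Henderson-Hasselbalch equilibrium

    pH = pK'1 + log10([HCO3-] / (alpha * pCO2))

where ``alpha`` is the physical solubility of CO2 in the fluid
(mmol L-1 mmHg-1, temperature dependent) and pK'1 is the *apparent* first
dissociation constant, an operational constant that absorbs ionic-strength
and protein effects and therefore has to be measured in the fluid of
interest.  Total CO2 content closes the system:

    TCO2 = [HCO3-] + alpha * pCO2

This module provides gas-tension units, the solubility lookup table and the
four re-arrangements of the equilibrium that the rest of the package
composes: apparent-pK from a measured point, in-vivo pCO2 from pH and TCO2,
and bicarbonate from TCO2.

All internal pressure arithmetic is done in mmHg because alpha is tabulated
per mmHg; kPa appears only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "MMHG_PER_KPA",
    "GasTension",
    "SolubilityTable",
    "AcidBaseState",
    "ChemistryError",
    "UnitError",
    "convert_pressure",
    "alpha_at",
    "pk1_from_point",
    "pco2_from_state",
    "hco3_from_tco2",
]

#: Exact conversion factor: 1 kPa = 7.500617 mmHg (1 mmHg = 0.1333224 kPa).
MMHG_PER_KPA = 7.500617

_UNITS = ("kPa", "mmHg")


class ChemistryError(ValueError):
    """Raised when inputs are outside the domain of an equilibrium formula."""


class UnitError(ValueError):
    """Raised for an unrecognised pressure unit."""


@dataclass(frozen=True)
class GasTension:
    """A nonnegative gas partial pressure tagged with its unit."""

    value: float
    unit: str = "kPa"

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise UnitError(
                f"unknown pressure unit {self.unit!r}; expected one of {_UNITS}"
            )
        if not np.all(np.asarray(self.value) >= 0):
            raise ValueError(f"gas tension must be nonnegative, got {self.value}")

    @property
    def mmhg(self) -> float:
        """Value expressed in mmHg."""
        return self.value if self.unit == "mmHg" else self.value * MMHG_PER_KPA

    @property
    def kpa(self) -> float:
        """Value expressed in kPa."""
        return self.value if self.unit == "kPa" else self.value / MMHG_PER_KPA

    def to(self, unit: str) -> "GasTension":
        return convert_pressure(self, unit)


def convert_pressure(t: GasTension, target_unit: str) -> GasTension:
    """Convert a :class:`GasTension` between kPa and mmHg.

    Conversion uses multiplication by ``MMHG_PER_KPA`` in one direction and
    division in the other, so a round trip returns the input to within one
    ulp.  Converting to the tension's own unit returns it unchanged.
    """
    if target_unit not in _UNITS:
        raise UnitError(
            f"unknown pressure unit {target_unit!r}; expected one of {_UNITS}"
        )
    if target_unit == t.unit:
        return t
    if target_unit == "mmHg":
        return GasTension(t.value * MMHG_PER_KPA, "mmHg")
    return GasTension(t.value / MMHG_PER_KPA, "kPa")


def _load_table(name: str) -> list[tuple[float, float]]:
    rows = []
    text = resources.files("coelomic.data").joinpath(name).read_text()
    for line in text.strip().splitlines()[1:]:
        a, b = line.split(",")
        rows.append((float(a), float(b)))
    return rows


@dataclass(frozen=True)
class SolubilityTable:
    """CO2 solubility coefficients alpha (mmol L-1 mmHg-1) by temperature (degC).

    The shipped default holds the decapod (*Carcinus maenas*) hemolymph
    values 0.058, 0.050 and 0.043 mmol L-1 mmHg-1 at 10, 15 and 20 degC,
    conventionally borrowed for other marine ectotherm extracellular fluids.
    Physical solubility falls with temperature, and the table enforces that.
    """

    entries: Mapping[float, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("solubility table must not be empty")
        temps = sorted(self.entries)
        alphas = [self.entries[t] for t in temps]
        if any(a <= 0 for a in alphas):
            raise ValueError("all solubility coefficients must be positive")
        if any(b >= a for a, b in zip(alphas, alphas[1:])):
            raise ValueError("solubility must strictly decrease with temperature")
        object.__setattr__(self, "entries", dict(zip(temps, alphas)))

    @classmethod
    def default(cls) -> "SolubilityTable":
        return cls(dict(_load_table("solubility.csv")))

    @classmethod
    def from_csv(cls, path) -> "SolubilityTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(dict(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float))))

    def alpha_at(self, temperature: float, interpolate: bool = False) -> float:
        return alpha_at(temperature, self, interpolate=interpolate)


def alpha_at(
    temperature: float,
    table: SolubilityTable | None = None,
    interpolate: bool = False,
) -> float:
    """Look up the CO2 solubility coefficient at a temperature.

    By default the lookup is strict (the factorial designs this package
    targets use a small set of fixed temperatures).  With
    ``interpolate=True`` the value is linearly interpolated between the
    bracketing tabulated temperatures; extrapolation is refused.
    """
    if table is None:
        table = SolubilityTable.default()
    temps = sorted(table.entries)
    for t in temps:
        if math.isclose(t, temperature, rel_tol=0.0, abs_tol=1e-9):
            return table.entries[t]
    if not interpolate:
        raise KeyError(
            f"temperature {temperature} degC is not tabulated "
            f"(stored: {temps}); pass interpolate=True for linear interpolation"
        )
    if temperature < temps[0] or temperature > temps[-1]:
        raise ValueError(
            f"temperature {temperature} degC outside tabulated range "
            f"[{temps[0]}, {temps[-1]}]; extrapolation is not supported"
        )
    return float(np.interp(temperature, temps, [table.entries[t] for t in temps]))


def _as_mmhg(pco2: GasTension | float) -> float:
    """Accept a GasTension or a bare number already in mmHg."""
    if isinstance(pco2, GasTension):
        return pco2.mmhg
    return float(pco2)


def pk1_from_point(
    ph: float, tco2: float, pco2: GasTension | float, alpha: float
) -> float:
    """Apparent first dissociation constant from one equilibrated point.

    pK'1 = pH - log10((TCO2 - alpha*pCO2) / (alpha*pCO2)), pCO2 in mmHg.
    This is the working form used on each tonometry step, where the fluid
    has been equilibrated at a known CO2 tension and its pH and TCO2
    measured.
    """
    p = _as_mmhg(pco2)
    if p <= 0:
        raise ChemistryError("pCO2 must be positive to define the dissolved fraction")
    if alpha <= 0:
        raise ChemistryError("solubility coefficient must be positive")
    dissolved = alpha * p
    if tco2 <= dissolved:
        raise ChemistryError(
            f"TCO2 ({tco2}) must exceed dissolved CO2 (alpha*pCO2 = {dissolved:.6g}); "
            "the bicarbonate ratio would be nonpositive and its log undefined"
        )
    return ph - math.log10((tco2 - dissolved) / dissolved)


def pco2_from_state(
    tco2: float, ph: float, pk1: float, alpha: float
) -> GasTension:
    """In-vivo CO2 tension from measured TCO2 and pH given an apparent pK'1.

    pCO2 = TCO2 / (alpha * (10**(pH - pK'1) + 1)), returned in mmHg
    (convert with :func:`convert_pressure` for kPa reporting).  Exact
    algebraic inverse of :func:`pk1_from_point`.
    """
    if tco2 <= 0:
        raise ChemistryError("TCO2 must be positive")
    if alpha <= 0:
        raise ChemistryError("solubility coefficient must be positive")
    mmhg = tco2 / (alpha * (10.0 ** (ph - pk1) + 1.0))
    return GasTension(mmhg, "mmHg")


def hco3_from_tco2(
    tco2: float, pco2: GasTension | float, alpha: float
) -> float:
    """Bicarbonate as total CO2 minus the physically dissolved fraction.

    [HCO3-] = TCO2 - alpha*pCO2 (pCO2 in mmHg).
    """
    if alpha <= 0:
        raise ChemistryError("solubility coefficient must be positive")
    p = _as_mmhg(pco2)
    hco3 = tco2 - alpha * p
    if hco3 < 0:
        raise ChemistryError(
            f"inconsistent inputs: dissolved CO2 (alpha*pCO2 = {alpha * p:.6g}) "
            f"exceeds TCO2 ({tco2})"
        )
    return hco3


@dataclass(frozen=True)
class AcidBaseState:
    """A complete, internally consistent acid-base state of a fluid sample."""

    ph: float
    tco2: float
    pco2: GasTension
    hco3: float
    pk1: float
    temperature: float

    def __post_init__(self) -> None:
        if not (4.0 <= self.ph <= 10.0):
            raise ValueError(f"pH {self.ph} outside the plausible range [4, 10]")
        if self.hco3 < 0:
            raise ValueError("bicarbonate must be nonnegative")

    def check_conservation(self, alpha: float, rel_tol: float = 1e-9) -> None:
        """Assert TCO2 = [HCO3-] + alpha*pCO2 to a relative tolerance."""
        resid = self.tco2 - self.hco3 - alpha * self.pco2.mmhg
        if abs(resid) > rel_tol * max(abs(self.tco2), 1.0):
            raise ChemistryError(
                f"mass conservation violated: residual {resid:.3e} for TCO2 {self.tco2}"
            )
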