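"""CSV interchange, schema validation and run manifests.

All tabular interchange is RFC-4180 CSV, UTF-8, '.' decimal.  Schemas:

* ``individuals.csv`` -- individual_id, temperature_c, pco2_level, ph_cf,
  tco2_cf_mmol_l, test_height_mm, test_diameter_mm, volume_cm3, wet_mass_g,
  alive (+ true_pk1 when the file was simulated);
* ``tonometry.csv`` -- individual_id, temperature_c, set_tension_kpa, ph,
  tco2_mmol_l (one row per equilibration step);
* ``results.csv`` -- individual_id, source, pk_used, pco2_kpa, hco3_mmol_l,
  temperature_c, pco2_level.

Every pipeline output directory gets a ``manifest.json`` recording the
command, configuration snapshot, seed and SHA-256 digests of the files
written, so results are traceable to their run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .simulate import IndividualRecord
from .tonometry import TonometrySeries

__all__ = [
    "SchemaError",
    "INDIVIDUALS_COLUMNS",
    "TONOMETRY_COLUMNS",
    "records_to_frame",
    "tonometry_to_frame",
    "read_individuals",
    "read_tonometry",
    "write_csv",
    "write_manifest",
]


class SchemaError(ValueError):
    """Raised when an input table does not match its expected schema."""


INDIVIDUALS_COLUMNS = [
    "individual_id", "temperature_c", "pco2_level", "ph_cf", "tco2_cf_mmol_l",
    "test_height_mm", "test_diameter_mm", "volume_cm3", "wet_mass_g", "alive",
]
TONOMETRY_COLUMNS = [
    "individual_id", "temperature_c", "set_tension_kpa", "ph", "tco2_mmol_l",
]


def records_to_frame(records: list[IndividualRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    cols = INDIVIDUALS_COLUMNS + ["true_pk1"]
    return df[[c for c in cols if c in df.columns]]


def tonometry_to_frame(series: list[TonometrySeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for step in s.steps:
            rows.append(
                {
                    "individual_id": s.individual_id,
                    "temperature_c": s.temperature,
                    "set_tension_kpa": step.set_tension.kpa,
                    "ph": step.measured_ph,
                    "tco2_mmol_l": step.measured_tco2,
                }
            )
    return pd.DataFrame(rows, columns=TONOMETRY_COLUMNS)


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_individuals(path) -> pd.DataFrame:
    """Read and validate an individuals table."""
    df = pd.read_csv(path)
    _require(df, INDIVIDUALS_COLUMNS[:5], f"individuals file {path}")
    df["individual_id"] = df["individual_id"].astype(str)
    for col in ("temperature_c", "ph_cf", "tco2_cf_mmol_l"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df["individual_id"].duplicated().any():
        dups = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise SchemaError(f"duplicate individual ids: {dups}")
    if not df["ph_cf"].between(4, 10).all():
        raise SchemaError("ph_cf values outside the plausible range [4, 10]")
    if (df["tco2_cf_mmol_l"] <= 0).any():
        raise SchemaError("tco2_cf_mmol_l must be positive")
    if "alive" in df.columns:
        df["alive"] = df["alive"].astype(bool)
    else:
        df["alive"] = True
    return df


def read_tonometry(path) -> pd.DataFrame:
    """Read and validate a tonometry-step table."""
    df = pd.read_csv(path)
    _require(df, TONOMETRY_COLUMNS, f"tonometry file {path}")
    df["individual_id"] = df["individual_id"].astype(str)
    for col in TONOMETRY_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["set_tension_kpa"] < 0).any():
        raise SchemaError("set_tension_kpa must be nonnegative")
    if (df["tco2_mmol_l"] <= 0).any():
        raise SchemaError("tco2_mmol_l must be positive")
    return df


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir, command: str, config: dict | None, seed: int | None, files: list
) -> Path:
    """Record command, config, seed and output digests for one run."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "files": {str(Path(f).name): _sha256(f) for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
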