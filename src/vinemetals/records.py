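"""Tidy concentration records: schema, validation, I/O and grouped summaries.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per element measurement (a replicate mean with its standard deviation
and replicate count) for a given sampling area, cultivar and compartment.
Soil rows additionally carry a depth interval; must and wine rows are
expressed in mg/L after loading, soil and plant tissue in mg/kg dry weight.

Left-censored measurements (below the limit of quantification) are kept as
rows with ``value = 0`` and ``censored = True`` so that grouped averages
treat them as zero while the censored count stays visible in summaries.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

ELEMENTS = ("Cu", "Zn", "Pb", "Cd", "Ni", "Co", "As", "Cr", "Hg")
COMPARTMENTS = ("soil", "root", "cane", "leaf", "grape", "must", "wine")
PLANT_COMPARTMENTS = ("root", "cane", "leaf", "grape")
BEVERAGE_COMPARTMENTS = ("must", "wine")
DEPTHS = ("0-20", "20-40", "40-60", "60-80")

#: canonical reporting unit per compartment
CANONICAL_UNITS = {
    **{c: "mg/kg DW" for c in ("soil",) + PLANT_COMPARTMENTS},
    **{c: "mg/L" for c in BEVERAGE_COMPARTMENTS},
}

#: multiplicative conversion into the canonical unit of the same dimension
_UNIT_FACTORS = {"mg/kg DW": 1.0, "mg/L": 1.0, "ug/L": 1e-3, "µg/L": 1e-3}

RECORD_COLUMNS = [
    "area", "distance_km", "variety", "compartment", "depth_cm",
    "element", "value", "sd", "n", "unit", "censored",
]

_CENSOR_TOKENS = {"LOQ", "LOD", "<LOQ", "<LOD"}


@dataclass
class ConcentrationRecord:
    """One element measurement for a site/variety/compartment cell."""

    area: str
    compartment: str
    element: str
    value: float
    sd: float = 0.0
    n: int = 3
    variety: str = "n/a"
    depth_cm: str | None = None
    distance_km: float | None = None
    unit: str | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.unit is None:
            self.unit = CANONICAL_UNITS[self.compartment]

    def as_row(self) -> dict:
        return {
            "area": self.area, "distance_km": self.distance_km,
            "variety": self.variety, "compartment": self.compartment,
            "depth_cm": self.depth_cm, "element": self.element,
            "value": self.value, "sd": self.sd, "n": self.n,
            "unit": self.unit, "censored": self.censored,
        }


def records_frame(records: list[ConcentrationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_row() for r in records], columns=RECORD_COLUMNS)
    validate_records(df)
    return df


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed report tables do."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check a record table against the schema invariants.

    Raises ``ValueError`` naming the first offending row.  Returns the
    (unmodified) frame so the call can be chained.
    """
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    for idx, row in df.iterrows():
        if row["element"] not in ELEMENTS:
            raise ValueError(f"row {idx}: unknown element symbol {row['element']!r}")
        if row["compartment"] not in COMPARTMENTS:
            raise ValueError(f"row {idx}: unknown compartment {row['compartment']!r}")
        if not np.isfinite(row["value"]) or row["value"] < 0:
            raise ValueError(f"row {idx}: value must be a nonnegative number, got {row['value']!r}")
        if pd.notna(row["sd"]) and row["sd"] < 0:
            raise ValueError(f"row {idx}: sd must be nonnegative, got {row['sd']!r}")
        has_depth = pd.notna(row["depth_cm"]) and str(row["depth_cm"]).strip() != ""
        if row["compartment"] == "soil" and not has_depth:
            raise ValueError(f"row {idx}: soil record lacks a depth interval")
        if row["compartment"] != "soil" and has_depth:
            raise ValueError(f"row {idx}: depth given for non-soil compartment")
        if row["unit"] != CANONICAL_UNITS[row["compartment"]]:
            raise ValueError(
                f"row {idx}: unit {row['unit']!r} not canonical for "
                f"{row['compartment']} (expect {CANONICAL_UNITS[row['compartment']]!r})"
            )
        if row["censored"] and row["value"] != 0:
            raise ValueError(f"row {idx}: censored record must carry value 0")
    return df


def load_concentration_table(path: str | Path, unit_policy: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tidy delimited concentration table into a validated frame.

    ``LOQ``/``LOD`` cells become censored records with value 0; units are
    converted to the canonical unit of each compartment (µg/L → mg/L by
    dividing by 1000).  ``unit_policy`` may override the canonical unit map.
    """
    canonical = dict(CANONICAL_UNITS)
    if unit_policy:
        canonical.update(unit_policy)

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    # keep_default_na off for variety: "n/a" is the literal soil label
    raw = pd.read_csv(path, sep=sep, dtype={"value": str, "depth_cm": str, "variety": str})
    if "variety" in raw.columns:
        raw["variety"] = raw["variety"].fillna("n/a")
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if raw.empty:
        return raw.assign(value=pd.Series(dtype=float), censored=pd.Series(dtype=bool))[RECORD_COLUMNS]

    df = raw.copy()
    tokens = df["value"].astype(str).str.strip().str.upper()
    censored = tokens.isin(_CENSOR_TOKENS) | df["censored"].fillna(0).astype(bool)
    values = pd.to_numeric(df["value"].where(~tokens.isin(_CENSOR_TOKENS)), errors="coerce")
    bad = values.isna() & ~censored
    if bad.any():
        raise ValueError(f"{path}: row {bad.idxmax()}: unparseable value {df.loc[bad.idxmax(), 'value']!r}")
    df["value"] = values.fillna(0.0)
    df["sd"] = pd.to_numeric(df["sd"], errors="coerce").fillna(0.0)
    df["censored"] = censored
    df["n"] = pd.to_numeric(df["n"], errors="coerce").fillna(3).astype(int)
    df["distance_km"] = pd.to_numeric(df["distance_km"], errors="coerce")

    # unit conversion into the canonical unit per compartment
    for idx, row in df.iterrows():
        target = canonical.get(row["compartment"])
        if target is None:
            raise ValueError(f"{path}: row {idx}: unknown compartment {row['compartment']!r}")
        unit = str(row["unit"]).strip()
        if unit == target:
            continue
        if unit in _UNIT_FACTORS and target in _UNIT_FACTORS and unit.endswith("/L") == target.endswith("/L"):
            factor = _UNIT_FACTORS[unit] / _UNIT_FACTORS[target]
            df.loc[idx, ["value", "sd"]] = [row["value"] * factor, df.loc[idx, "sd"] * factor]
            df.loc[idx, "unit"] = target
        else:
            raise ValueError(f"{path}: row {idx}: cannot convert {unit!r} to {target!r}")
    return validate_records(df[RECORD_COLUMNS])


def write_concentration_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write records back to tidy CSV in the same layout they load from."""
    out = df.copy()
    out["censored"] = out["censored"].astype(int)
    out.to_csv(path, index=False)


def _packaged(name: str) -> Path:
    return Path(resources.files("vinemetals.data") / name)


def load_table1() -> pd.DataFrame:
    """Packaged transcription of the soil survey (three areas, four depths)."""
    return load_concentration_table(_packaged("table1_soil.csv"))


def load_table2() -> pd.DataFrame:
    """Packaged transcription of the plant-organ survey (root/cane/leaf/grape)."""
    return load_concentration_table(_packaged("table2_plant.csv"))


def load_table3() -> pd.DataFrame:
    """Packaged transcription of the must and wine survey (mg/L after load)."""
    return load_concentration_table(_packaged("table3_must_wine.csv"))


def aggregate(records: pd.DataFrame, group_by: list[str], over: str = "value") -> pd.DataFrame:
    """Grouped mean / sample SD / RSD% / min / max over ``over``.

    Groups are emitted in input order.  Singleton groups report ``sd_sample``
    0 with ``sd_undefined`` flagged.  Mixed units within a group are
    rejected.  Censored members enter the mean as 0; their count is reported.
    """
    rows = []
    for key, grp in records.groupby(group_by, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        units = grp["unit"].unique()
        if len(units) > 1:
            raise ValueError(f"group {dict(zip(group_by, key))}: mixed units {sorted(units)}")
        vals = grp[over].to_numpy(dtype=float)
        mean = float(vals.mean())
        singleton = len(vals) < 2
        sd = 0.0 if singleton else float(vals.std(ddof=1))
        rows.append({
            **dict(zip(group_by, key)),
            "mean": mean,
            "sd_sample": sd,
            "rsd_pct": 100.0 * sd / mean if mean > 0 else np.nan,
            "n_values": len(vals),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n_censored": int(grp["censored"].sum()),
            "sd_undefined": singleton,
            "unit": units[0],
        })
    return pd.DataFrame(rows)


def extremes(records: pd.DataFrame, over: str = "value") -> tuple[pd.Series, pd.Series]:
    """Records attaining the minimum and maximum of ``over`` (ties: input order)."""
    if records.empty:
        raise ValueError("extremes of an empty record collection")
    vals = records[over].to_numpy(dtype=float)
    return records.iloc[int(vals.argmin())], records.iloc[int(vals.argmax())]
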