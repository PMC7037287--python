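"""Regulatory exceedance grading for soils and for must/wine.

Soils are graded against the Romanian Order 756/1997 tier system (normal
value, alert threshold, intervention threshold; the last two split by
land-use susceptibility).  Must and wine are graded against OIV-style
maximum permissible limits (M.P.L.), with separate, laxer limits for must.

A tier is assigned only when its bound is *strictly* exceeded: a value
sitting exactly on a threshold stays in the tier below.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

SOIL_TIERS = ("within_normal", "above_normal", "above_alert", "above_intervention")
BEVERAGE_TIERS = ("within_mpl", "above_mpl", "no_limit")
LAND_USES = ("susceptible", "less_susceptible")


@dataclass
class ExceedanceResult:
    element: str
    value: float
    tier: str
    ratio_to_limit: float
    land_use: str | None = None


def load_soil_thresholds(path: str | Path | None = None) -> pd.DataFrame:
    """Tiered soil limits, indexed by element (editable CSV data file)."""
    path = path or resources.files("vinemetals.data") / "thresholds_ro_order756.csv"
    df = pd.read_csv(path).set_index("element")
    for land_use in LAND_USES:
        ok = (df["normal"] <= df[f"alert_{land_use}"]) & (df[f"alert_{land_use}"] <= df[f"intervention_{land_use}"])
        if not ok.all():
            raise ValueError(f"threshold ordering violated for {list(df.index[~ok])} ({land_use})")
    return df


def load_beverage_mpl(path: str | Path | None = None) -> pd.DataFrame:
    """Maximum permissible limits for must and wine, indexed (element, matrix)."""
    path = path or resources.files("vinemetals.data") / "mpl_oiv.csv"
    return pd.read_csv(path).set_index(["element", "matrix"])


def _value_of(record) -> tuple[str, float]:
    if isinstance(record, (pd.Series, dict)):
        return record["element"], float(record["value"])
    element, value = record
    return element, float(value)


def grade_soil(record, thresholds: pd.DataFrame, land_use: str = "susceptible") -> ExceedanceResult:
    """Highest soil tier whose bound the value strictly exceeds."""
    if land_use not in LAND_USES:
        raise ValueError(f"unknown land use {land_use!r}")
    element, value = _value_of(record)
    if element not in thresholds.index:
        raise ValueError(f"no soil thresholds for element {element!r}")
    row = thresholds.loc[element]
    if value > row[f"intervention_{land_use}"]:
        tier = "above_intervention"
    elif value > row[f"alert_{land_use}"]:
        tier = "above_alert"
    elif value > row["normal"]:
        tier = "above_normal"
    else:
        tier = "within_normal"
    return ExceedanceResult(element, value, tier, value / row["normal"], land_use)


def grade_beverage(record, mpl: pd.DataFrame, matrix: str | None = None) -> ExceedanceResult:
    """Grade a must or wine value against its M.P.L. (or flag no limit)."""
    if matrix is None:
        matrix = record["compartment"]
    if matrix not in ("must", "wine"):
        raise ValueError(f"beverage matrix must be must or wine, got {matrix!r}")
    element, value = _value_of(record)
    limit = mpl["mpl_mg_L"].get((element, matrix), np.nan)
    if pd.isna(limit):
        return ExceedanceResult(element, value, "no_limit", np.nan)
    tier = "above_mpl" if value > limit else "within_mpl"
    return ExceedanceResult(element, value, tier, value / limit)


def exceedance_report(records: pd.DataFrame,
                      soil_thresholds: pd.DataFrame | None = None,
                      beverage_mpl: pd.DataFrame | None = None,
                      land_use: str = "susceptible") -> pd.DataFrame:
    """Per-record tiers for a mixed table of soil and beverage records.

    Returns the input key columns plus ``tier`` and ``ratio_to_limit``;
    plant-tissue records (no statutory limits here) are skipped.
    """
    soil_thresholds = soil_thresholds if soil_thresholds is not None else load_soil_thresholds()
    beverage_mpl = beverage_mpl if beverage_mpl is not None else load_beverage_mpl()
    rows = []
    for _, rec in records.iterrows():
        comp = rec["compartment"]
        if comp == "soil":
            res = grade_soil(rec, soil_thresholds, land_use)
        elif comp in ("must", "wine"):
            res = grade_beverage(rec, beverage_mpl)
        else:
            continue
        rows.append({
            "area": rec["area"], "variety": rec["variety"], "compartment": comp,
            "depth_cm": rec["depth_cm"], "element": rec["element"],
            "value": rec["value"], "tier": res.tier,
            "ratio_to_limit": res.ratio_to_limit, "land_use": res.land_use,
        })
    return pd.DataFrame(rows)


def tier_counts(report: pd.DataFrame) -> pd.DataFrame:
    """Tier count table per area × element (aggregation of a report)."""
    return (report.groupby(["area", "element", "tier"], sort=False)
            .size().rename("count").reset_index())
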