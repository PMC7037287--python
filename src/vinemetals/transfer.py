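"""Translocation factors (TF) and mobility ratios (MR) along the
soil → root → cane → {leaf, grape → must → wine} chain.

A translocation factor is the concentration ratio between two adjacent
compartments (e.g. TF roots/soil = C_root / C_soil); the mobility ratio
relates any compartment to the topsoil.  Mean MR above ~1 marks the plant
as an accumulator of the element, around 1 an indicator, clearly below 1
an excluder.

Ratios are computed per site (the soil denominator resolved per site by
the chosen ``soil_reference``), then combined across sites within each
cultivar according to ``site_policy``, and finally summarised across
cultivars with mean, sample SD and RSD% — the layout of the published
transfer tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ELEMENTS

#: adjacent-compartment pairs of the default TF chain
TF_PAIRS = (
    ("root", "soil"), ("cane", "root"), ("leaf", "cane"),
    ("grape", "cane"), ("must", "grape"), ("wine", "must"),
)
#: compartment-vs-topsoil pairs of the mobility-ratio table
MR_PAIRS = tuple((c, "soil") for c in ("root", "cane", "leaf", "grape", "must", "wine"))

#: mean-ratio band read as "around 1" (indicator behaviour)
DEFAULT_INDICATOR_BAND = (0.75, 1.25)


@dataclass
class TransferSummary:
    pair: tuple[str, str]
    element: str
    per_variety: dict[str, float]
    mean: float
    sd_sample: float
    rsd_pct: float
    classification: str
    ranking_position: int | None = None
    warnings: list[str] = field(default_factory=list)


def ratio(numerator: float, denominator: float) -> float:
    """Concentration ratio; a zero or censored denominator yields NaN."""
    if denominator is None or not np.isfinite(denominator) or denominator <= 0:
        warnings.warn("undefined transfer ratio: zero/censored denominator", stacklevel=2)
        return np.nan
    return numerator / denominator


def summarize_transfer(values) -> tuple[float, float, float]:
    """(mean, sample SD, RSD%) of per-variety ratios.

    RSD% is 100·SD/mean; with a zero mean it is undefined and returned as
    NaN.  All-missing input is rejected.
    """
    vals = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if len(vals) == 0:
        raise ValueError("no non-missing ratios to summarise")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    rsd = 100.0 * sd / mean if mean > 0 else np.nan
    return mean, sd, rsd


def classify_mobility(mean_ratio: float, band: tuple[float, float] = DEFAULT_INDICATOR_BAND) -> str:
    """accumulator / indicator / excluder from the mean ratio and band."""
    lo, hi = band
    if lo > hi:
        raise ValueError(f"indicator band lower bound exceeds upper ({lo} > {hi})")
    if mean_ratio < 0:
        raise ValueError("mean ratio must be nonnegative")
    if mean_ratio > hi:
        return "accumulator"
    if mean_ratio < lo:
        return "excluder"
    return "indicator"


def rank_elements(means: dict[str, float]) -> tuple[str, list[tuple[str, str]]]:
    """Elements joined by ">" in descending order of mean ratio.

    Ties are broken alphabetically and returned as flagged pairs.
    """
    if any(v is None or not np.isfinite(v) for v in means.values()):
        raise ValueError("ranking requires a non-missing mean for every element")
    ordered = sorted(means, key=lambda el: (-means[el], el))
    ties = [(a, b) for a, b in zip(ordered, ordered[1:]) if means[a] == means[b]]
    return ">".join(ordered), ties


def _soil_value(soil: pd.DataFrame, soil_reference: str) -> float:
    if soil.empty:
        return np.nan
    if soil_reference == "topsoil_0_20":
        top = soil[soil["depth_cm"] == "0-20"]
        return float(top["value"].iloc[0]) if not top.empty else np.nan
    if soil_reference == "depth_average":
        return float(soil["value"].mean())
    raise ValueError(f"unknown soil_reference {soil_reference!r}")


def _value_lookup(records: pd.DataFrame, soil_reference: str) -> dict:
    """(site, variety, compartment) → value for one element's records.

    Censored cells map to 0; the per-site soil denominator is resolved per
    ``soil_reference`` and stored under variety ``n/a``.
    """
    lut = {}
    soil = records[records["compartment"] == "soil"]
    for site, grp in soil.groupby("area", sort=False):
        lut[(site, "n/a", "soil")] = _soil_value(grp, soil_reference)
    rest = records[records["compartment"] != "soil"]
    for site, variety, comp, value, censored in zip(
            rest["area"], rest["variety"], rest["compartment"],
            rest["value"], rest["censored"]):
        lut[(site, variety, comp)] = 0.0 if censored else float(value)
    return lut


def tf_chain(records: pd.DataFrame, element: str,
             pairs=TF_PAIRS, varieties=None,
             soil_reference: str = "depth_average",
             site_policy: str = "per_site_mean",
             band: tuple[float, float] = DEFAULT_INDICATOR_BAND) -> list[TransferSummary]:
    """One :class:`TransferSummary` per chain pair for a single element.

    ``soil_reference`` picks the soil denominator (``depth_average`` for TF
    chains, ``topsoil_0_20`` conventional for MR); ``site_policy`` is
    ``per_site_mean`` (ratio per site, then averaged) or ``pooled``
    (ratio of across-site mean concentrations).
    """
    if site_policy not in ("per_site_mean", "pooled"):
        raise ValueError(f"unknown site_policy {site_policy!r}")
    records = records[records["element"] == element]
    sites = list(dict.fromkeys(records["area"]))
    if varieties is None:
        varieties = [v for v in dict.fromkeys(records["variety"]) if v != "n/a"]
    lut = _value_lookup(records, soil_reference)

    def lookup(site, variety, compartment):
        if compartment == "soil":
            return lut.get((site, "n/a", "soil"))
        return lut.get((site, variety, compartment))

    out = []
    for pair in pairs:
        num_c, den_c = pair
        per_variety, notes = {}, []
        for variety in varieties:
            nums, dens = [], []
            for site in sites:
                num = lookup(site, variety, num_c)
                den = lookup(site, variety, den_c)
                if num is None or den is None:
                    notes.append(f"{variety}/{site}: missing {num_c if num is None else den_c}")
                    continue
                nums.append(num)
                dens.append(den)
            if not nums:
                per_variety[variety] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if site_policy == "per_site_mean":
                    ratios = [ratio(nu, de) for nu, de in zip(nums, dens)]
                    ratios = [r for r in ratios if np.isfinite(r)]
                    per_variety[variety] = float(np.mean(ratios)) if ratios else np.nan
                else:
                    per_variety[variety] = ratio(float(np.mean(nums)), float(np.mean(dens)))
        finite = [v for v in per_variety.values() if np.isfinite(v)]
        if finite:
            mean, sd, rsd = summarize_transfer(finite)
            cls = classify_mobility(mean, band)
        else:
            mean = sd = rsd = np.nan
            cls = "undefined"
            notes.append(f"no defined ratios for pair {num_c}/{den_c}")
        if notes:
            warnings.warn(f"{element} {num_c}/{den_c}: " + "; ".join(sorted(set(notes))), stacklevel=2)
        out.append(TransferSummary(pair, element, per_variety, mean, sd, rsd, cls,
                                   warnings=sorted(set(notes))))
    return out


def chain_summary_table(records: pd.DataFrame, pairs=TF_PAIRS,
                        elements=ELEMENTS, varieties=None,
                        soil_reference: str = "depth_average",
                        site_policy: str = "per_site_mean",
                        band: tuple[float, float] = DEFAULT_INDICATOR_BAND) -> pd.DataFrame:
    """Published-table layout: per-variety ratios, Average/STDEV/RSD% rows,
    classification and per-pair element rankings (by mean and by RSD%)."""
    summaries = {el: tf_chain(records, el, pairs, varieties, soil_reference, site_policy, band)
                 for el in elements}
    rows = []
    for i, pair in enumerate(pairs):
        label = f"{pair[0]}/{pair[1]}"
        by_el = {el: summaries[el][i] for el in elements}
        var_names = list(by_el[elements[0]].per_variety)
        for v in var_names:
            rows.append({"pair": label, "row": v,
                         **{el: by_el[el].per_variety[v] for el in elements}})
        means = {el: by_el[el].mean for el in elements}
        rank_mean, _ = rank_elements({el: m for el, m in means.items() if np.isfinite(m)}) \
            if any(np.isfinite(m) for m in means.values()) else ("", [])
        rsds = {el: by_el[el].rsd_pct for el in elements}
        finite_rsds = {el: r for el, r in rsds.items() if np.isfinite(r)}
        rank_rsd, _ = rank_elements(finite_rsds) if finite_rsds else ("", [])
        rows.append({"pair": label, "row": "Average", **means, "ranking": rank_mean})
        rows.append({"pair": label, "row": "STDEV", **{el: by_el[el].sd_sample for el in elements}})
        rows.append({"pair": label, "row": "RSD %", **rsds, "ranking": rank_rsd})
        rows.append({"pair": label, "row": "Classification",
                     **{el: by_el[el].classification for el in elements}})
    return pd.DataFrame(rows)
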