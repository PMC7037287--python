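"""Pearson correlation cells and ANOVA with Duncan multiple-range letters.

The letter display follows the classic multiple-range convention: group
means are sorted in descending order, ranges are tested stepwise with
stage-wise significance levels ``alpha_p = 1 - (1 - alpha)**(p - 1)`` on
the studentized range, and two groups share a letter exactly when the
procedure does not separate them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationCell:
    var_x: str
    var_y: str
    r: float
    p_two_tailed: float
    stars: str
    n: int
    degenerate: bool = False
    insufficient: bool = False


@dataclass
class LetterDisplay:
    labels: list[str]          # in descending-mean order
    means: list[float]
    letters: list[str]         # per label, same order
    alpha: float
    anova_f: float
    anova_p: float

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.labels, self.letters))


def _stars(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def significance_code(p: float) -> str:
    """ANOVA significance code: *** / ** / * / "in" (insignificant)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "in"


def pearson(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationCell:
    """Product-moment correlation with a two-tailed p from the t transform.

    Zero-variance input is reported as a degenerate cell with r = 0 (the
    convention used for all-censored element columns) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        return CorrelationCell(var_x, var_y, np.nan, np.nan, "", len(x), insufficient=True)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationCell(var_x, var_y, 0.0, 1.0, "", len(x), degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationCell(var_x, var_y, float(r), float(p), _stars(p), len(x))


def correlation_matrix(records: pd.DataFrame, element: str,
                       variables: list[str] | None = None,
                       soil_reference: str = "depth_average") -> pd.DataFrame:
    """Lower-triangular table of correlation cells for one element.

    ``variables`` are compartment names plus optionally ``distance``; each
    resolves to one value per (area, variety) observation.  Soil values are
    broadcast to every cultivar of the area (resolved per
    ``soil_reference``); the diagonal holds unit cells.
    """
    from .transfer import _soil_value

    if variables is None:
        variables = ["distance", "soil", "root", "cane", "leaf", "grape", "must", "wine"]
    sub = records[records["element"] == element]
    obs_keys = sorted({(a, v) for a, v in zip(sub["area"], sub["variety"]) if v != "n/a"})

    vectors = {}
    for var in variables:
        vals = []
        for area, variety in obs_keys:
            area_rows = sub[sub["area"] == area]
            if var == "distance":
                d = area_rows["distance_km"].dropna()
                vals.append(float(d.iloc[0]) if len(d) else np.nan)
            elif var == "soil":
                vals.append(_soil_value(area_rows[area_rows["compartment"] == "soil"], soil_reference))
            else:
                cell = area_rows[(area_rows["compartment"] == var) & (area_rows["variety"] == variety)]
                vals.append(float(cell["value"].iloc[0]) if len(cell) else np.nan)
        vectors[var] = np.asarray(vals)

    table = pd.DataFrame(index=variables, columns=variables, dtype=object)
    for i, vy in enumerate(variables):
        for j, vx in enumerate(variables):
            if j > i:
                continue
            if i == j:
                table.loc[vy, vx] = CorrelationCell(vx, vy, 1.0, 0.0, "", len(obs_keys))
                continue
            mask = np.isfinite(vectors[vx]) & np.isfinite(vectors[vy])
            table.loc[vy, vx] = pearson(vectors[vx][mask], vectors[vy][mask], vx, vy)
    return table


def format_correlation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render a cell table as printed strings like ``0.9942**``."""
    def fmt(cell):
        if not isinstance(cell, CorrelationCell):
            return ""
        if cell.insufficient:
            return "n<3"
        return f"{cell.r:.4f}{cell.stars}"
    return table.map(fmt)


# ------------------------------------------------------- Duncan's test

@lru_cache(maxsize=None)
def _q_crit(alpha: float, span: int, df: int) -> float:
    """Studentized-range critical value at the stage-wise Duncan level."""
    alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(sps.studentized_range.ppf(1.0 - alpha_p, span, df))


def anova_duncan(groups: dict[str, np.ndarray], alpha: float = 0.05) -> LetterDisplay:
    """One-way ANOVA plus Duncan's multiple range test letter display.

    Unequal group sizes use the harmonic mean of all group sizes in the
    standard error of a mean.  Sorting and the stepwise range tests make
    the letter partition independent of input order.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {k!r} needs at least two values")

    f_stat, p_val = sps.f_oneway(*arrays.values())
    k = len(arrays)
    ns = np.array([len(a) for a in arrays.values()])
    df_err = int(ns.sum() - k)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err
    n_h = len(ns) / (1.0 / ns).sum()
    se = np.sqrt(mse / n_h)

    order = sorted(arrays, key=lambda g: -arrays[g].mean())
    means = [float(arrays[g].mean()) for g in order]

    homogeneous: list[tuple[int, int]] = []

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in homogeneous)

    def test(i: int, j: int) -> None:
        if j <= i or covered(i, j):
            return
        span = j - i + 1
        crit = _q_crit(alpha, span, df_err) * se if se > 0 else 0.0
        if means[i] - means[j] <= crit:
            homogeneous.append((i, j))
        else:
            test(i, j - 1)
            test(i + 1, j)

    test(0, k - 1)

    # maximal homogeneous spans -> letters; uncovered singletons get their own
    spans = [s for s in homogeneous
             if not any(s != t and t[0] <= s[0] and s[1] <= t[1] for t in homogeneous)]
    for i in range(k):
        if not any(a <= i <= b for a, b in spans):
            spans.append((i, i))
    spans.sort()
    letters = ["" for _ in range(k)]
    for letter_idx, (a, b) in enumerate(spans):
        letter = chr(ord("a") + letter_idx)
        for i in range(a, b + 1):
            letters[i] += letter

    return LetterDisplay(order, means, letters, alpha, float(f_stat), float(p_val))
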