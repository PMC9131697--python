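"""Abundance statistics: counts, densities, fractions, change ratios, and
group comparisons (one-way ANOVA with Tukey's HSD).

Conventions follow the source analyses: per-sample counts are normalized by
the total number of pan-marker-positive cells in that sample/region ("cells
per Plp1+ cells", in %), densities are counts per polygon area in mm^2, and
the rate of change between two conditions is expressed as a percentage of
the larger condition:

    ratio = 100 - 100 / (X / Y)      with X >= Y > 0,

e.g. X = 30 vs Y = 10 gives 66.66% (the increase of 20 is two thirds of X).
"""
from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionAnnotation

UNASSIGNED = "unassigned"

#: Significance thresholds and their star annotations.
STAR_LEVELS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Star annotation for a p-value (ns above 0.05)."""
    if np.isnan(p):
        return "na"
    for cut, symbol in STAR_LEVELS:
        if p < cut:
            return symbol
    return "ns"


def count_by_region(called: pd.DataFrame, layout: RegionAnnotation,
                    types: Sequence[str] | None = None) -> pd.DataFrame:
    """Counts per (region, type) by point-in-polygon on cell centroids.

    Cells outside every region land in the ``unassigned`` bucket rather than
    being dropped.  Returns a region x type table including all requested
    types (zero-filled).
    """
    region = layout.locate(called["x_um"].to_numpy(), called["y_um"].to_numpy())
    tab = pd.crosstab(pd.Series(region, name="region"),
                      called["called_type"].reset_index(drop=True))
    all_types = list(types) if types is not None else sorted(tab.columns)
    rows = layout.region_names + ([UNASSIGNED] if UNASSIGNED in tab.index else [])
    return tab.reindex(index=rows, columns=all_types, fill_value=0).fillna(0).astype(int)


def density(counts: pd.DataFrame | pd.Series | np.ndarray,
            area_mm2: float | pd.Series) -> pd.DataFrame | pd.Series | np.ndarray:
    """Cells per mm^2: elementwise count / area.  Zero area is an error."""
    area = np.asarray(area_mm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("region area must be > 0")
    if isinstance(counts, pd.DataFrame):
        return counts.div(pd.Series(area_mm2), axis=0)
    return counts / area


def relative_abundance(counts: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Per-type fraction of the total, in percent (sums to 100)."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        warnings.warn("zero total count: fractions undefined")
        frac = np.full_like(arr, np.nan)
    else:
        frac = 100.0 * arr / total
    if isinstance(counts, pd.Series):
        return pd.Series(frac, index=counts.index)
    return frac


def abundance_table(called_by_sample: Mapping[str, pd.DataFrame],
                    layout: RegionAnnotation,
                    types: Sequence[str] | None = None) -> pd.DataFrame:
    """Tidy per-(sample, region, type) table with count, density, fraction.

    ``fraction`` is the percentage of pan-marker-positive cells of that type
    within the sample/region; ``density`` is cells/mm^2 of the region
    polygon (NaN for the unassigned bucket).
    """
    if types is None:
        types = sorted(set().union(
            *(df["called_type"].unique() for df in called_by_sample.values())))
    rows = []
    for sample, called in called_by_sample.items():
        counts = count_by_region(called, layout, types)
        for region in counts.index:
            region_counts = counts.loc[region]
            frac = relative_abundance(region_counts) if region_counts.sum() > 0 \
                else pd.Series(np.nan, index=region_counts.index)
            area = layout.area_mm2(region) if region in layout.regions else np.nan
            for t in types:
                c = int(region_counts[t])
                rows.append((sample, region, t, c,
                             c / area if area and np.isfinite(area) else np.nan,
                             frac[t]))
    return pd.DataFrame(rows, columns=["sample", "region", "type",
                                       "count", "density", "fraction"])


def change_ratio(x: float, y: float) -> float:
    """Percent increase of the larger condition X over the smaller Y.

    ``100 - 100 / (x / y)`` with the caller orienting arguments so that
    ``x >= y``; a type absent from the smaller condition (y <= 0) has an
    undefined ratio (NaN, with a warning).  The result lives in [0, 100)
    and is 0 iff x == y.
    """
    if y <= 0:
        warnings.warn("change_ratio undefined for y <= 0 (type absent)")
        return float("nan")
    if x < y:
        raise ValueError("orient arguments so that x >= y (x is the larger condition)")
    return 100.0 - 100.0 / (x / y)


def oriented_change(value_a: float, value_b: float,
                    name_a: str, name_b: str) -> tuple[float, str]:
    """Change ratio with automatic orientation; returns (ratio, larger side)."""
    if value_a >= value_b:
        return change_ratio(value_a, value_b), name_a
    return change_ratio(value_b, value_a), name_b


def compare_groups(data: pd.DataFrame,
                   value: str = "fraction",
                   group: str = "group",
                   by: str = "type",
                   bh_across: bool = False) -> pd.DataFrame:
    """One-way ANOVA across groups with Tukey HSD pairwise contrasts.

    ``data`` is tidy with one row per sample: a ``by`` column (e.g. cell
    type), a ``group`` column (condition), and a ``value`` column.  For each
    level of ``by``, groups with >= 2 samples enter a one-way ANOVA;
    pairwise contrasts get Tukey-adjusted p-values and star annotations.
    Degenerate input (zero variance everywhere) is flagged, not an error.
    ``bh_across`` optionally Benjamini-Hochberg-adjusts the Tukey p-values
    across the ``by`` levels per contrast (off by default).
    """
    rows = []
    for key, sub in data.groupby(by, sort=False):
        groups = {g: s[value].dropna().to_numpy() for g, s in sub.groupby(group, sort=False)}
        names = list(groups)
        testable = [g for g in names if len(groups[g]) >= 2]
        for a, b in combinations(names, 2):
            row = {by: key, "contrast": f"{a} vs {b}"}
            xa, xb = groups[a], groups[b]
            if a not in testable or b not in testable:
                row.update(direction=None, ratio=np.nan, p_anova=np.nan,
                           p_tukey=np.nan, flag="not_testable")
                rows.append(row)
                continue
            ratio, direction = oriented_change(float(np.mean(xa)), float(np.mean(xb)), a, b)
            pooled = np.concatenate([groups[g] for g in testable])
            if np.ptp(pooled) == 0:
                row.update(direction=direction, ratio=ratio, p_anova=1.0,
                           p_tukey=1.0, flag="degenerate")
                rows.append(row)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_anova = stats.f_oneway(*(groups[g] for g in testable)).pvalue
                tuk = stats.tukey_hsd(*(groups[g] for g in testable))
            ia, ib = testable.index(a), testable.index(b)
            row.update(direction=direction, ratio=ratio,
                       p_anova=float(p_anova),
                       p_tukey=float(tuk.pvalue[ia, ib]), flag="ok")
            rows.append(row)
    out = pd.DataFrame(rows)
    if bh_across and len(out):
        for contrast, sub in out.groupby("contrast"):
            mask = sub["p_tukey"].notna()
            if mask.any():
                adj = stats.false_discovery_control(sub.loc[mask, "p_tukey"])
                out.loc[sub.index[mask], "p_adj"] = adj
    else:
        out["p_adj"] = out["p_tukey"]
    out["significance"] = out["p_adj"].map(stars)
    return out
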