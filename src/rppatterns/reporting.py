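"""Aggregation: count matrices and pattern rosters.

Turns long-format comparison results into the up/down count matrix reported
per region x fraction x comparison, and pattern assignments into rosters
grouped by pattern code, region, fraction and residual band.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .patterns import MEMANTINE_NOT_REQUIRED, MEMANTINE_REQUIRED, PatternCode

COUNT_KEY = ["region", "fraction", "comparison"]


def summarize_counts(results: pd.DataFrame) -> pd.DataFrame:
    """Up/down counts of significant responses per region x fraction x comparison.

    ``results`` needs columns protein, region, fraction, comparison,
    percent_difference, significant.  A significant result with a percent
    difference of exactly zero is direction-less: it is counted as neither
    up nor down, with a warning.
    """
    df = results.copy()
    zero_sig = df["significant"] & (df["percent_difference"] == 0)
    if zero_sig.any():
        warnings.warn(
            f"{int(zero_sig.sum())} significant result(s) with zero percent "
            "difference counted as neither increase nor decrease",
            stacklevel=2,
        )
    df["up"] = df["significant"] & (df["percent_difference"] > 0)
    df["down"] = df["significant"] & (df["percent_difference"] < 0)
    tested = df["percent_difference"].notna()
    out = (
        df.assign(tested=tested)
        .groupby(COUNT_KEY, sort=True)
        .agg(n_up=("up", "sum"), n_down=("down", "sum"), n_tested=("tested", "sum"))
        .reset_index()
    )
    for c in ("n_up", "n_down", "n_tested"):
        out[c] = out[c].astype(int)
    return out


def aggregate_totals(
    table: pd.DataFrame,
    region: str,
    comparison: str | None = None,
    direction: str | None = None,
) -> int:
    """Sum cells of a count matrix or roster over one region.

    For a count matrix (columns n_up/n_down), sums the requested comparison
    across the region's fractions; ``direction`` limits to "up" or "down".
    For a roster (a protein per row), counts the region's instances.
    """
    if "n_up" in table.columns:
        sub = table[table["region"] == region]
        if len(table) and sub.empty:
            raise KeyError(f"region {region!r} not present")
        if comparison is not None:
            sub = sub[sub["comparison"] == comparison]
        if direction is None:
            return int(sub["n_up"].sum() + sub["n_down"].sum())
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up', 'down' or None")
        return int(sub[f"n_{direction}"].sum())
    if "protein" in table.columns:
        if not (table["region"] == region).any() and len(table):
            raise KeyError(f"region {region!r} not present")
        return int((table["region"] == region).sum())
    raise TypeError("expected a count matrix (n_up/n_down) or a roster (protein rows)")


def build_roster(assignments: pd.DataFrame) -> pd.DataFrame:
    """Group pattern assignments into a roster.

    One row per (code, region, fraction, band) with the member proteins,
    ordered with the memantine-not-required family first.
    """
    df = assignments.copy()
    df["band"] = df["band"].fillna("").replace("", "none")
    order = [c.value for c in MEMANTINE_NOT_REQUIRED] + [c.value for c in MEMANTINE_REQUIRED] + [
        c.value for c in PatternCode
        if c not in MEMANTINE_NOT_REQUIRED and c not in MEMANTINE_REQUIRED
    ]
    roster = (
        df.groupby(["code", "region", "fraction", "band"], sort=True)["protein"]
        .agg(list)
        .reset_index()
    )
    roster["n"] = roster["protein"].str.len()
    roster["code"] = pd.Categorical(roster["code"], categories=order, ordered=True)
    return roster.sort_values(["code", "region", "fraction", "band"]).reset_index(drop=True)


def family_totals(assignments: pd.DataFrame) -> pd.DataFrame:
    """Instance counts per region for the two memantine families."""
    df = assignments.copy()
    fam = np.select(
        [
            df["code"].isin([c.value for c in MEMANTINE_NOT_REQUIRED]),
            df["code"].isin([c.value for c in MEMANTINE_REQUIRED]),
        ],
        ["memantine_not_required", "memantine_required"],
        default="other",
    )
    out = (
        df.assign(family=fam)
        .groupby(["family", "region"], sort=True)
        .size()
        .rename("n_instances")
        .reset_index()
    )
    return out
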