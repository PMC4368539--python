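"""Spot-level preprocessing: total-protein normalization and exclusion rules.

Raw antibody intensities are divided by the paired total-protein stain
signal, which removes both loading and the dilution-series structure.  Two
reliability rules then gate what reaches the statistics, mirroring standard
RPPA practice:

* whole protein-instances whose median normalized intensity falls below a
  floor (default 0.1) are unreliable antibody screenings and are discarded;
* individual spots farther than k standard deviations (default 3) from
  their instance mean are excluded, in a single pass.

Nothing is deleted: every spot keeps its row and gains boolean ``qc_*``
flag columns; flagged spots simply never enter model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INSTANCE_KEY = ["protein", "region", "fraction"]

QC_COLUMNS = ["qc_invalid", "qc_low_signal", "qc_technical_outlier", "qc_sd_excluded", "qc_unestimable"]


@dataclass
class PreprocessConfig:
    low_signal_floor: float = 0.1
    sd_inclusion_k: float = 3.0
    replicate_outlier_rule: str = "none"  # "none" or "mad"
    mad_threshold: float = 5.0
    sd_pooling: str = "pooled"  # "pooled" across groups (default) or "per_group"

    def __post_init__(self) -> None:
        if self.low_signal_floor <= 0:
            raise ValueError("low_signal_floor must be > 0")
        if self.sd_inclusion_k <= 0:
            raise ValueError("sd_inclusion_k must be > 0")
        if self.replicate_outlier_rule not in ("none", "mad"):
            raise ValueError("replicate_outlier_rule must be 'none' or 'mad'")
        if self.sd_pooling not in ("pooled", "per_group"):
            raise ValueError("sd_pooling must be 'pooled' or 'per_group'")


def normalize_to_total_protein(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_intensity = raw / sypro`` per spot.

    Spots with non-positive stain signal cannot be normalized; they are
    flagged ``qc_invalid`` (normalized value NaN) rather than divided.
    """
    df = measurements.copy()
    sypro = df["sypro_intensity"].to_numpy(dtype=float)
    raw = df["raw_intensity"].to_numpy(dtype=float)
    invalid = ~(sypro > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(invalid, np.nan, raw / np.where(invalid, np.nan, sypro))
    df["normalized_intensity"] = norm
    df["qc_invalid"] = invalid
    for col in QC_COLUMNS[1:]:
        if col not in df.columns:
            df[col] = False
    return df


def discard_low_signal(df: pd.DataFrame, config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Flag whole protein-instances whose median normalized intensity < floor.

    The reliability rule is per antibody screening (protein x region x
    fraction), not per spot: a screening too weak to trust is dropped
    entirely.  The median is taken over valid spots; the boundary value
    (median exactly at the floor) is retained.
    """
    config = config or PreprocessConfig()
    df = df.copy()
    valid = df.loc[~df["qc_invalid"]]
    med = valid.groupby(INSTANCE_KEY)["normalized_intensity"].median()
    low = set(med.index[med < config.low_signal_floor])
    keys = pd.MultiIndex.from_frame(df[INSTANCE_KEY])
    df["qc_low_signal"] = keys.isin(low)
    return df


def flag_replicate_outliers(df: pd.DataFrame, config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Optional median-absolute-deviation rule within replicate triplets.

    Off by default (``replicate_outlier_rule='none'``): the documented k-SD
    rule is then the only active spot exclusion.
    """
    config = config or PreprocessConfig()
    df = df.copy()
    if "qc_technical_outlier" not in df.columns:
        df["qc_technical_outlier"] = False
    if config.replicate_outlier_rule == "none":
        return df
    usable = ~(df["qc_invalid"] | df["qc_low_signal"])
    sub = df.loc[usable]
    grp = sub.groupby(INSTANCE_KEY + ["mouse_id", "dilution_step"])["normalized_intensity"]
    med = grp.transform("median")
    mad = (sub["normalized_intensity"] - med).abs().groupby(
        [sub[c] for c in INSTANCE_KEY + ["mouse_id", "dilution_step"]]
    ).transform("median")
    out = (sub["normalized_intensity"] - med).abs() > config.mad_threshold * mad
    df.loc[out.index[out & (mad > 0)], "qc_technical_outlier"] = True
    return df


def exclude_extreme_values(df: pd.DataFrame, config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Single-pass k-SD exclusion within each protein-instance.

    Mean and SD are computed over all spots not already flagged, pooled
    across groups by default; a spot is excluded when it deviates from the
    mean by strictly more than k standard deviations (a value exactly at
    k SD is "within" and retained).  Instances with fewer than 3 usable
    spots cannot support the rule and are flagged unestimable.
    """
    config = config or PreprocessConfig()
    df = df.copy()
    usable = ~(df["qc_invalid"] | df["qc_low_signal"] | df["qc_technical_outlier"])
    sub = df.loc[usable]
    keys = INSTANCE_KEY if config.sd_pooling == "pooled" else INSTANCE_KEY + ["group"]
    grp = sub.groupby(keys)["normalized_intensity"]
    mean = grp.transform("mean")
    sd = grp.transform("std", ddof=1)
    n = grp.transform("count")

    excluded = (sub["normalized_intensity"] - mean).abs() > config.sd_inclusion_k * sd.fillna(0.0)
    df["qc_sd_excluded"] = False
    df.loc[excluded.index[excluded], "qc_sd_excluded"] = True

    df["qc_unestimable"] = False
    too_few = n < 3
    df.loc[too_few.index[too_few], "qc_unestimable"] = True
    return df


def preprocess(
    measurements: pd.DataFrame, config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Run the full preprocessing chain; idempotent on its own output."""
    config = config or PreprocessConfig()
    df = measurements.drop(columns=[c for c in QC_COLUMNS + ["normalized_intensity"] if c in measurements.columns])
    df = normalize_to_total_protein(df)
    df = discard_low_signal(df, config)
    df = flag_replicate_outliers(df, config)
    df = exclude_extreme_values(df, config)
    return df


def usable_mask(df: pd.DataFrame) -> pd.Series:
    """Spots eligible for model fitting (no QC flag set)."""
    mask = ~df["qc_invalid"]
    for col in QC_COLUMNS[1:]:
        if col in df.columns:
            mask &= ~df[col]
    return mask
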