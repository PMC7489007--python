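"""Normalization arithmetic for blot and plate-based assay readouts.

Three conventions, each with an exact identity that the test-suite checks:

* western-blot lanes: target signal over loading-control (actin) signal,
  further divided by the mean target/loading ratio of the standard lanes
  run on the same blot — so the standards themselves average to 1.0 per
  blot, and a uniform gain applied to one blot cancels exactly;
* plate background: the mean signal of a control (analyte-free) group is
  subtracted from every sample, so corrected controls average 0; negative
  corrected values are retained unless clipping is requested;
* relative levels: values divided by the control-group mean, so the control
  group's relative mean is exactly 1.0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BLOT_COLUMNS = ["sample_id", "group", "blot_id", "target_signal", "loading_signal", "is_standard"]


def normalize_blot(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-lane relative protein level, standard-normalized within blot.

    ``measurements`` needs columns sample_id, group, blot_id, target_signal,
    loading_signal, is_standard (boolean marking the standard lanes run on
    every blot). Returns the frame with added ``ratio`` (target/loading) and
    ``level`` (ratio / mean standard ratio of the same blot) columns.
    """
    df = measurements.copy()
    missing = [c for c in BLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"blot table missing columns {missing}")
    if (df["loading_signal"] <= 0).any():
        bad = df.loc[df["loading_signal"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive loading signal for samples {bad}")
    df["ratio"] = df["target_signal"] / df["loading_signal"]

    std_means = (
        df[df["is_standard"]].groupby("blot_id")["ratio"].mean()
    )
    blots_without = sorted(set(df["blot_id"]) - set(std_means.index))
    if blots_without:
        raise ValueError(f"blot(s) without standard lanes: {blots_without}")
    if (std_means <= 0).any():
        raise ValueError("standard lanes with non-positive mean ratio")
    df["level"] = df["ratio"] / df["blot_id"].map(std_means)
    return df


def subtract_background(
    measurements: pd.DataFrame,
    control_group_label: str,
    signal_col: str = "signal",
    clip_negative: bool = False,
) -> pd.DataFrame:
    """Subtract the control-group mean signal from every measurement.

    Adds a ``corrected`` column; corrected control values average exactly 0.
    Values below background are kept negative unless ``clip_negative``.
    """
    df = measurements.copy()
    ctl = df.loc[df["group"] == control_group_label, signal_col]
    if len(ctl) == 0:
        raise ValueError(f"control group {control_group_label!r} not found")
    corrected = df[signal_col] - ctl.mean()
    if clip_negative:
        corrected = corrected.clip(lower=0.0)
    df["corrected"] = corrected
    return df


def normalize_to_control(
    measurements: pd.DataFrame,
    control_group_label: str,
    value_col: str = "value",
) -> pd.DataFrame:
    """Express values relative to the control-group mean (defined as 1.0)."""
    df = measurements.copy()
    ctl = df.loc[df["group"] == control_group_label, value_col]
    if len(ctl) == 0:
        raise ValueError(f"control group {control_group_label!r} not found")
    m = ctl.mean()
    if m <= 0:
        raise ValueError(f"control mean must be > 0, got {m}")
    df["relative"] = df[value_col] / m
    return df
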