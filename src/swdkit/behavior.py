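"""Rank-summary scoring of behavioral learning data and probe-trial metrics.

Rather than comparing raw learning curves point by point, each mouse's
performance on every training trial is converted to its percentile rank
among all mice of all groups on that trial, and the per-trial ranks are
averaged into one rank summary score per mouse. The rank transform uses
spreadsheet PERCENTRANK semantics (inclusive): for a member value, the
count of cohort values strictly below it divided by (n - 1); ties take the
strictly-below count; non-member values within the cohort range are ranked
by linear interpolation between the bracketing members.

Scores live in [0, 1]. The direction of "better" depends on the measure
(fewer shock-zone entrances is better; longer avoidance time is better);
the score itself is computed on the raw measure and interpreted at
reporting time.

Probe-trial metrics: the target preference index is the time fraction in
the former target quadrant divided by the mean fraction across the three
non-target quadrants, so chance performance scores 1.0; the mean distance
to target averages per-second distances from the former platform location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def percent_rank(value: float, cohort) -> float:
    """Percentile rank of ``value`` within ``cohort``, PERCENTRANK-style.

    Inclusive semantics: minimum -> 0.0, maximum -> 1.0, member values rank
    as (# strictly below) / (n - 1). Non-members inside the range are
    linearly interpolated; outside the range is an error.
    """
    a = np.sort(np.asarray(cohort, dtype=float))
    n = len(a)
    if n < 2:
        raise ValueError("cohort must contain at least 2 values")
    if value < a[0] or value > a[-1]:
        raise ValueError(f"value {value} outside cohort range [{a[0]}, {a[-1]}]")
    below = int(np.searchsorted(a, value, side="left"))
    if a[below] == value:  # member (or tied with a member)
        return below / (n - 1)
    lo, hi = a[below - 1], a[below]
    frac = (value - lo) / (hi - lo)
    return ((below - 1) + frac) / (n - 1)


@dataclass
class RankScore:
    mouse_id: str
    group: str
    score: float
    n_trials_used: int


def rank_summary_scores(
    trials: pd.DataFrame,
    excluded_trials: set[int] | None = None,
) -> pd.DataFrame:
    """One rank summary score per mouse from a long trial table.

    ``trials`` needs columns mouse_id, group, trial (1-based), value. For
    every non-excluded trial each mouse's value is percentile-ranked against
    all mice of all groups on that trial; a mouse's score is the mean of its
    per-trial ranks. Every mouse must have a value in every non-excluded
    trial.

    Returns a frame with columns mouse_id, group, score, n_trials_used.
    """
    excluded = excluded_trials or set()
    needed = {"mouse_id", "group", "trial", "value"}
    if not needed <= set(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(needed)}")
    use = trials[~trials["trial"].isin(excluded)]
    kept_trials = sorted(use["trial"].unique())
    if not kept_trials:
        raise ValueError("all trials excluded")

    wide = use.pivot_table(index="mouse_id", columns="trial", values="value")
    missing = wide.index[wide.isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"mice missing trial values: {missing}")

    ranks = pd.DataFrame(index=wide.index)
    for t in kept_trials:
        cohort = wide[t].to_numpy()
        ranks[t] = [percent_rank(v, cohort) for v in cohort]
    groups = use.drop_duplicates("mouse_id").set_index("mouse_id")["group"]
    out = pd.DataFrame(
        {
            "mouse_id": wide.index,
            "group": groups.loc[wide.index].to_numpy(),
            "score": ranks.mean(axis=1).to_numpy(),
            "n_trials_used": len(kept_trials),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class ProbeTrial:
    """Probe-trial observation of one mouse.

    ``quadrant_times`` are the four time fractions (target first) and must
    sum to 1; ``per_second_distance_to_target`` is the tracked distance (cm)
    from the former platform location sampled once per second.
    """

    mouse_id: str
    group: str
    quadrant_times: tuple[float, float, float, float]
    per_second_distance_to_target: list[float] | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.quadrant_times, dtype=float)
        if len(q) != 4 or (q < 0).any():
            raise ValueError("quadrant_times must be 4 non-negative fractions")
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("quadrant_times must sum to 1")


def target_preference_index(probe: ProbeTrial, denominator: str = "mean") -> float:
    """Target-quadrant time over non-target time; chance = 1.0.

    ``denominator`` selects the non-target aggregate: ``"mean"`` (default,
    chance = 1.0) or ``"sum"`` (chance = 1/3).
    """
    q = np.asarray(probe.quadrant_times, dtype=float)
    others = q[1:]
    denom = others.mean() if denominator == "mean" else others.sum()
    if denom <= 0:
        raise ValueError("all non-target quadrant times are zero")
    return float(q[0] / denom)


def mean_distance_to_target(probe: ProbeTrial) -> float:
    """Mean of the per-second distances (cm) to the former target location."""
    d = probe.per_second_distance_to_target
    if not d:
        raise ValueError("no per-second distance track")
    return float(np.mean(d))
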