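"""Clustering of detected spikes into spike-and-wave discharges (SWDs).

An SWD is a cluster of at least ``min_components`` spike-and-wave components
within a window of at most ``max_cluster_span`` seconds (defaults: 4
components in 1 s). Qualified clusters separated by a gap shorter than
``merge_gap`` (default 500 ms) count as a single event; a gap of exactly
``merge_gap`` or more keeps them separate. "Component" here is a detected
spike — the slow wave is not independently verified.

Algorithm
---------
1. chain consecutive spikes whose inter-spike interval is at most
   ``max_component_interval`` into candidate clusters (maximal chains);
2. a candidate qualifies if some sub-window of length ``max_cluster_span``
   contains at least ``min_components`` of its spikes;
3. qualified clusters whose last-to-first gap is below ``merge_gap`` are
   merged into one event;
4. member spikes are flagged ``is_swd_member`` in place.

Sub-threshold trailing components stay in the event: events are maximal
chained clusters, not minimal qualifying windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spikes import SpikeEvent


@dataclass
class SWDParams:
    min_components: int = 4
    max_cluster_span: float = 1.0
    merge_gap: float = 0.5
    max_component_interval: float = 0.25

    def __post_init__(self) -> None:
        if self.min_components < 2:
            raise ValueError("min_components must be >= 2")
        if min(self.max_cluster_span, self.merge_gap, self.max_component_interval) <= 0:
            raise ValueError("durations must be > 0")
        if self.max_component_interval > self.max_cluster_span:
            raise ValueError("max_component_interval must be <= max_cluster_span")


@dataclass
class SWDEvent:
    """One spike-and-wave discharge: first-to-last component interval."""

    start: float
    end: float
    component_times: list[float]

    @property
    def n_components(self) -> int:
        return len(self.component_times)

    @property
    def length(self) -> float:
        """Seconds from first to last component."""
        return self.end - self.start


def _chain(times: np.ndarray, max_interval: float) -> list[np.ndarray]:
    """Maximal runs of indices with consecutive gaps <= max_interval."""
    if len(times) == 0:
        return []
    breaks = np.where(np.diff(times) > max_interval)[0]
    return np.split(np.arange(len(times)), breaks + 1)


def _qualifies(times: np.ndarray, params: SWDParams) -> bool:
    """True if some window of length max_cluster_span holds >= min_components."""
    k = params.min_components
    if len(times) < k:
        return False
    # window anchored at each component: span of k consecutive components
    spans = times[k - 1 :] - times[: len(times) - k + 1]
    return bool((spans <= params.max_cluster_span).any())


def detect_swds(spikes: list[SpikeEvent], params: SWDParams = SWDParams()) -> list[SWDEvent]:
    """Cluster spikes into SWD events and flag member spikes.

    Input spikes must be sorted by time; artifact-excluded spikes do not
    participate. Returns events sorted by start, pairwise separated by at
    least ``merge_gap``.
    """
    usable = [s for s in spikes if not s.excluded_artifact]
    times = np.array([s.time for s in usable], dtype=float)
    if len(times) and (np.diff(times) < 0).any():
        raise ValueError("spikes must be sorted by time")

    clusters = [c for c in _chain(times, params.max_component_interval) if _qualifies(times[c], params)]

    # merge qualified clusters with last-to-first gap < merge_gap
    merged: list[list[int]] = []
    for c in clusters:
        if merged and times[c[0]] - times[merged[-1][-1]] < params.merge_gap:
            merged[-1] = merged[-1] + list(c)
        else:
            merged.append(list(c))

    events = []
    for idx in merged:
        ct = [float(times[i]) for i in idx]
        for i in idx:
            usable[i].is_swd_member = True
        events.append(SWDEvent(start=ct[0], end=ct[-1], component_times=ct))
    return events


def swd_statistics(
    swds: list[SWDEvent], analyzed_duration: float
) -> tuple[float, float | None, np.ndarray]:
    """Rate (events/hour), mean event length (s, None if no events), lengths."""
    if analyzed_duration <= 0:
        raise ValueError("analyzed_duration must be > 0")
    lengths = np.array([e.length for e in swds], dtype=float)
    rate = len(swds) / (analyzed_duration / 3600.0)
    mean_len = float(lengths.mean()) if len(lengths) else None
    return rate, mean_len, lengths


def swds_to_frame(swds: list[SWDEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": e.start,
                "end_s": e.end,
                "n_components": e.n_components,
                "length_s": e.length,
                "component_times": ";".join(repr(t) for t in e.component_times),
            }
            for e in swds
        ],
        columns=["start_s", "end_s", "n_components", "length_s", "component_times"],
    )


def frame_to_swds(df: pd.DataFrame) -> list[SWDEvent]:
    out = []
    for r in df.itertuples():
        ct = [float(x) for x in str(r.component_times).split(";") if x]
        out.append(SWDEvent(start=float(r.start_s), end=float(r.end_s), component_times=ct))
    return out
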