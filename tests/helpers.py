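"""Shared test utilities: independent oracles and event matching.

The SWD oracle here deliberately re-derives the clustering rules by
exhaustive enumeration (O(n^2) window scan, fixpoint merging) so it shares
no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

from swdkit.spikes import SpikeEvent


def make_spikes(times, amplitude=100.0, ratio=6.0, sharpness=10.0):
    return [
        SpikeEvent(time=float(t), channel="ch1", amplitude=amplitude,
                   amplitude_ratio=ratio, sharpness=sharpness)
        for t in sorted(times)
    ]


def oracle_swds(
    times,
    min_components: int = 4,
    max_cluster_span: float = 1.0,
    merge_gap: float = 0.5,
    max_component_interval: float = 0.25,
) -> list[list[float]]:
    """Brute-force SWD clustering: returns lists of component times."""
    times = sorted(float(t) for t in times)

    chains: list[list[float]] = []
    cur: list[float] = []
    for t in times:
        if cur and t - cur[-1] > max_component_interval:
            chains.append(cur)
            cur = []
        cur.append(t)
    if cur:
        chains.append(cur)

    qualified = []
    for ch in chains:
        ok = False
        for i in range(len(ch)):
            for j in range(i, len(ch)):
                if ch[j] - ch[i] <= max_cluster_span and (j - i + 1) >= min_components:
                    ok = True
        if ok:
            qualified.append(list(ch))

    events = qualified
    changed = True
    while changed:
        changed = False
        out: list[list[float]] = []
        for ev in events:
            if out and ev[0] - out[-1][-1] < merge_gap:
                out[-1] = out[-1] + ev
                changed = True
            else:
                out.append(ev)
        events = out
    return events


def sensitivity_precision(detected, truth, tol=0.03):
    """Greedy one-to-one matching of event times within ``tol`` seconds."""
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for t in truth:
        cand = np.where(~used & (np.abs(detected - t) < tol))[0]
        if len(cand):
            used[cand[0]] = True
            tp += 1
    sens = tp / len(truth) if len(truth) else 1.0
    prec = tp / len(detected) if len(detected) else 1.0
    return sens, prec


def excel_percentrank_inc(cohort, value) -> float:
    """Spreadsheet PERCENTRANK.INC re-derived from first principles.

    Member values: fraction of the other n-1 values strictly below.
    Non-members: linear interpolation between neighbouring member ranks.
    """
    a = sorted(float(v) for v in cohort)
    n = len(a)
    if value in a:
        below = sum(1 for v in a if v < value)
        return below / (n - 1)
    lo = max(v for v in a if v < value)
    hi = min(v for v in a if v > value)
    r_lo = excel_percentrank_inc(a, lo)
    r_hi = excel_percentrank_inc(a, hi)
    return r_lo + (r_hi - r_lo) * (value - lo) / (hi - lo)


def assert_component_lists_equal(got, expected, atol=1e-9):
    assert len(got) == len(expected), f"{len(got)} events vs {len(expected)}"
    for g, e in zip(got, expected):
        np.testing.assert_allclose(g, e, atol=atol)
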