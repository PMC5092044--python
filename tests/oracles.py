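"""Independent reference implementations used only by the tests.

These are deliberately written from scratch, with their own hard-coded
antenna table and a discretized timeline, so they share no code path with
the package modules they check.
"""

from __future__ import annotations

import math

import numpy as np

# antenna -> (corridor, nearest compartment) for the canonical ring numbering
ANTENNA_TABLE = {
    1: (1, 1), 2: (1, 2),
    3: (2, 2), 4: (2, 3),
    5: (3, 3), 6: (3, 4),
    7: (4, 4), 8: (4, 1),
}


def brute_force_sessions(events, threshold_s=2.0):
    """Naive re-application of the pair rules to one mouse's event list.

    ``events`` is a list of (timestamp_ms, antenna_id) sorted by time.
    Returns (sessions, outcome list) where each session is a tuple
    (compartment, start_ms, end_ms, consecutive_flag).
    """
    sessions = []
    outcomes = []
    for (t1, a1), (t2, a2) in zip(events, events[1:]):
        gap = (t2 - t1) / 1000.0
        if gap < threshold_s:
            outcomes.append("skip_short")
            continue
        cor1, near1 = ANTENNA_TABLE[a1]
        cor2, near2 = ANTENNA_TABLE[a2]
        if a1 == a2:
            sessions.append((near1, t1, t2, False))
            outcomes.append("session")
        elif cor1 == cor2:
            outcomes.append("skip_corridor")
        elif near1 == near2:
            sessions.append((near1, t1, t2, True))
            outcomes.append("session")
        else:
            outcomes.append("skip_opposite")
    return sessions, outcomes


def grid_occupancy_ms(intervals, t1_ms, t2_ms):
    """Total covered time of [start, end) intervals inside [t1, t2), counted
    on a 1-ms grid.  Intervals must have integer-ms endpoints."""
    length = int(t2_ms - t1_ms)
    grid = np.zeros(length, dtype=bool)
    for s, e in intervals:
        lo = max(int(s) - int(t1_ms), 0)
        hi = min(int(e) - int(t1_ms), length)
        if hi > lo:
            grid[lo:hi] = True
    return int(grid.sum())


def grid_together_ms(intervals_a, intervals_b, t1_ms, t2_ms):
    """Overlap time of two interval sets inside [t1, t2) on a 1-ms grid."""
    length = int(t2_ms - t1_ms)
    ga = np.zeros(length, dtype=bool)
    gb = np.zeros(length, dtype=bool)
    for grid, ivs in ((ga, intervals_a), (gb, intervals_b)):
        for s, e in ivs:
            lo = max(int(s) - int(t1_ms), 0)
            hi = min(int(e) - int(t1_ms), length)
            if hi > lo:
                grid[lo:hi] = True
    return int((ga & gb).sum())


def random_event_times(rng, n, span_around_threshold=True):
    """Timestamps with gaps straddling the 2-s threshold, in ms."""
    t = 0
    times = []
    for _ in range(n):
        if span_around_threshold and rng.random() < 0.4:
            gap = int(rng.integers(0, 2000))       # below threshold
        else:
            gap = int(rng.integers(2000, 60_000))  # at/above threshold
        t += gap
        times.append(t)
    return times


def random_session_set(rng, n_sessions, horizon_ms, n_comp=4):
    """Non-overlapping integer-ms sessions for one mouse: list of
    (compartment, start_ms, end_ms)."""
    cuts = np.sort(rng.integers(0, horizon_ms, size=2 * n_sessions))
    out = []
    for i in range(n_sessions):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if e > s:
            out.append((int(rng.integers(1, n_comp + 1)), s, e))
    return out
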