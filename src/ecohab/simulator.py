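"""Ground-truth cohort movement simulator and RFID detection model.

Mice perform a continuous-time walk on the apparatus ring: an exponential
dwell inside a compartment, then a move through one of the two adjacent
corridors (chosen with equal probability) taking a fixed transit time, into
the next compartment.  Two couplings modulate the dwell rate:

* **pair affinity** ``alpha >= 0``: while mouse *a* shares a compartment
  with affiliated partners, its leaving rate is divided by ``(1 + alpha*)``
  where ``alpha*`` is the strongest affinity among its co-residents (it
  stays longer when together), directly inflating co-residence time — the
  quantity the in-cohort sociability score measures.  Using the strongest
  partner rather than a product over all partners keeps the slowdown
  bounded in large cohorts: a multiplicative product makes a fully
  affiliated cohort clump and freeze (dwells of hours), which starves the
  antennas of events; for a pair of mice the two rules coincide;
* **odor effect** ``k >= 1``: from a designated onset time, dwell in a
  designated compartment is multiplied by ``k`` (leaving rate divided by
  ``k``), emulating an attractive olfactory stimulus.

Because dwells are exponential, a rate change (a partner arriving or
leaving, the odor switching on) is handled exactly by resampling the
residual dwell at the change point.  Each mouse draws from its own
counter-based stream spawned from the master seed, so cohorts are
reproducible and mice are statistically independent unless coupled by
affinity.

The detection model emulates the acquisition hardware: each corridor-end
passage yields, with probability ``1 − p_miss``, a burst of one or more
reads at the corresponding antenna; extra reads within a burst are spaced
by more than the acquisition's 210 ms read-out-termination window.

This movement model is a test harness for the analysis pipeline, not a
behavioral claim: there is no circadian rhythm, dominance or scent-mark
dynamics.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError
from .measures import COMPARTMENTS, OccupancyProfile, PairCooccupancy, _intersect_sorted
from .phases import Interval
from .rfid_io import EventLog, RawEvent
from .topology import Topology, standard_topology

__all__ = [
    "SimConfig",
    "DetectionModel",
    "Segment",
    "Trajectory",
    "simulate_cohort",
    "emit_events",
    "true_occupancy",
    "true_together",
    "DEFAULT_START_EPOCH_MS",
]

# arbitrary reference recording start: 2015-02-16 12:00:00 UTC
DEFAULT_START_EPOCH_MS = 1_424_088_000_000


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; rates in seconds.

    Defaults emulate free exploration of the standard four-compartment
    apparatus: a one-minute mean compartment dwell and a 2.5 s corridor
    transit (deliberately above the 2 s sessionizer threshold, so genuine
    corridor transits are classified by geometry rather than discarded as
    short gaps).
    """

    n_mice: int = 8
    duration_s: float = 7200.0
    mean_dwell_s: float = 60.0
    transit_s: float = 2.5
    affinity: np.ndarray | None = None
    odor_compartment: int | None = None
    odor_effect: float = 1.0
    odor_onset_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_mice <= 12:
            raise ValidationError("n_mice must be between 1 and 12")
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")
        if self.mean_dwell_s <= 0 or self.transit_s <= 0:
            raise ValidationError("dwell and transit times must be positive")
        if self.odor_effect < 0:
            raise ValidationError("odor effect multiplier must be >= 0")
        if self.affinity is not None:
            a = np.asarray(self.affinity, dtype=float)
            if a.shape != (self.n_mice, self.n_mice):
                raise ValidationError("affinity matrix must be n_mice x n_mice")
            if (a < 0).any() or not np.allclose(a, a.T) or np.diag(a).any():
                raise ValidationError("affinity must be symmetric, non-negative, zero diagonal")

    def affinity_matrix(self) -> np.ndarray:
        if self.affinity is None:
            return np.zeros((self.n_mice, self.n_mice))
        return np.asarray(self.affinity, dtype=float)

    @staticmethod
    def uniform_affinity(n_mice: int, alpha: float) -> np.ndarray:
        a = np.full((n_mice, n_mice), float(alpha))
        np.fill_diagonal(a, 0.0)
        return a


@dataclass(frozen=True)
class DetectionModel:
    """Imperfect-antenna model for event emission.

    ``burst_mean_extra`` is the Poisson mean of extra reads per detected
    crossing; reads within a burst are ``burst_gap_s`` apart, which must
    exceed the 0.21 s read-out-termination window of the acquisition
    software (otherwise they would have been merged into one read-out).
    """

    p_miss: float = 0.0
    burst_mean_extra: float = 0.0
    burst_gap_s: float = 0.3
    readout_ms_range: tuple[int, int] = (20, 200)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_miss < 1.0:
            raise ValidationError("p_miss must lie in [0, 1)")
        if self.burst_mean_extra < 0:
            raise ValidationError("burst mean must be >= 0")
        if self.burst_gap_s <= 0.21:
            raise ValidationError("burst gap must exceed the 210 ms read-out window")


@dataclass(frozen=True)
class Segment:
    kind: Literal["compartment", "corridor"]
    node: int
    start: float
    end: float
    # for corridor segments: compartments at entry and exit
    from_comp: int | None = None
    to_comp: int | None = None


@dataclass
class Trajectory:
    """Piecewise-constant ground-truth path of one mouse over [0, duration)."""

    mouse: str
    segments: list[Segment] = field(default_factory=list)

    def compartment_intervals(self, comp: int) -> list[tuple[float, float]]:
        return [
            (s.start, s.end)
            for s in self.segments
            if s.kind == "compartment" and s.node == comp
        ]


def _mouse_code(i: int) -> str:
    return f"{90001020000000 + i + 1:014d}"


def simulate_cohort(cfg: SimConfig, top: Topology | None = None) -> list[Trajectory]:
    """Simulate ground-truth trajectories for a cohort.

    Event-driven simulation: a priority queue holds each mouse's next
    transition (compartment departure or corridor arrival); whenever the set
    of co-residents of a compartment changes — or the odor switches on —
    the residual dwells of the affected occupants are resampled at the new
    rate, which is exact for exponential dwells.
    """
    top = top or standard_topology()
    alpha = cfg.affinity_matrix()
    n = cfg.n_mice
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(n)]

    comp_ids = top.compartments
    trajs = [Trajectory(_mouse_code(i)) for i in range(n)]
    # per-mouse state
    location = [0] * n          # current compartment (valid when in_comp)
    in_comp = [True] * n
    seg_start = [0.0] * n
    corridor_info: list[tuple[int, int, int] | None] = [None] * n  # (corridor, from, to)
    occupants: dict[int, set[int]] = {c: set() for c in comp_ids}
    version = [0] * n
    heap: list[tuple[float, int, int, int]] = []  # (time, seq, mouse, version)
    seq = 0

    def leave_rate(m: int, t: float) -> float:
        rate = 1.0 / cfg.mean_dwell_s
        comp = location[m]
        if (
            cfg.odor_compartment is not None
            and comp == cfg.odor_compartment
            and t >= cfg.odor_onset_s
            and cfg.odor_effect > 0
        ):
            rate /= cfg.odor_effect
        strongest = max((alpha[m, p] for p in occupants[comp] if p != m), default=0.0)
        rate /= 1.0 + strongest
        return rate

    def schedule_leave(m: int, t: float) -> None:
        nonlocal seq
        version[m] += 1
        dwell = streams[m].exponential(1.0 / leave_rate(m, t))
        heapq.heappush(heap, (t + dwell, seq, m, version[m]))
        seq += 1

    def schedule_arrival(m: int, t_arrive: float) -> None:
        nonlocal seq
        version[m] += 1
        heapq.heappush(heap, (t_arrive, seq, m, version[m]))
        seq += 1

    def resample_neighbors(comp: int, mover: int, t: float) -> None:
        for p in list(occupants[comp]):
            if p != mover and alpha[p, mover] > 0:
                schedule_leave(p, t)

    # initial placement
    for m in range(n):
        location[m] = comp_ids[streams[m].integers(len(comp_ids))]
        occupants[location[m]].add(m)
    for m in range(n):
        schedule_leave(m, 0.0)

    # odor onset changes the rate of odor-compartment occupants
    odor_pending = (
        cfg.odor_compartment is not None
        and cfg.odor_effect != 1.0
        and 0.0 < cfg.odor_onset_s < cfg.duration_s
    )

    while heap:
        t, _, m, ver = heapq.heappop(heap)
        if t >= cfg.duration_s:
            break
        if odor_pending and t >= cfg.odor_onset_s:
            odor_pending = False
            for p in list(occupants[cfg.odor_compartment]):
                schedule_leave(p, cfg.odor_onset_s)
            heapq.heappush(heap, (t, seq, m, ver))
            seq += 1
            continue
        if ver != version[m]:
            continue  # superseded by a resample
        if in_comp[m]:
            comp = location[m]
            trajs[m].segments.append(Segment("compartment", comp, seg_start[m], t))
            corridors = top.corridors_of_compartment(comp)
            corridor = corridors[streams[m].integers(len(corridors))]
            ends = top.corridor_ends(corridor)
            dest = ends[1] if ends[0] == comp else ends[0]
            occupants[comp].discard(m)
            resample_neighbors(comp, m, t)
            in_comp[m] = False
            corridor_info[m] = (corridor, comp, dest)
            seg_start[m] = t
            schedule_arrival(m, t + cfg.transit_s)
        else:
            corridor, from_comp, dest = corridor_info[m]
            trajs[m].segments.append(
                Segment("corridor", corridor, seg_start[m], t, from_comp, dest)
            )
            location[m] = dest
            in_comp[m] = True
            seg_start[m] = t
            occupants[dest].add(m)
            resample_neighbors(dest, m, t)
            schedule_leave(m, t)
            corridor_info[m] = None

    # close open segments at the horizon so intervals tile [0, duration)
    for m in range(n):
        if in_comp[m]:
            trajs[m].segments.append(
                Segment("compartment", location[m], seg_start[m], cfg.duration_s)
            )
        else:
            corridor, from_comp, dest = corridor_info[m]
            trajs[m].segments.append(
                Segment("corridor", corridor, seg_start[m], cfg.duration_s, from_comp, dest)
            )
    return trajs


def emit_events(
    trajs: Sequence[Trajectory],
    top: Topology | None = None,
    det: DetectionModel = DetectionModel(),
    seed: int = 0,
    start_epoch_ms: int = DEFAULT_START_EPOCH_MS,
) -> EventLog:
    """Turn trajectories into a raw event log through the detection model.

    Each corridor segment implies two antenna crossings: under the antenna
    nearest the compartment being left (at segment start) and under the
    antenna nearest the destination (at segment end).
    """
    top = top or standard_topology()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xEC0)))
    lo, hi = det.readout_ms_range
    events: list[RawEvent] = []

    def crossings(traj: Trajectory, horizon: float):
        for s in traj.segments:
            if s.kind != "corridor":
                continue
            if s.from_comp is not None:
                yield s.start, top.antenna_at(s.node, s.from_comp)
            # a corridor segment truncated at the horizon has no exit crossing
            if s.to_comp is not None and s.end < horizon:
                yield s.end, top.antenna_at(s.node, s.to_comp)

    for traj in trajs:
        horizon = max(s.end for s in traj.segments)
        for t, antenna in crossings(traj, horizon):
            if det.p_miss > 0 and rng.random() < det.p_miss:
                continue
            n_reads = 1 + (rng.poisson(det.burst_mean_extra) if det.burst_mean_extra > 0 else 0)
            for k in range(n_reads):
                ts = start_epoch_ms + round((t + k * det.burst_gap_s) * 1000)
                events.append(
                    RawEvent(
                        event_number=0,
                        timestamp_ms=ts,
                        antenna_id=antenna,
                        readout_duration_ms=int(rng.integers(lo, hi + 1)),
                        transponder_code=traj.mouse,
                    )
                )
    events.sort(key=lambda e: (e.timestamp_ms, e.antenna_id, e.transponder_code))
    numbered = [
        RawEvent(i, e.timestamp_ms, e.antenna_id, e.readout_duration_ms, e.transponder_code)
        for i, e in enumerate(events, start=1)
    ]
    return EventLog(numbered)


def _check_span(traj: Trajectory, iv: Interval) -> None:
    span_end = max(s.end for s in traj.segments)
    if iv.t1 < 0 or iv.t2 > span_end:
        raise ValidationError(f"interval [{iv.t1}, {iv.t2}) outside simulated span [0, {span_end})")


def true_occupancy(traj: Trajectory, iv: Interval) -> OccupancyProfile:
    """Exact per-compartment occupancy from the ground-truth path (interval
    in simulation seconds), normalized like the measured profiles."""
    _check_span(traj, iv)
    t = []
    visits = []
    for comp in COMPARTMENTS:
        pieces = traj.compartment_intervals(comp)
        t.append(sum(min(e, iv.t2) - max(s, iv.t1) for s, e in pieces if min(e, iv.t2) > max(s, iv.t1)) / iv.length)
        visits.append(sum(1 for s, _ in pieces if iv.t1 <= s < iv.t2))
    return OccupancyProfile(traj.mouse, iv, tuple(t), tuple(visits))


def true_together(trajs: Sequence[Trajectory], a: str, b: str, iv: Interval) -> PairCooccupancy:
    """Exact pair co-occupancy from two ground-truth paths."""
    if a == b:
        raise ValidationError("true_together requires two distinct mice")
    by_name = {t.mouse: t for t in trajs}
    ta, tb = by_name[a], by_name[b]
    _check_span(ta, iv)
    _check_span(tb, iv)

    def clipped(traj: Trajectory, comp: int) -> list[tuple[float, float]]:
        out = []
        for s, e in traj.compartment_intervals(comp):
            lo, hi = max(s, iv.t1), min(e, iv.t2)
            if hi > lo:
                out.append((lo, hi))
        return sorted(out)

    per_comp = tuple(
        _intersect_sorted(clipped(ta, c), clipped(tb, c)) / iv.length for c in COMPARTMENTS
    )
    return PairCooccupancy((a, b), iv, per_comp)
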