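"""Behavioral statistics computed from a session log.

The two headline measures:

* **In-cohort sociability** of a pair (a, b) over an analysis interval:
  ``t_ab − Σ_i t_ai · t_bi`` where ``t_ai`` is the fraction of the interval
  mouse *a* spent in compartment *i*, and ``t_ab = Σ_i t_abi`` the fraction
  the pair spent together (in the same compartment simultaneously).  The
  subtracted product term is the time the pair would be expected to share
  under independent exploration, so the score is chance-corrected:
  positive for pairs that seek each other out, negative for avoidance.

* **Approach to social odor**: the ratio of a mouse's social/non-social
  compartment time ratio during stimulus presentation, ``T_S/T_nS``, to the
  same ratio ``t_S/t_nS`` in a pre-stimulus baseline bin.  A value above 1
  means the social odor increased the relative attractiveness of its
  compartment.

All occupancy and co-occupancy times are normalized by the length of the
analyzed segment, so each quantity lies in [0, 1]; time spent in corridors
(or undetected) is the deficit from 1.  Intervals are clipped (not
start-filtered) before duration sums, see :mod:`ecohab.phases`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .phases import Interval, PhaseTable, mask_sessions
from .sessionizer import Session, SessionLog

__all__ = [
    "OccupancyProfile",
    "PairCooccupancy",
    "OdorApproachResult",
    "SociabilityMatrix",
    "Exclusion",
    "occupancy",
    "activity",
    "together_time",
    "in_cohort_sociability",
    "sociability_matrix",
    "approach_to_social_odor",
    "qc_exclusions",
    "dominance_score",
    "mann_whitney",
    "pearson",
]

COMPARTMENTS = (1, 2, 3, 4)


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-compartment occupancy fractions of one mouse over one interval."""

    mouse: str
    interval: Interval
    t: tuple[float, ...]          # fraction of the interval per compartment
    visits: tuple[int, ...]       # sessions starting inside the interval
    mouse_present: bool = True

    @property
    def total(self) -> float:
        return float(sum(self.t))


@dataclass(frozen=True)
class PairCooccupancy:
    """Normalized together-times of a pair, per compartment and in total."""

    mice: tuple[str, str]
    interval: Interval
    t_ab_per_comp: tuple[float, ...]

    @property
    def t_ab(self) -> float:
        return float(sum(self.t_ab_per_comp))


@dataclass(frozen=True)
class OdorApproachResult:
    mouse: str
    T_S: float
    T_nS: float
    t_S: float
    t_nS: float
    defined: bool
    ratio: float | None

    def __post_init__(self) -> None:
        if self.defined != (self.ratio is not None):
            raise ValidationError("ratio present iff defined")


def _comp_intervals(slog: SessionLog, mouse: str, iv: Interval) -> dict[int, list[tuple[float, float]]]:
    clipped = mask_sessions(slog, iv, mode="clip")
    out: dict[int, list[tuple[float, float]]] = {c: [] for c in COMPARTMENTS}
    for s in clipped.sessions_for(mouse):
        out.setdefault(s.compartment, []).append((s.start_ms, s.end_ms))
    return out


def occupancy(slog: SessionLog, mouse: str, iv: Interval) -> OccupancyProfile:
    """Fraction of the interval spent in each compartment, plus visit counts.

    A mouse absent from the log yields a profile of zeros flagged
    ``mouse_present=False``.
    """
    present = mouse in slog.mice()
    per_comp = _comp_intervals(slog, mouse, iv)
    t = tuple(
        sum(e - s for s, e in per_comp.get(c, [])) / iv.length for c in COMPARTMENTS
    )
    visits = tuple(
        sum(
            1
            for s in slog.sessions_for(mouse)
            if s.compartment == c and iv.t1 <= s.start_ms < iv.t2
        )
        for c in COMPARTMENTS
    )
    return OccupancyProfile(mouse, iv, t, visits, mouse_present=present)


def activity(slog: SessionLog, mouse: str, iv: Interval) -> int:
    """Number of visits to all compartments during the interval (sessions
    starting inside it)."""
    return sum(1 for s in slog.sessions_for(mouse) if iv.t1 <= s.start_ms < iv.t2)


def _intersect_sorted(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> float:
    """Total overlap length of two lists of disjoint sorted intervals."""
    total = 0.0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def together_time(slog: SessionLog, a: str, b: str, iv: Interval) -> PairCooccupancy:
    """Normalized time the pair spent simultaneously in each compartment."""
    if a == b:
        raise ValidationError("together_time requires two distinct mice")
    ia = _comp_intervals(slog, a, iv)
    ib = _comp_intervals(slog, b, iv)
    per_comp = tuple(
        _intersect_sorted(sorted(ia.get(c, [])), sorted(ib.get(c, []))) / iv.length
        for c in COMPARTMENTS
    )
    return PairCooccupancy((a, b), iv, per_comp)


def in_cohort_sociability(slog: SessionLog, a: str, b: str, iv: Interval) -> float:
    """Observed together-time minus the independent-exploration expectation:
    ``t_ab − (t_a1·t_b1 + t_a2·t_b2 + t_a3·t_b3 + t_a4·t_b4)``."""
    if a == b:
        raise ValidationError("in-cohort sociability requires two distinct mice")
    ta = occupancy(slog, a, iv).t
    tb = occupancy(slog, b, iv).t
    t_ab = together_time(slog, a, b, iv).t_ab
    return t_ab - sum(x * y for x, y in zip(ta, tb))


class SociabilityMatrix:
    """Symmetric pair → score map for a whole cohort."""

    def __init__(self, cohort: Sequence[str], interval: Interval, scores: dict[frozenset, float]):
        self.cohort = list(cohort)
        self.interval = interval
        self._scores = scores

    def score(self, a: str, b: str) -> float:
        return self._scores[frozenset((a, b))]

    def pair_scores(self) -> list[float]:
        return [self._scores[frozenset(p)] for p in combinations(self.cohort, 2)]

    def mean_score(self) -> float:
        return float(np.mean(self.pair_scores()))

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.cohort)
        mat = np.full((n, n), np.nan)
        for i, a in enumerate(self.cohort):
            for j, b in enumerate(self.cohort):
                if i != j:
                    mat[i, j] = self.score(a, b)
        return pd.DataFrame(mat, index=self.cohort, columns=self.cohort)

    def histogram(self, bins=20, range=(-0.5, 0.5)) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.pair_scores(), bins=bins, range=range)


def sociability_matrix(slog: SessionLog, cohort: Sequence[str], iv: Interval) -> SociabilityMatrix:
    if len(cohort) < 2:
        raise ValidationError("a sociability matrix needs at least 2 mice")
    scores = {
        frozenset((a, b)): in_cohort_sociability(slog, a, b, iv)
        for a, b in combinations(cohort, 2)
    }
    return SociabilityMatrix(cohort, iv, scores)


def approach_to_social_odor(
    slog: SessionLog,
    mouse: str,
    stim_iv: Interval,
    baseline_iv: Interval,
    social_comp: int,
    nonsocial_comp: int,
) -> OdorApproachResult:
    """Odor-approach ratio ``(T_S/T_nS) / (t_S/t_nS)``.

    Stimulus-phase times come from ``stim_iv``, baseline times from a bin in
    the last dark phase before presentation.  Any zero denominator makes the
    ratio undefined rather than infinite; undefined results feed the QC
    exclusion path.  Arbitrary stimulus bin lengths (30 min, 1 h, 2 h, 4 h)
    are supported by passing the corresponding interval.
    """
    if social_comp == nonsocial_comp:
        raise ValidationError("social and non-social compartments must differ")
    if stim_iv.overlaps(baseline_iv):
        raise ValidationError("stimulus and baseline intervals must be disjoint")
    if baseline_iv.t1 >= stim_iv.t1:
        raise ValidationError("baseline bin must precede the stimulus bin")
    idx_s = COMPARTMENTS.index(social_comp)
    idx_ns = COMPARTMENTS.index(nonsocial_comp)
    stim = occupancy(slog, mouse, stim_iv).t
    base = occupancy(slog, mouse, baseline_iv).t
    T_S, T_nS = stim[idx_s] * stim_iv.length, stim[idx_ns] * stim_iv.length
    t_S, t_nS = base[idx_s] * baseline_iv.length, base[idx_ns] * baseline_iv.length
    defined = T_nS > 0 and t_S > 0 and t_nS > 0
    ratio = (T_S / T_nS) / (t_S / t_nS) if defined else None
    return OdorApproachResult(mouse, T_S, T_nS, t_S, t_nS, defined, ratio)


@dataclass(frozen=True)
class Exclusion:
    mouse: str
    reason: str


def qc_exclusions(
    slog: SessionLog,
    phases: PhaseTable,
    adaptation_phase: str,
    testing_phase: str,
    stimulus_comps: Sequence[int],
    mice: Sequence[str] | None = None,
) -> list[Exclusion]:
    """Flag animals with extremely low locomotor activity.

    A mouse is excluded when it failed to visit every stimulus compartment
    in the adaptation phase or in the testing phase (at least one visit to
    each is required in both phases).
    """
    adaptation = phases.interval(adaptation_phase)
    testing = phases.interval(testing_phase)
    cohort = list(mice) if mice is not None else slog.mice()
    excluded = []
    for mouse in cohort:
        sessions = slog.sessions_for(mouse)
        if not sessions:
            excluded.append(Exclusion(mouse, "no visits"))
            continue
        reason = None
        for phase_name, iv in ((adaptation_phase, adaptation), (testing_phase, testing)):
            for comp in stimulus_comps:
                n = sum(
                    1
                    for s in sessions
                    if s.compartment == comp and iv.t1 <= s.start_ms < iv.t2
                )
                if n == 0:
                    reason = f"no visit to stimulus compartment {comp} in phase {phase_name!r}"
                    break
            if reason:
                break
        if reason:
            excluded.append(Exclusion(mouse, reason))
    return excluded


def dominance_score(encounters: Iterable[tuple[str, str]], mouse: str) -> float:
    """Tube-dominance winning score: the percentage of confrontations won.

    ``encounters`` is a sequence of (winner, loser) records from round-robin
    pairings of the cohort.
    """
    wins = total = 0
    for winner, loser in encounters:
        if mouse in (winner, loser):
            total += 1
            wins += winner == mouse
    if total == 0:
        raise ValidationError(f"mouse {mouse!r} has no recorded encounters")
    return 100.0 * wins / total


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two groups; returns (U, p)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation; returns (r, p)."""
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
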