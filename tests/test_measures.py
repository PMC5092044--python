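
import numpy as np
import pytest

from ecohab.errors import ValidationError
from ecohab.measures import (
    activity,
    approach_to_social_odor,
    dominance_score,
    in_cohort_sociability,
    mann_whitney,
    occupancy,
    pearson,
    qc_exclusions,
    sociability_matrix,
    together_time,
)
from ecohab.phases import Interval, parse_phase_config
from ecohab.sessionizer import Session, SessionLog

from oracles import grid_occupancy_ms, grid_together_ms, random_session_set

M1, M2, M3 = "mouseA", "mouseB", "mouseC"


def slog_from(*per_mouse):
    """per_mouse: (mouse, [(comp, start, end), ...])"""
    sessions = [
        Session(mouse, c, s, e, False) for mouse, specs in per_mouse for c, s, e in specs
    ]
    return SessionLog(sessions)


class TestOccupancy:
    def test_full_interval_single_compartment(self):
        slog = slog_from((M1, [(1, 0, 1000)]))
        prof = occupancy(slog, M1, Interval(0, 1000))
        assert prof.t == (1.0, 0.0, 0.0, 0.0)

    def test_two_sessions_partial_cover(self):
        slog = slog_from((M1, [(1, 0, 3), (2, 5, 8)]))
        prof = occupancy(slog, M1, Interval(0, 10))
        assert prof.t == (0.3, 0.3, 0.0, 0.0)
        assert prof.total == pytest.approx(0.6)

    def test_absent_mouse_zero_profile_with_flag(self):
        slog = slog_from((M1, [(1, 0, 1000)]))
        prof = occupancy(slog, "ghost", Interval(0, 1000))
        assert prof.t == (0.0, 0.0, 0.0, 0.0)
        assert prof.mouse_present is False

    def test_agrees_with_millisecond_grid_oracle(self):
        rng = np.random.default_rng(10)
        horizon = 60_000
        for _ in range(25):
            sessions = random_session_set(rng, 12, horizon)
            slog = slog_from((M1, [(c, s, e) for c, s, e in sessions]))
            t1 = int(rng.integers(0, horizon // 2))
            t2 = int(rng.integers(t1 + 1000, horizon))
            prof = occupancy(slog, M1, Interval(t1, t2))
            for idx, comp in enumerate((1, 2, 3, 4)):
                expected = grid_occupancy_ms(
                    [(s, e) for c, s, e in sessions if c == comp], t1, t2
                ) / (t2 - t1)
                if expected:
                    assert abs(prof.t[idx] - expected) / expected < 1e-9
                else:
                    assert prof.t[idx] == 0.0


class TestActivity:
    def test_no_sessions(self):
        assert activity(slog_from((M1, [(1, 0, 10)])), M2, Interval(0, 10)) == 0

    def test_counts_only_starts_in_window(self):
        specs = [(1, i * 100, i * 100 + 50) for i in range(10)]
        slog = slog_from((M1, specs))
        assert activity(slog, M1, Interval(0, 700)) == 7

    def test_equals_sum_of_profile_visits(self):
        rng = np.random.default_rng(11)
        sessions = random_session_set(rng, 15, 30_000)
        slog = slog_from((M1, sessions))
        iv = Interval(5000, 25_000)
        assert activity(slog, M1, iv) == sum(occupancy(slog, M1, iv).visits)


class TestTogetherTime:
    def test_overlap_same_compartment(self):
        slog = slog_from((M1, [(1, 0, 10)]), (M2, [(1, 5, 15)]))
        pair = together_time(slog, M1, M2, Interval(0, 20))
        assert pair.t_ab_per_comp[0] == pytest.approx(0.25)
        assert pair.t_ab == pytest.approx(0.25)

    def test_different_compartments_no_overlap(self):
        slog = slog_from((M1, [(1, 0, 10)]), (M2, [(2, 0, 10)]))
        assert together_time(slog, M1, M2, Interval(0, 10)).t_ab == 0.0

    def test_same_mouse_rejected(self):
        slog = slog_from((M1, [(1, 0, 10)]))
        with pytest.raises(ValidationError):
            together_time(slog, M1, M1, Interval(0, 10))

    def test_agrees_with_millisecond_grid_oracle(self):
        rng = np.random.default_rng(12)
        horizon = 60_000
        for _ in range(25):
            sa = random_session_set(rng, 10, horizon)
            sb = random_session_set(rng, 10, horizon)
            slog = slog_from((M1, sa), (M2, sb))
            t1, t2 = 1000, horizon - 1000
            pair = together_time(slog, M1, M2, Interval(t1, t2))
            for idx, comp in enumerate((1, 2, 3, 4)):
                expected = grid_together_ms(
                    [(s, e) for c, s, e in sa if c == comp],
                    [(s, e) for c, s, e in sb if c == comp],
                    t1, t2,
                ) / (t2 - t1)
                assert abs(pair.t_ab_per_comp[idx] - expected) <= 1e-9 * max(expected, 1)


class TestInCohortSociability:
    def test_saturated_same_compartment_scores_zero(self):
        slog = slog_from((M1, [(1, 0, 1000)]), (M2, [(1, 0, 1000)]))
        assert in_cohort_sociability(slog, M1, M2, Interval(0, 1000)) == 0.0

    def test_synchronized_split_scores_half(self):
        slog = slog_from(
            (M1, [(1, 0, 500), (2, 500, 1000)]),
            (M2, [(1, 0, 500), (2, 500, 1000)]),
        )
        score = in_cohort_sociability(slog, M1, M2, Interval(0, 1000))
        assert abs(score - 0.5) < 1e-12

    def test_antisynchronized_split_scores_minus_half(self):
        slog = slog_from(
            (M1, [(1, 0, 500), (2, 500, 1000)]),
            (M2, [(2, 0, 500), (1, 500, 1000)]),
        )
        score = in_cohort_sociability(slog, M1, M2, Interval(0, 1000))
        assert abs(score + 0.5) < 1e-12

    def test_symmetry_exact(self):
        rng = np.random.default_rng(13)
        slog = slog_from(
            (M1, random_session_set(rng, 10, 30_000)),
            (M2, random_session_set(rng, 10, 30_000)),
        )
        iv = Interval(0, 30_000)
        assert in_cohort_sociability(slog, M1, M2, iv) == in_cohort_sociability(slog, M2, M1, iv)

    def test_bounds_and_attainable_ceiling(self):
        """Score lies in [-1, 1] and below sum_i min(t_ai,t_bi) - sum t_ai t_bi."""
        rng = np.random.default_rng(14)
        for _ in range(20):
            slog = slog_from(
                (M1, random_session_set(rng, 10, 30_000)),
                (M2, random_session_set(rng, 10, 30_000)),
            )
            iv = Interval(0, 30_000)
            score = in_cohort_sociability(slog, M1, M2, iv)
            ta = occupancy(slog, M1, iv).t
            tb = occupancy(slog, M2, iv).t
            ceiling = sum(min(a, b) for a, b in zip(ta, tb)) - sum(
                a * b for a, b in zip(ta, tb)
            )
            assert -1.0 <= score <= 1.0
            assert score <= ceiling + 1e-12


class TestSociabilityMatrix:
    def _three_mouse_log(self):
        rng = np.random.default_rng(15)
        return slog_from(
            (M1, random_session_set(rng, 8, 20_000)),
            (M2, random_session_set(rng, 8, 20_000)),
            (M3, random_session_set(rng, 8, 20_000)),
        )

    def test_three_mice_three_pairs(self):
        matrix = sociability_matrix(self._three_mouse_log(), [M1, M2, M3], Interval(0, 20_000))
        assert len(matrix.pair_scores()) == 3

    def test_symmetric_and_consistent_with_pairwise_calls(self):
        slog = self._three_mouse_log()
        iv = Interval(0, 20_000)
        matrix = sociability_matrix(slog, [M1, M2, M3], iv)
        df = matrix.to_dataframe()
        for a in (M1, M2, M3):
            for b in (M1, M2, M3):
                if a != b:
                    assert df.loc[a, b] == df.loc[b, a]
                    assert df.loc[a, b] == in_cohort_sociability(slog, a, b, iv)

    def test_histogram_counts_all_pairs(self):
        matrix = sociability_matrix(self._three_mouse_log(), [M1, M2, M3], Interval(0, 20_000))
        counts, _ = matrix.histogram()
        assert counts.sum() == 3

    def test_fewer_than_two_mice_rejected(self):
        with pytest.raises(ValidationError):
            sociability_matrix(self._three_mouse_log(), [M1], Interval(0, 20_000))


class TestApproachToSocialOdor:
    def test_no_preference_change_gives_unity(self):
        slog = slog_from(
            (M1, [(2, 0, 300), (4, 300, 600),      # baseline: equal
                  (2, 1000, 1300), (4, 1300, 1600)])  # stimulus: equal
        )
        res = approach_to_social_odor(slog, M1, Interval(1000, 1600), Interval(0, 600), 2, 4)
        assert res.defined and res.ratio == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        # stimulus 0.4 vs 0.2, baseline 0.3 vs 0.3 -> ratio 2
        slog = slog_from(
            (M1, [(2, 0, 300), (4, 300, 600),
                  (2, 1000, 1400), (4, 1400, 1600)])
        )
        res = approach_to_social_odor(slog, M1, Interval(1000, 2000), Interval(0, 1000), 2, 4)
        assert res.ratio == pytest.approx(2.0)

    def test_zero_denominator_is_undefined_not_infinite(self):
        slog = slog_from((M1, [(2, 0, 300), (4, 300, 600), (2, 1000, 1600)]))
        res = approach_to_social_odor(slog, M1, Interval(1000, 1600), Interval(0, 600), 2, 4)
        assert res.defined is False and res.ratio is None

    def test_zero_social_time_is_defined_zero(self):
        slog = slog_from((M1, [(2, 0, 300), (4, 300, 600), (4, 1000, 1600)]))
        res = approach_to_social_odor(slog, M1, Interval(1000, 1600), Interval(0, 600), 2, 4)
        assert res.defined and res.ratio == 0.0

    def test_overlapping_intervals_rejected(self):
        slog = slog_from((M1, [(2, 0, 600)]))
        with pytest.raises(ValidationError):
            approach_to_social_odor(slog, M1, Interval(100, 700), Interval(0, 600), 2, 4)

    def test_same_compartments_rejected(self):
        slog = slog_from((M1, [(2, 0, 600)]))
        with pytest.raises(ValidationError):
            approach_to_social_odor(slog, M1, Interval(1000, 1600), Interval(0, 600), 2, 2)


PHASE_CONFIG = """\
[ADAPTATION]
startdate = 16.02.2015
starttime = 12:00
enddate = 18.02.2015
endtime = 12:00

[TESTING]
startdate = 18.02.2015
starttime = 12:00
enddate = 19.02.2015
endtime = 12:00
"""

T_AD = 1_424_088_000_000            # adaptation start epoch ms
T_TE = T_AD + 48 * 3_600_000        # testing start


class TestQcExclusions:
    def _table(self):
        return parse_phase_config(PHASE_CONFIG)

    def test_fully_active_mouse_retained(self):
        slog = slog_from(
            (M1, [(2, T_AD, T_AD + 5000), (4, T_AD + 9000, T_AD + 14_000),
                  (2, T_TE, T_TE + 5000), (4, T_TE + 9000, T_TE + 14_000)])
        )
        assert qc_exclusions(slog, self._table(), "ADAPTATION", "TESTING", (2, 4)) == []

    def test_missing_stimulus_compartment_in_testing_excluded(self):
        slog = slog_from(
            (M1, [(2, T_AD, T_AD + 5000), (4, T_AD + 9000, T_AD + 14_000),
                  (4, T_TE, T_TE + 5000)])
        )
        (excl,) = qc_exclusions(slog, self._table(), "ADAPTATION", "TESTING", (2, 4))
        assert excl.mouse == M1
        assert "compartment 2" in excl.reason and "TESTING" in excl.reason

    def test_missing_compartment_in_adaptation_excluded(self):
        slog = slog_from(
            (M1, [(2, T_AD, T_AD + 5000),
                  (2, T_TE, T_TE + 5000), (4, T_TE + 9000, T_TE + 14_000)])
        )
        (excl,) = qc_exclusions(slog, self._table(), "ADAPTATION", "TESTING", (2, 4))
        assert "ADAPTATION" in excl.reason

    def test_zero_activity_mouse_excluded_as_no_visits(self):
        slog = slog_from((M1, [(2, T_AD, T_AD + 5000)]))
        excl = qc_exclusions(
            slog, self._table(), "ADAPTATION", "TESTING", (2, 4), mice=[M1, M2]
        )
        reasons = {e.mouse: e.reason for e in excl}
        assert reasons[M2] == "no visits"

    def test_unknown_phase_rejected(self):
        slog = slog_from((M1, [(2, T_AD, T_AD + 5000)]))
        with pytest.raises(Exception, match="PRESENTATION"):
            qc_exclusions(slog, self._table(), "ADAPTATION", "PRESENTATION", (2, 4))


class TestDominanceScore:
    def test_seven_of_ten(self):
        enc = [("a", "b")] * 7 + [("b", "a")] * 3
        assert dominance_score(enc, "a") == 70.0
        assert dominance_score(enc, "b") == 30.0

    def test_all_wins_and_all_losses(self):
        enc = [("a", "b")] * 5
        assert dominance_score(enc, "a") == 100.0
        assert dominance_score(enc, "b") == 0.0

    def test_no_encounters_rejected(self):
        with pytest.raises(ValidationError):
            dominance_score([("a", "b")], "c")


class TestStatWrappers:
    def test_mann_whitney_separated_groups(self):
        _, p = mann_whitney([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert p < 0.05

    def test_pearson_perfect_line(self):
        r, _ = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
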