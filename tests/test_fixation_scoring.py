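"""Interval extraction, debouncing, and the TOFF/TFD metrics."""

import math

import numpy as np
import pytest

from gazefix import (
    ScoringConfig,
    compute_tfd,
    compute_toff,
    intervals_from_scores,
    prune_intervals,
    score_stimulus,
)
from gazefix.synth import FAR_OFFSET, HOVER_OFFSET
from conftest import make_trace


class TestIntervalsFromScores:
    def test_run_of_three(self):
        t = np.arange(5) * 0.02
        assert intervals_from_scores([0, 1, 1, 1, 0], t) == [(0.02, 0.08)]

    def test_all_zeros(self):
        assert intervals_from_scores([0] * 5, np.arange(5) * 0.02) == []

    def test_run_to_end_exits_one_period_after_last_sample(self):
        t = np.arange(5) * 0.02
        out = intervals_from_scores([1] * 5, t)
        assert len(out) == 1
        assert out[0][0] == 0.0
        assert out[0][1] == pytest.approx(0.10)

    def test_multiple_runs(self):
        t = np.arange(8) * 0.02
        out = intervals_from_scores([1, 1, 0, 0, 1, 0, 1, 0], t)
        assert out == [(0.0, 0.04), (0.08, 0.10), (0.12, 0.14)]

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            intervals_from_scores([1, 0], np.arange(3) * 0.02)


def brute_force_prune(intervals, m, gaps_first=True):
    """Fixpoint oracle: apply one removal at a time until none applies.

    With gap priority (gaps_first), the first sub-threshold internal gap is
    merged before any short fixation is deleted; the opposite priority
    deletes first.  Repeats until the list satisfies the output contract.
    """
    ivs = list(intervals)
    while True:
        gap_idx = next(
            (i for i in range(len(ivs) - 1) if ivs[i + 1][0] - ivs[i][1] < m), None
        )
        short_idx = next((i for i, (a, b) in enumerate(ivs) if b - a < m), None)
        if gap_idx is None and short_idx is None:
            return ivs
        if gaps_first:
            if gap_idx is not None:
                ivs[gap_idx] = (ivs[gap_idx][0], ivs[gap_idx + 1][1])
                del ivs[gap_idx + 1]
            else:
                del ivs[short_idx]
        else:
            if short_idx is not None:
                del ivs[short_idx]
            else:
                ivs[gap_idx] = (ivs[gap_idx][0], ivs[gap_idx + 1][1])
                del ivs[gap_idx + 1]


def random_intervals(rng, span=10.0, max_n=8):
    n = int(rng.integers(0, max_n + 1))
    cuts = np.sort(rng.uniform(0, span, size=2 * n))
    return [(float(cuts[2 * i]), float(cuts[2 * i + 1])) for i in range(n) if cuts[2 * i + 1] > cuts[2 * i]]


class TestPrune:
    def test_short_gap_merged(self):
        out = prune_intervals([(1.0, 3.0), (3.06, 4.56)])
        assert out == [(1.0, 4.56)]

    def test_short_interval_deleted(self):
        assert prune_intervals([(1.0, 1.08)]) == []

    def test_compliant_list_unchanged(self):
        ivs = [(1.0, 3.0), (3.5, 4.5)]
        assert prune_intervals(ivs) == ivs

    def test_lead_in_and_tail_never_merged(self):
        # a 50 ms lead-in before the first fixation is not an internal gap
        out = prune_intervals([(0.05, 0.30)])
        assert out == [(0.05, 0.30)]

    def test_min_interval_zero_is_identity(self):
        ivs = [(0.0, 0.01), (0.02, 0.021), (5.0, 5.0001)]
        assert prune_intervals(ivs, cfg=ScoringConfig(min_interval=0.0)) == ivs

    @pytest.mark.parametrize("order", ["gaps_first", "intervals_first"])
    def test_matches_fixpoint_oracle_randomized(self, order):
        rng = np.random.default_rng(42)
        cfg = ScoringConfig(min_interval=0.1, prune_order=order)
        for _ in range(300):
            ivs = random_intervals(rng)
            got = prune_intervals(ivs, cfg=cfg)
            want = brute_force_prune(ivs, 0.1, gaps_first=(order == "gaps_first"))
            assert got == pytest.approx(want)
            # output contract: no short fixation, no short internal gap
            for a, b in got:
                assert b - a >= 0.1
            for (_, b0), (a1, _) in zip(got, got[1:]):
                assert a1 - b0 >= 0.1

    def test_merge_never_decreases_tfd(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ivs = random_intervals(rng)
            merged_only = prune_intervals(
                ivs, cfg=ScoringConfig(min_interval=0.1, prune_order="gaps_first")
            )
            # deleting short fixations first can only lower TFD relative to
            # merging first
            deleted_first = prune_intervals(
                ivs, cfg=ScoringConfig(min_interval=0.1, prune_order="intervals_first")
            )
            assert compute_tfd(merged_only) >= compute_tfd(deleted_first) - 1e-12


class TestMetrics:
    def test_first_entry_half_second_after_stimulus(self):
        """A stimulus delivered at 90.000 s with gaze entering 0.5 s later
        must score TOFF = 90.500 s."""
        assert compute_toff([(90.5, 92.5)]) == 90.5

    def test_toff_absent_without_fixations(self):
        assert math.isnan(compute_toff([]))

    def test_toff_is_first_enter(self):
        assert compute_toff([(2.0, 5.0)]) == 2.0

    def test_three_fixations_sum(self):
        """Fixations of 2, 1.5 and 3 s give TFD = 6.500 s."""
        assert compute_tfd([(90.5, 92.5), (93.0, 94.5), (95.0, 98.0)]) == pytest.approx(6.5)

    def test_tfd_empty(self):
        assert compute_tfd([]) == 0.0

    def test_tfd_full_window(self):
        assert compute_tfd([(0.0, 10.0)]) == pytest.approx(10.0)


def build_session_trace(schedule, window, half_w=2.0, rate_hz=200.0, lead=1.0, tail=1.0):
    """Render a gaze trace at `rate_hz` following an on/off schedule against
    the 2 x 1.5 test AOI in the z=0 plane: on-AOI samples at the center,
    off-AOI samples near/far outside its right edge."""
    t = np.round(np.arange((window.t_end - window.t_start + lead + tail) * rate_hz) / rate_hz
                 + window.t_start - lead, 9)
    p = np.tile([FAR_OFFSET * half_w, 0.0, 0.0], (t.size, 1))
    for a, b in schedule:
        p[(t >= a) & (t < b)] = [0.0, 0.0, 0.0]
        hover = (t >= a - 0.16) & (t < a)
        p[hover] = [HOVER_OFFSET * half_w, 0.0, 0.0]
    return make_trace(t, p, rate_hz=rate_hz)


class TestScoreStimulus:
    def test_saturated_window(self, static_aoi, window):
        tr = build_session_trace([(window.t_start, window.t_end)], window)
        s = score_stimulus(tr, static_aoi, window)
        assert s.qc == "accepted"
        assert s.tfd == pytest.approx(window.duration, abs=0.02)
        assert s.toff == pytest.approx(window.t_start, abs=0.02)

    def test_gaze_never_near_aoi(self, static_aoi, window):
        tr = build_session_trace([], window)
        s = score_stimulus(tr, static_aoi, window)
        assert s.qc == "accepted"
        assert s.tfd == 0.0 and math.isnan(s.toff) and s.intervals == ()

    def test_recovers_schedule(self, static_aoi, window):
        schedule = [(1.0, 3.5), (4.2, 5.0), (7.0, 9.2)]
        tr = build_session_trace(schedule, window)
        s = score_stimulus(tr, static_aoi, window)
        assert len(s.intervals) == 3
        for (ga, gb), (ea, eb) in zip(schedule, s.intervals):
            assert ea == pytest.approx(ga, abs=0.021)
            assert eb == pytest.approx(gb, abs=0.021)
        assert s.toff == pytest.approx(1.0, abs=0.021)
        assert s.tfd == pytest.approx(2.5 + 0.8 + 2.2, abs=0.05)

    def test_dropout_rejection(self, static_aoi, window):
        tr = build_session_trace([(1.0, 9.0)], window)
        valid = tr.valid.copy()
        # 120 ms of tracking loss at 200 Hz
        valid[(tr.t >= 4.0) & (tr.t < 4.12)] = False
        tr = make_trace(tr.t, tr.p, valid=valid, rate_hz=200.0)
        s = score_stimulus(tr, static_aoi, window)
        assert s.qc == "rejected_dropout"
        assert math.isnan(s.toff) and math.isnan(s.tfd) and s.intervals == ()

    def test_deterministic(self, static_aoi, window):
        tr = build_session_trace([(2.0, 4.0)], window)
        s1 = score_stimulus(tr, static_aoi, window)
        s2 = score_stimulus(tr, static_aoi, window)
        assert s1 == s2

    def test_metrics_within_window_bounds(self, static_aoi, window):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = float(rng.uniform(0.3, 8))
            b = float(rng.uniform(a + 0.2, 10))
            tr = build_session_trace([(round(a, 2), round(b, 2))], window)
            s = score_stimulus(tr, static_aoi, window)
            assert 0 <= s.tfd <= window.duration + 1e-9
            if not math.isnan(s.toff):
                assert window.t_start <= s.toff < window.t_end
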