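import itertools

import numpy as np
import pandas as pd
import pytest

from gazeway.segmentation import (GazeSegment, GazeSegmenter, _ols_sse,
                                  classify_segments, refine_jumps,
                                  saccade_th_stats, segment_trace,
                                  segments_to_frame)
from gazeway.synth import simulate_sawtooth_trace


def total_cost(t, Y, bounds, penalty):
    return sum(_ols_sse(t, Y, i, j) for i, j in zip(bounds[:-1], bounds[1:])) \
        + penalty * (len(bounds) - 1)


def brute_force_cost(t, Y, penalty, min_len=2):
    """Enumerate every valid partition of a tiny trace (oracle)."""
    n = len(t)
    best = np.inf
    interior = range(min_len, n - min_len + 1)
    for k in range(0, n):
        for cuts in itertools.combinations(interior, k):
            bounds = [0, *cuts, n]
            if any(b - a < min_len for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            best = min(best, total_cost(t, Y, list(bounds), penalty))
    return best


class TestSegmentTrace:
    def test_dp_matches_brute_force_on_tiny_trace(self):
        rng = np.random.default_rng(0)
        t = np.arange(10) / 60
        Y = np.column_stack([rng.normal(0, 1, 10), rng.normal(0, 1, 10)])
        for penalty in (0.1, 0.5, 2.0):
            segs = segment_trace(t, Y, penalty=penalty)
            bounds = [segs[0].i_start] + [s.i_stop for s in segs]
            assert total_cost(t, Y, bounds, penalty) == pytest.approx(
                brute_force_cost(t, Y, penalty), abs=1e-9)

    def test_sawtooth_breakpoints_recovered(self):
        """Noiseless sawtooth of five pursuits joined by single-frame
        jumps: at least 9 segments, breakpoints within one frame."""
        t, Y, truth = simulate_sawtooth_trace(
            np.random.default_rng(1), n_episodes=5, dur_mean_s=0.4,
            dur_sd_s=0.0, noise_deg=0.0, saccade_frames=1)
        seg = GazeSegmenter().fit((t, Y))
        assert len(seg.segments_) >= 9
        starts = [s.i_start for s in seg.segments_]
        for true_start in truth["episode_starts"][1:]:
            assert min(abs(true_start - s) for s in starts) <= 1

    def test_constant_signal_is_one_segment(self):
        t = np.arange(200) / 60
        Y = np.full((200, 2), 3.0)
        assert len(segment_trace(t, Y)) == 1

    def test_white_noise_with_large_penalty_is_one_segment(self):
        rng = np.random.default_rng(2)
        t = np.arange(300) / 60
        Y = rng.normal(0, 1, (300, 2))
        assert len(segment_trace(t, Y, penalty=1e6)) == 1

    def test_short_trace_yields_nothing(self):
        assert segment_trace(np.arange(4) / 60, np.zeros((4, 2))) == []

    def test_gap_splits_trace(self):
        t = np.concatenate([np.arange(50) / 60, 2.0 + np.arange(50) / 60])
        Y = np.zeros((100, 2))
        segs = segment_trace(t, Y)
        assert len(segs) == 2
        assert segs[0].i_stop == 50 and segs[1].i_start == 50

    def test_partition_covers_trace_without_overlap(self):
        rng = np.random.default_rng(3)
        t, Y, _ = simulate_sawtooth_trace(rng, n_episodes=10)
        segs = segment_trace(t, Y)
        assert segs[0].i_start == 0 and segs[-1].i_stop == len(t)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.i_stop == b.i_start
            assert a.t_end == b.t_start  # shared endpoints

    def test_lower_penalty_never_fewer_segments(self):
        rng = np.random.default_rng(4)
        t, Y, _ = simulate_sawtooth_trace(rng, n_episodes=8)
        counts = [len(segment_trace(t, Y, penalty=p))
                  for p in (20.0, 6.0, 2.0, 0.5)]
        assert all(b >= a for a, b in zip(counts[:-1], counts[1:]))


class TestClassify:
    def _seg(self, dur, speed, i0=0, n=10):
        return GazeSegment(t_start=0.0, t_end=dur, i_start=i0, i_stop=i0 + n,
                           coef=((speed, 0.0), (0.0, 0.0)),
                           mean_speed_deg_s=speed)

    @pytest.mark.parametrize("dur,speed,expected", [
        (0.020, 200.0, "saccade"),    # fast and brief
        (0.400, 3.0, "tracking"),     # slow and long
        (0.400, 80.0, "tracking"),    # fast smooth drift: fails duration
        (0.020, 10.0, "tracking"),    # brief but slow
    ])
    def test_two_criteria_rule_table(self, dur, speed, expected):
        out = classify_segments([self._seg(dur, speed)], merge=False)
        assert out[0].kind == expected

    def test_consecutive_tracking_merged_when_lines_agree(self):
        a = GazeSegment(0.0, 0.5, 0, 30, ((0.0, 1.0), (0.0, 1.0)), 2.0)
        b = GazeSegment(0.5, 1.0, 30, 60, ((0.0, 1.1), (0.0, 1.0)), 2.0)
        out = classify_segments([a, b])
        assert len(out) == 1
        assert out[0].duration_s == pytest.approx(1.0)

    def test_merge_blocked_by_boundary_discontinuity(self):
        # fitted lines 3 deg apart at the shared boundary: a real jump
        a = GazeSegment(0.0, 0.5, 0, 30, ((0.0, 1.0), (0.0, 1.0)), 2.0)
        b = GazeSegment(0.5, 1.0, 30, 60, ((0.0, 4.0), (0.0, 1.0)), 2.0)
        out = classify_segments([a, b])
        assert len(out) == 2


class TestRefineJumps:
    def test_absorbed_jump_samples_promoted_to_saccade(self):
        """A jump whose mid-flight samples were swallowed by the flanking
        tracking fits is carved back out as its own saccade segment."""
        t, Y, truth = simulate_sawtooth_trace(
            np.random.default_rng(5), n_episodes=2, dur_mean_s=0.4,
            dur_sd_s=0.0, noise_deg=0.0)
        # force the absorbed configuration: one boundary at the jump
        b = truth["episode_starts"][1]
        raw = [GazeSegment(t[0], t[b - 1], 0, b - 1,
                           ((0.0, 0.0), (-9.0, 0.0)), 9.0),
               GazeSegment(t[b - 1], t[-1], b - 1, len(t),
                           ((0.0, 0.0), (-9.0, 4.0)), 9.0)]
        refined = refine_jumps(t, Y, raw)
        kinds = [classify_segments([s], merge=False)[0].kind for s in refined]
        assert "saccade" in kinds
        assert len(refined) == 3


class TestSaccadeThStats:
    def _th_table(self, t, th, excluded=None):
        n = len(t)
        return pd.DataFrame({
            "t": t, "time_into_trial_s": t, "th_s": th,
            "excluded": excluded if excluded is not None else [False] * n,
        })

    def _saccade(self, t0, t1):
        return GazeSegment(t0, t1, 0, 2, ((0.0, 0.0), (0.0, 0.0)), 100.0,
                           kind="saccade")

    def test_constant_jump_launch_and_land_medians(self):
        """Saccades always jumping from TH 1.7 to 2.3: medians recover
        the construction exactly."""
        t = np.arange(600) / 60
        th = np.full(600, 1.7)
        segs = []
        for k in range(10):
            t0 = 0.5 + k * 0.9
            i0 = int(round(t0 * 60))
            th[i0 + 1:i0 + 3] = 2.0
            th[i0 + 3:] = 1.7
            th[i0 + 3] = 2.3          # land sample
            segs.append(self._saccade(t[i0], t[i0 + 3]))
        table = self._th_table(t, th)
        events, _ = saccade_th_stats(segs, table)
        launches = np.median([e.launch_th_s for e in events])
        lands = np.median([e.land_th_s for e in events])
        assert launches == pytest.approx(1.7, abs=0.05)
        assert lands == pytest.approx(2.3, abs=0.05)
        assert all(e.forward for e in events)

    def test_event_dropped_when_boundary_in_excluded_gap(self):
        t = np.arange(100) / 60
        th = np.full(100, 2.0)
        excluded = np.zeros(100, dtype=bool)
        excluded[28:36] = True        # gap around the saccade end
        seg = self._saccade(t[25], t[30])
        events, _ = saccade_th_stats([seg], self._th_table(t, th, excluded))
        assert events == []

    def test_bend_window_restriction(self):
        t = np.arange(100) / 60
        th = np.full(100, 2.0)
        seg = self._saccade(t[10], t[12])
        inside, _ = saccade_th_stats([seg], self._th_table(t, th),
                                     bend_window=(0.0, 1.0))
        outside, _ = saccade_th_stats([seg], self._th_table(t, th),
                                      bend_window=(1.0, 2.0))
        assert len(inside) == 1 and len(outside) == 0

    def test_tracking_durations_from_generator(self):
        """Pooled tracking-duration median across sawtooth seeds recovers
        the generator's 0.35 s within 0.02."""
        durs = []
        for seed in range(5):
            t, Y, _ = simulate_sawtooth_trace(np.random.default_rng(seed),
                                              n_episodes=25)
            seg = GazeSegmenter().fit((t, Y))
            table = self._th_table(t, np.full(len(t), 2.0))
            _, episodes = saccade_th_stats(seg.segments_, table)
            durs += [e.duration_s for e in episodes]
        assert np.median(durs) == pytest.approx(0.35, abs=0.02)


def test_segments_to_frame_labels():
    seg = GazeSegment(0.0, 0.5, 0, 30, ((0.0, 0.0), (0.0, 0.0)), 1.0,
                      kind="tracking")
    df = segments_to_frame([seg], participant="P01", mode="Manual", trial=0)
    assert list(df.columns[:3]) == ["participant", "mode", "trial"]
    assert df.loc[0, "kind"] == "tracking"
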