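"""Tracking/saccade parsing of the gaze trace.

The gaze angle signal (horizontal and vertical visual angle, degrees)
is approximated by a piecewise-linear function chosen by exact dynamic
programming: minimise total squared residual plus ``penalty`` per
segment.  Slow, persistent segments are *tracking* eye movements
(pursuits and fixations collapsed into one class, as both track a
waypoint in this task); brief, fast segments are *saccades*.  Saccade
launch/land time headways and inter-saccadic tracking durations are
then read off the TH table, restricted to the bend portion of the
track where waypoint-tracking gaze is not confounded by prolonged
bend-entry fixations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

#: Default per-segment penalty, deg^2 units.  Calibrated so that a pure
#: 0.5 deg-noise constant trace of trial length yields a single segment
#: while the few-degree inter-waypoint saccades still split reliably.
DEFAULT_PENALTY = 6.0


@dataclass(frozen=True)
class GazeSegment:
    """One piecewise-linear span of the trace.

    ``coef`` holds (slope, intercept) per channel; ``i_start``/``i_stop``
    are sample indices (stop exclusive).  Adjacent segments share their
    boundary timestamp.
    """

    t_start: float
    t_end: float
    i_start: int
    i_stop: int
    coef: tuple          # ((slope_h, icpt_h), (slope_v, icpt_v))
    mean_speed_deg_s: float
    kind: str = ""       # "", "tracking" or "saccade"

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SaccadeEvent:
    launch_th_s: float
    land_th_s: float
    t_launch: float
    t_land: float

    @property
    def forward(self) -> bool:
        return self.land_th_s > self.launch_th_s


@dataclass(frozen=True)
class TrackingEpisode:
    duration_s: float
    t_start: float
    t_end: float


def _prefix_sums(t, y):
    """Prefix sums enabling O(1) per-window OLS residual sums."""
    z = lambda a: np.concatenate([[0.0], np.cumsum(a)])
    return z(t), z(t * t), z(y), z(y * y), z(t * y)


def _window_sse(ps, i, j):
    """Residual sum of squares of the OLS line on samples [i, j).

    ``i`` may be an array; ``j`` is a scalar.
    """
    St, Stt, Sy, Syy, Sty = ps
    n = j - i
    st = St[j] - St[i]
    stt = Stt[j] - Stt[i]
    sy = Sy[j] - Sy[i]
    syy = Syy[j] - Syy[i]
    sty = Sty[j] - Sty[i]
    ctt = stt - st * st / n
    cty = sty - st * sy / n
    cyy = syy - sy * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = cyy - np.where(ctt > 1e-12, cty * cty / np.where(ctt > 1e-12, ctt, 1.0), 0.0)
    return np.maximum(sse, 0.0)


def _dp_breakpoints(t, Y, penalty, min_len):
    """Exact DP over segment boundaries; returns sorted boundary indices
    (including 0 and n)."""
    n = len(t)
    ps = [_prefix_sums(t, Y[:, c]) for c in range(Y.shape[1])]
    cost = np.full(n + 1, np.inf)
    cost[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(min_len, n + 1):
        i = np.arange(0, j - min_len + 1)
        sse = sum(_window_sse(p, i, j) for p in ps)
        total = cost[i] + sse + penalty
        k = int(np.argmin(total))
        cost[j] = total[k]
        back[j] = i[k]
    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(back[bounds[-1]]))
    return bounds[::-1]


def _fit_segment(t, Y, i, j, t_end):
    ts = t[i:j]
    coefs = []
    for c in range(Y.shape[1]):
        if j - i >= 2:
            slope, icpt = np.polyfit(ts, Y[i:j, c], 1)
        else:
            slope, icpt = 0.0, float(Y[i, c])
        coefs.append((float(slope), float(icpt)))
    speed = float(np.hypot(coefs[0][0], coefs[1][0]))
    return GazeSegment(t_start=float(t[i]), t_end=float(t_end),
                       i_start=int(i), i_stop=int(j),
                       coef=tuple(coefs), mean_speed_deg_s=speed)


def segment_trace(t, angles, penalty: float = DEFAULT_PENALTY,
                  min_segment_len: int = 2,
                  max_gap_frames: int = 3, fs: float = 60.0) -> list[GazeSegment]:
    """Piecewise-linear segmentation of a 2-channel gaze angle trace.

    ``t`` must be (near-)uniformly sampled at ``fs``; gaps longer than
    ``max_gap_frames`` frames split the trace into independently
    segmented chunks.  Traces (or chunks) shorter than 5 samples yield
    no segments.
    """
    t = np.asarray(t, dtype=float)
    Y = np.atleast_2d(np.asarray(angles, dtype=float))
    if Y.shape[0] != len(t):
        Y = Y.T
    if len(t) == 0:
        return []

    gap = np.where(np.diff(t) > max_gap_frames / fs)[0]
    starts = np.concatenate([[0], gap + 1])
    stops = np.concatenate([gap + 1, [len(t)]])
    segments: list[GazeSegment] = []
    for a, b in zip(starts, stops):
        if b - a < 5:
            continue
        tc, Yc = t[a:b], Y[a:b]
        bounds = _dp_breakpoints(tc, Yc, penalty, min_segment_len)
        for i, j in zip(bounds[:-1], bounds[1:]):
            # shared endpoint: segment ends where the next one starts
            t_end = tc[j] if j < len(tc) else tc[-1]
            segments.append(_fit_segment(tc, Yc, i, j, t_end))
            segments[-1] = replace(segments[-1],
                                   i_start=segments[-1].i_start + a,
                                   i_stop=segments[-1].i_stop + a)
    return segments


def _boundary_jump_deg(left: GazeSegment, right: GazeSegment) -> float:
    """Discontinuity between the two fitted lines at their shared
    boundary time (total visual angle)."""
    tb = left.t_end
    d = [abs((sl * tb + ic) - (sr * tb + ir))
         for (sl, ic), (sr, ir) in zip(left.coef, right.coef)]
    return float(np.hypot(*d)) if len(d) == 2 else float(d[0])


def _ols_sse(t, Y, i, j):
    """Total two-channel residual sum of squares of OLS lines on [i, j)."""
    ts = t[i:j]
    sse = 0.0
    for c in range(Y.shape[1]):
        if j - i >= 2:
            _, res, *_ = np.polyfit(ts, Y[i:j, c], 1, full=True)
            sse += float(res[0]) if len(res) else 0.0
    return sse


def refine_jumps(t, Y, segments, jump_threshold_deg: float = 1.0,
                 max_strip: int = 2,
                 speed_threshold_deg_s: float = 40.0,
                 max_saccade_dur_s: float = 0.12) -> list[GazeSegment]:
    """Recover saccade samples absorbed by neighbouring tracking fits.

    The exact-DP partition reliably places a boundary at each gaze jump,
    but the one or two samples emitted mid-saccade often cost less as
    edge outliers of the adjacent tracking segments than as a dedicated
    two-point segment.  Wherever two adjacent segments disagree by more
    than ``jump_threshold_deg`` at their shared boundary, this pass
    searches over stripping up to ``max_strip`` samples from each side,
    refits the flanking lines, and promotes the stripped run to its own
    segment whose speed is the fitted jump divided by its duration.
    """
    t = np.asarray(t, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != len(t):
        Y = Y.T
    def saccade_like(seg: GazeSegment) -> bool:
        return (seg.mean_speed_deg_s > speed_threshold_deg_s
                and seg.duration_s <= max_saccade_dur_s)

    out: list[GazeSegment] = []
    k = 0
    segments = list(segments)
    while k < len(segments):
        s = segments[k]
        nxt = segments[k + 1] if k + 1 < len(segments) else None
        contiguous = nxt is not None and s.i_stop == nxt.i_start
        if (nxt is None or not contiguous
                or saccade_like(s) or saccade_like(nxt)
                or _boundary_jump_deg(s, nxt) < jump_threshold_deg):
            out.append(s)
            k += 1
            continue
        base = _ols_sse(t, Y, s.i_start, s.i_stop) \
            + _ols_sse(t, Y, nxt.i_start, nxt.i_stop)
        n_base = (s.i_stop - s.i_start) + (nxt.i_stop - nxt.i_start)
        # stripping any sample lowers the SSE, so charge each stripped
        # sample twice the mean residual: only genuine outliers pay off
        lam = 2.0 * base / max(n_base, 1)
        best = (0, 0, base)
        for k1 in range(max_strip + 1):
            for k2 in range(max_strip + 1):
                if k1 + k2 == 0 or k1 + k2 > max_strip + 1:
                    continue
                if s.i_stop - k1 - s.i_start < 2 or nxt.i_stop - (nxt.i_start + k2) < 2:
                    continue
                score = _ols_sse(t, Y, s.i_start, s.i_stop - k1) \
                    + _ols_sse(t, Y, nxt.i_start + k2, nxt.i_stop) \
                    + lam * (k1 + k2)
                if score < best[2] - 1e-12:
                    best = (k1, k2, score)
        k1, k2, _ = best
        if k1 + k2 == 0:
            out.append(s)
            k += 1
            continue
        a, b = s.i_stop - k1, nxt.i_start + k2   # stripped run [a, b)
        left = _fit_segment(t, Y, s.i_start, a, t[a])
        right = _fit_segment(t, Y, b, nxt.i_stop,
                             t[nxt.i_stop] if nxt.i_stop < len(t) else t[-1])
        # saccade speed: fitted displacement across the jump over its span
        disp = np.hypot(*[abs((rs * t[b] + ri) - (ls * t[b] + li))
                          for (ls, li), (rs, ri) in zip(left.coef, right.coef)])
        span = t[b] - t[a]
        sac = GazeSegment(t_start=float(t[a]), t_end=float(t[b]),
                          i_start=int(a), i_stop=int(b),
                          coef=tuple((0.0, float(Y[a, c])) for c in range(Y.shape[1])),
                          mean_speed_deg_s=float(disp / span) if span > 0 else np.inf)
        out.extend([left, sac])
        segments[k + 1] = right
        k += 1
    return out


def classify_segments(segments, speed_threshold_deg_s: float = 40.0,
                      max_saccade_dur_s: float = 0.12,
                      merge: bool = True,
                      merge_discontinuity_deg: float = 1.0) -> list[GazeSegment]:
    """Label segments: saccade iff fast *and* brief, else tracking.

    A fast but long segment (smooth drift) fails the duration criterion
    and counts as tracking.  Consecutive same-kind segments within a
    contiguous chunk are merged (merged speed is the duration-weighted
    mean) — unless the fitted lines disagree by more than
    ``merge_discontinuity_deg`` at the shared boundary, which marks an
    unresolved gaze jump: such boundaries are kept so inter-saccadic
    tracking durations are not inflated.
    """
    labelled = [
        replace(s, kind="saccade"
                if (s.mean_speed_deg_s > speed_threshold_deg_s
                    and s.duration_s <= max_saccade_dur_s) else "tracking")
        for s in segments
    ]
    if not merge:
        return labelled
    out: list[GazeSegment] = []
    for s in labelled:
        prev = out[-1] if out else None
        contiguous = prev is not None and prev.i_stop == s.i_start
        guard_ok = (s.kind == "saccade"
                    or _boundary_jump_deg(prev, s) < merge_discontinuity_deg) \
            if prev is not None else False
        if prev is not None and prev.kind == s.kind and contiguous and guard_ok:
            d1, d2 = prev.duration_s, s.duration_s
            tot = d1 + d2
            speed = (prev.mean_speed_deg_s * d1 + s.mean_speed_deg_s * d2) / tot \
                if tot > 0 else prev.mean_speed_deg_s
            out[-1] = replace(prev, t_end=s.t_end, i_stop=s.i_stop,
                              coef=prev.coef, mean_speed_deg_s=speed)
        else:
            out.append(s)
    return out


class GazeSegmenter(BaseEstimator):
    """sklearn-style wrapper: fit a (t, angles) trace, expose segments.

    Attributes after ``fit``: ``segments_`` (classified, merged) and
    ``raw_segments_`` (pre-classification partition).
    """

    def __init__(self, penalty: float = DEFAULT_PENALTY,
                 min_segment_len: int = 2,
                 speed_threshold_deg_s: float = 40.0,
                 max_saccade_dur_s: float = 0.12,
                 jump_threshold_deg: float = 1.0,
                 max_gap_frames: int = 3, fs: float = 60.0):
        self.penalty = penalty
        self.min_segment_len = min_segment_len
        self.speed_threshold_deg_s = speed_threshold_deg_s
        self.max_saccade_dur_s = max_saccade_dur_s
        self.jump_threshold_deg = jump_threshold_deg
        self.max_gap_frames = max_gap_frames
        self.fs = fs

    def fit(self, X, y=None):
        """``X``: array (n, 3) of columns (t, angle_h_deg, angle_v_deg),
        or a tuple ``(t, angles)``."""
        if isinstance(X, tuple):
            t, ang = X
        else:
            X = np.asarray(X, dtype=float)
            t, ang = X[:, 0], X[:, 1:3]
        self.raw_segments_ = segment_trace(
            t, ang, penalty=self.penalty, min_segment_len=self.min_segment_len,
            max_gap_frames=self.max_gap_frames, fs=self.fs)
        refined = refine_jumps(t, np.asarray(ang), self.raw_segments_,
                               jump_threshold_deg=self.jump_threshold_deg)
        self.segments_ = classify_segments(
            refined, self.speed_threshold_deg_s, self.max_saccade_dur_s,
            merge_discontinuity_deg=self.jump_threshold_deg)
        return self

    def predict(self, t):
        """Per-sample kind label ('tracking'/'saccade'/'' outside any
        segment) at query times ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.full(len(t), "", dtype=object)
        for s in self.segments_:
            out[(t >= s.t_start) & (t <= s.t_end)] = s.kind
        return out


def saccade_th_stats(segments, th_table: pd.DataFrame,
                     bend_window: tuple | None = None,
                     max_boundary_gap_s: float = 2.0 / 60.0):
    """Launch/land TH of saccades and inter-saccadic tracking durations.

    Parameters
    ----------
    segments : classified segments from one trial trace.
    th_table : tidy TH table for the same trial (columns t,
        time_into_trial_s, th_s, excluded).
    bend_window : optional (lo, hi) in time-into-trial seconds; events
        whose boundaries fall outside it are dropped (the analysis is
        restricted to the bend portion of the track).
    max_boundary_gap_s : TH samples further than this (2 frames) from a
        segment boundary do not count; the event is dropped instead.

    Returns ``(events, episodes)``: lists of :class:`SaccadeEvent` and
    :class:`TrackingEpisode`.
    """
    inc = th_table[~th_table["excluded"].astype(bool)]
    t_inc = inc["t"].to_numpy(dtype=float)
    th_inc = inc["th_s"].to_numpy(dtype=float)
    tit_inc = inc["time_into_trial_s"].to_numpy(dtype=float)

    def th_at(time):
        if len(t_inc) == 0:
            return None
        k = int(np.argmin(np.abs(t_inc - time)))
        if abs(t_inc[k] - time) > max_boundary_gap_s:
            return None
        return float(th_inc[k]), float(tit_inc[k])

    def in_bend(tit):
        return bend_window is None or (bend_window[0] <= tit <= bend_window[1])

    events: list[SaccadeEvent] = []
    episodes: list[TrackingEpisode] = []
    for s in segments:
        if s.kind == "saccade":
            launch = th_at(s.t_start)
            land = th_at(s.t_end)
            if launch is None or land is None:
                continue
            if not (in_bend(launch[1]) and in_bend(land[1])):
                continue
            events.append(SaccadeEvent(launch_th_s=launch[0], land_th_s=land[0],
                                       t_launch=s.t_start, t_land=s.t_end))
        elif s.kind == "tracking":
            mid = th_at(0.5 * (s.t_start + s.t_end))
            if mid is None or not in_bend(mid[1]):
                continue
            episodes.append(TrackingEpisode(duration_s=s.duration_s,
                                            t_start=s.t_start, t_end=s.t_end))
    return events, episodes


def segments_to_frame(segments, **labels) -> pd.DataFrame:
    """Segments as a tidy table (for the CSV writers)."""
    rows = [{**labels, "kind": s.kind, "t_start": s.t_start, "t_end": s.t_end,
             "duration_s": s.duration_s, "mean_speed_deg_s": s.mean_speed_deg_s}
            for s in segments]
    return pd.DataFrame(rows, columns=[*labels, "kind", "t_start", "t_end",
                                       "duration_s", "mean_speed_deg_s"])
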