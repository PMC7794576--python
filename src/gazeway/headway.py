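"""Gaze time headway estimation.

Gaze time headway (TH) is the time it would take, at the current speed,
to travel from the vehicle's position to the point on the road where
gaze falls.  Projecting gaze through the screen into the world is
ill-conditioned near the horizon (distance ahead diverges as the
vertical angle goes to zero), so instead of a screen-to-world
projection, each gaze sample is mapped to the *gaze midline reference*:
the candidate midline point, within a bounded forward window, whose
screen projection is closest to the gaze point in screen coordinates.
TH is then the along-midline distance from the vehicle's own midline
foot point to that reference, divided by speed.  Lane-position offsets
are ignored by design.

Four exclusion filters are applied, in order, each sample keeping the
first reason that fires:

1. ``low_confidence`` — pupil-detection confidence below 0.6;
2. ``off_surface``    — gaze outside the display surface;
3. ``far_from_midline`` — gaze more than 20 degrees of visual angle
   from its midline reference (or no reference available on-screen);
4. ``on_marker``      — gaze inside one of the optical marker regions
   bordering the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera import CameraModel, angular_separation_deg, world_to_screen
from .track import Midline, TrialWindow, arc_to_world, world_to_arc

EXCLUSION_REASONS = ("low_confidence", "off_surface", "far_from_midline", "on_marker")

#: five square optical markers bordering the stimulus: four corners plus
#: top-centre; (centre_x, centre_y, half_side) in normalised screen units.
DEFAULT_MARKERS = tuple(
    (cx, cy, 0.025)
    for cx, cy in [(0.03, 0.03), (0.97, 0.03), (0.03, 0.97), (0.97, 0.97), (0.5, 0.97)]
)


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds of the four gaze-exclusion filters."""

    min_confidence: float = 0.6
    max_angle_deg: float = 20.0
    surface_bounds: tuple = (0.0, 1.0, 0.0, 1.0)  # xmin, xmax, ymin, ymax
    markers: tuple = DEFAULT_MARKERS


@dataclass(frozen=True)
class HeadwayConfig:
    """Forward search window and stream-alignment tolerance."""

    forward_window_s: tuple = (0.0, 8.0)
    candidate_step_m: float = 0.1
    max_join_gap_s: float = 1.0 / 120.0  # half a frame at 60 Hz
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)


def compute_time_headway(vehicle_arc_m, ref_arc_m, speed_mps: float,
                         total_arc_m: float):
    """TH in seconds: wrap-aware along-midline distance over speed."""
    d = (np.asarray(ref_arc_m, dtype=float) - np.asarray(vehicle_arc_m, dtype=float)) \
        % total_arc_m
    return d / speed_mps


def gaze_to_midline_reference(cam: CameraModel, midline: Midline,
                              vehicle_pos, vehicle_yaw, vehicle_arc_m,
                              gaze_xy, cfg: HeadwayConfig = HeadwayConfig()):
    """Map gaze screen coordinates to the nearest projected midline point.

    Vectorised over frames: ``vehicle_pos`` is (n, 2), ``gaze_xy`` (n, 2).

    Returns ``(ref_arc_m, th_s, angular_error_deg, valid)`` arrays; frames
    with no usable candidate (everything behind the camera) come back with
    ``valid=False``.
    """
    pos = np.atleast_2d(np.asarray(vehicle_pos, dtype=float))
    yaw = np.atleast_1d(np.asarray(vehicle_yaw, dtype=float))
    arc = np.atleast_1d(np.asarray(vehicle_arc_m, dtype=float))
    gaze = np.atleast_2d(np.asarray(gaze_xy, dtype=float))
    n = len(pos)

    speed = midline.speed_mps
    lo, hi = cfg.forward_window_s
    rel = np.arange(lo * speed, hi * speed + cfg.candidate_step_m,
                    cfg.candidate_step_m)                     # (m,) ascending
    cand_arc = (arc[:, None] + rel[None, :]) % midline.total_arc_m
    cand_world = arc_to_world(midline, cand_arc)              # (n, m, 2)

    # inlined pinhole projection of every candidate against every frame
    relx = cand_world[..., 0] - pos[:, 0, None]
    relz = cand_world[..., 1] - pos[:, 1, None]
    c, s = np.cos(yaw), np.sin(yaw)
    depth = relx * c[:, None] + relz * s[:, None]
    lat = -relx * s[:, None] + relz * c[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = cam.screen_distance_m / depth
        sx = 0.5 + 0.5 * lat * inv / cam.half_width
        sy = 0.5 - 0.5 * cam.eye_height_m * inv / cam.half_height
        d2 = (sx - gaze[:, 0, None]) ** 2 + (sy - gaze[:, 1, None]) ** 2
    d2[~np.isfinite(d2)] = np.inf
    d2[depth <= 1e-9] = np.inf
    # argmin takes the first minimum -> ties resolve to the smaller arc
    best = np.argmin(d2, axis=1)
    rows = np.arange(n)
    valid = np.isfinite(d2[rows, best])

    ref_arc = cand_arc[rows, best]
    th = rel[best] / speed
    ref_screen = np.column_stack([sx[rows, best], sy[rows, best]])
    ang = np.full(n, np.nan)
    ang[valid] = angular_separation_deg(cam, gaze[valid], ref_screen[valid])
    return ref_arc, th, ang, valid


def apply_exclusions(confidence, gaze_xy, angular_error_deg, reference_valid,
                     cfg: ExclusionConfig = ExclusionConfig()):
    """Apply the four filters in order; return (excluded, reason) arrays.

    ``reason`` is the first matching filter name, or "" for included
    samples.
    """
    conf = np.asarray(confidence, dtype=float)
    gaze = np.atleast_2d(np.asarray(gaze_xy, dtype=float))
    ang = np.asarray(angular_error_deg, dtype=float)
    ok = np.asarray(reference_valid, dtype=bool)

    n = len(conf)
    reason = np.full(n, "", dtype=object)

    low = conf < cfg.min_confidence
    xmin, xmax, ymin, ymax = cfg.surface_bounds
    off = (gaze[:, 0] < xmin) | (gaze[:, 0] > xmax) | \
          (gaze[:, 1] < ymin) | (gaze[:, 1] > ymax)
    far = ~ok | ~(ang <= cfg.max_angle_deg)
    marker = np.zeros(n, dtype=bool)
    for cx, cy, h in cfg.markers:
        marker |= (np.abs(gaze[:, 0] - cx) <= h) & (np.abs(gaze[:, 1] - cy) <= h)

    for mask, name in [(low, "low_confidence"), (off, "off_surface"),
                       (far, "far_from_midline"), (marker, "on_marker")]:
        hit = mask & (reason == "")
        reason[hit] = name
    return reason != "", reason


def align_streams(vehicle: pd.DataFrame, gaze: pd.DataFrame,
                  max_gap_s: float = 1.0 / 120.0) -> pd.DataFrame:
    """Join gaze to vehicle frames by nearest timestamp.

    Samples with no partner within ``max_gap_s`` (half a frame at 60 Hz)
    are dropped.  Both inputs must be sorted by ``t``.
    """
    merged = pd.merge_asof(
        gaze.sort_values("t"), vehicle.sort_values("t"),
        on="t", direction="nearest", tolerance=max_gap_s,
        suffixes=("", "_veh"),
    )
    return merged.dropna(subset=["x", "z", "yaw"]).reset_index(drop=True)


def estimate_time_headway(vehicle: pd.DataFrame, gaze: pd.DataFrame,
                          midline: Midline, cam: CameraModel,
                          window: TrialWindow | None = None,
                          cfg: HeadwayConfig = HeadwayConfig()) -> pd.DataFrame:
    """Full TH pipeline for one trial: align, reference, TH, exclusions.

    Parameters
    ----------
    vehicle : DataFrame with columns t, x, z, yaw (plus any labels).
    gaze : DataFrame with columns t, screen_x, screen_y, confidence.
    window : optional trial window; when given, rows are restricted to
        vehicle arc positions inside it and ``time_into_trial_s`` is
        measured from its start.

    Returns
    -------
    Tidy TH table with columns t, time_into_trial_s, th_s, ref_arc_m,
    angular_error_deg, excluded, reason, carrying through participant /
    mode / trial labels when present.
    """
    df = align_streams(vehicle, gaze, cfg.max_join_gap_s)
    if df.empty:
        return _empty_th_table()

    pos = df[["x", "z"]].to_numpy()
    arc = np.asarray(world_to_arc(midline, pos))
    if window is not None:
        keep = (arc >= window.start_arc_m) & (arc <= window.end_arc_m)
        df, pos, arc = df[keep].reset_index(drop=True), pos[keep], arc[keep]
        if df.empty:
            return _empty_th_table()
        t_into = window.time_into_trial(arc, midline.speed_mps)
    else:
        t_into = (arc - arc[0]) / midline.speed_mps

    gaze_xy = df[["screen_x", "screen_y"]].to_numpy()
    ref_arc, th, ang, valid = gaze_to_midline_reference(
        cam, midline, pos, df["yaw"].to_numpy(), arc, gaze_xy, cfg)
    excluded, reason = apply_exclusions(
        df["confidence"].to_numpy(), gaze_xy, ang, valid, cfg.exclusions)

    out = pd.DataFrame({
        "t": df["t"].to_numpy(),
        "time_into_trial_s": t_into,
        "th_s": th,
        "ref_arc_m": ref_arc,
        "angular_error_deg": ang,
        "excluded": excluded,
        "reason": reason,
    })
    for col in ("participant", "mode", "trial"):
        if col in df.columns:
            out.insert(0, col, df[col].to_numpy())
    return out


def _empty_th_table() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "t", "time_into_trial_s", "th_s", "ref_arc_m",
        "angular_error_deg", "excluded", "reason"])
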