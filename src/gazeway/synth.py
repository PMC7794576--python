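"""Synthetic vehicle and gaze data with known ground truth.

The generator emulates the gaze phenomenology the analysis assumes:

* *sawtooth waypoint tracking* — gaze saccades to a waypoint on the
  midline about 2 s ahead, tracks that fixed world point for ~0.35 s
  (so its TH decays at slope -1), then saccades on to the next one;
* a *bend-entry attractor* — on the approach, episodes increasingly
  target a single fixed point ~1 s of travel past the bend entry,
  producing the prolonged entry fixations of the EF cluster;
* *measurement noise* — additive Gaussian angular noise on the
  projected gaze position (~1.5 deg RMS, the typical calibration
  error), plus a small fraction of off-task artefact samples drawn
  from the classes the exclusion filters remove (low confidence,
  off-road corners, marker glances);
* *driving-mode shifts* — a configurable additive shift of the mean
  preview distance per mode (defaults follow the Manual/Auto-Replay/
  Auto-Stock ordering: 0, +0.17 s, +0.22 s), and the same shift
  lengthens the EF onset lead (the bend entry is fixated earlier).

Every emitted sample carries its latent label (GF / EF / noise and a
saccade flag), and every episode its true waypoint, so that parameter
recovery can be tested end to end.

A note on parameterisation: ``gf_mean_th_s`` is the mean *emitted*
time headway of a tracking episode — the waypoint is placed so that TH
at the episode's temporal midpoint equals the drawn value.  Anchoring
the drawn TH at episode *start* instead would bias the emitted
marginal low by half a tracking duration (TH decays while tracking),
making the nominal mean unrecoverable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .camera import CameraModel, world_to_screen
from .track import (Midline, TrackConfig, TrialWindow, arc_to_world,
                    build_midline, default_trial_window, stadium_heading)

FS = 60.0  # display / recording rate, Hz


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters (all times in seconds, lengths in metres)."""

    gf_mean_th_s: float = 2.0
    gf_sd_s: float = 0.3
    tracking_dur_mean_s: float = 0.35
    tracking_dur_sd_s: float = 0.08
    ef_point_offset_s: float = 1.0      # attractor location past bend entry
    ef_onset_lead_s: float = 3.5        # how early EF episodes may begin
    ef_episode_prob: float = 0.4        # per new episode on the approach
    noise_frac: float = 0.05
    angular_noise_deg: float = 1.5      # RMS slow (calibration-like) error
    tremor_noise_deg: float = 0.3       # RMS frame-to-frame white noise
    noise_corr_time_s: float = 3.0      # correlation time of the slow error
    mode_shift_s: dict = field(default_factory=lambda: {
        "Manual": 0.0, "Auto-Replay": 0.17, "Auto-Stock": 0.22})
    saccade_dur_s: float = 0.033
    participant_sd_s: float = 0.15      # between-participant sd of gf mean
    n_trials: int = 2
    n_participants: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ef_episode_prob <= 1 and 0 <= self.noise_frac <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        for name in ("gf_sd_s", "tracking_dur_sd_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrialData:
    participant: str
    mode: str
    trial: int
    vehicle: pd.DataFrame
    gaze: pd.DataFrame
    truth: pd.DataFrame          # per-sample latent labels
    episodes: pd.DataFrame       # per-episode ground truth


def simulate_trajectory(midline: Midline, window: TrialWindow,
                        speed_mps: float | None = None,
                        fs: float = FS) -> pd.DataFrame:
    """Constant-speed 60 Hz vehicle states along the midline.

    Arc position advances by exactly ``speed/fs`` per frame; yaw is the
    analytic track tangent.  A zero-length window yields an empty frame.
    """
    speed = speed_mps if speed_mps is not None else midline.speed_mps
    n = int(np.floor(window.length_m / (speed / fs)))
    if n <= 0:
        return pd.DataFrame(columns=["t", "x", "z", "yaw", "arc_m"])
    arc = window.start_arc_m + np.arange(n) * speed / fs
    pos = arc_to_world(midline, arc)
    yaw = stadium_heading(midline.config, arc)
    return pd.DataFrame({
        "t": np.arange(n) / fs,
        "x": pos[:, 0], "z": pos[:, 1], "yaw": yaw, "arc_m": arc,
    })


def _project(cam: CameraModel, pos, yaw, world_pts):
    """Noiseless per-frame projection of one world point per frame."""
    screen, behind = world_to_screen(cam, pos, yaw, world_pts[:, None, :])
    return screen[:, 0, :], behind[:, 0]


def _measurement_noise(cam: CameraModel, n: int, cfg: SynthConfig,
                       rng: np.random.Generator, fs: float = FS):
    """Per-frame screen offsets emulating eye-tracking error.

    Two components, both mean zero: a slowly varying AR(1) error with
    stationary RMS ``angular_noise_deg`` and correlation time
    ``noise_corr_time_s`` (miscalibration and drift between calibration
    anchors), and white frame-to-frame tremor of RMS
    ``tremor_noise_deg``.  Each component's per-axis sd is the RMS over
    sqrt(2); angular offsets are converted to normalised screen units
    at the screen centre.
    """
    off = np.zeros((n, 2))
    rho = np.exp(-1.0 / (cfg.noise_corr_time_s * fs)) \
        if cfg.noise_corr_time_s > 0 else 0.0
    for ax in range(2):
        total = 0.0
        if cfg.angular_noise_deg > 0:
            sd = np.radians(cfg.angular_noise_deg) / np.sqrt(2)
            e = rng.normal(0.0, sd, n)
            drift = np.empty(n)
            drift[0] = e[0]
            for k in range(1, n):
                drift[k] = rho * drift[k - 1] + np.sqrt(1 - rho * rho) * e[k]
            total = total + drift
        if cfg.tremor_noise_deg > 0:
            total = total + rng.normal(
                0.0, np.radians(cfg.tremor_noise_deg) / np.sqrt(2), n)
        half = cam.half_width if ax == 0 else cam.half_height
        off[:, ax] = 0.5 * np.tan(total) * cam.screen_distance_m / half
    return off


def simulate_gaze(trajectory: pd.DataFrame, midline: Midline,
                  cam: CameraModel, cfg: SynthConfig, mode: str = "Manual",
                  rng: np.random.Generator | None = None,
                  gf_mean_override: float | None = None):
    """Generate one trial's gaze trace plus ground truth.

    Returns ``(gaze, truth, episodes)`` data frames.  ``gaze`` has the
    reader columns (t, screen_x, screen_y, confidence); ``truth`` one
    row per sample (label, is_saccade, episode_id, waypoint_arc_m);
    ``episodes`` one row per fixation episode with its true waypoint,
    onset/offset and the true saccade boundaries preceding it.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if trajectory.empty:
        cols_g = ["t", "screen_x", "screen_y", "confidence"]
        return (pd.DataFrame(columns=cols_g), pd.DataFrame(), pd.DataFrame())

    t = trajectory["t"].to_numpy()
    arc = trajectory["arc_m"].to_numpy()
    pos = trajectory[["x", "z"]].to_numpy()
    yaw = trajectory["yaw"].to_numpy()
    speed = midline.speed_mps
    n = len(t)
    dt = 1.0 / FS

    shift = cfg.mode_shift_s.get(mode, 0.0)
    gf_mean = (gf_mean_override if gf_mean_override is not None
               else cfg.gf_mean_th_s) + shift
    track_cfg: TrackConfig = midline.config
    attractor_arc = track_cfg.bend_entry_arc_m + cfg.ef_point_offset_s * speed
    onset_lead = cfg.ef_onset_lead_s + shift

    # ------------------------------------------------------------------
    # episode schedule
    sac_frames = max(int(round(cfg.saccade_dur_s * FS)), 1)
    episodes = []
    i = 0
    ep_id = 0
    while i < n:
        dur = rng.normal(cfg.tracking_dur_mean_s, cfg.tracking_dur_sd_s)
        dur = float(np.clip(dur, 0.1, 1.0))
        n_frames = max(int(round(dur * FS)), 3)
        i_stop = min(i + n_frames, n)
        t_mid = t[i] + 0.5 * (i_stop - 1 - i) * dt
        arc_mid = np.interp(t_mid, t, arc)
        tta = (attractor_arc - arc_mid) / speed     # time to attractor
        if 0.0 < tta <= onset_lead and rng.random() < cfg.ef_episode_prob:
            label, wp_arc = "EF", attractor_arc
        else:
            th = rng.normal(gf_mean, cfg.gf_sd_s)
            th = float(np.clip(th, 0.5, 6.0))
            label, wp_arc = "GF", arc_mid + th * speed
        episodes.append({"episode_id": ep_id, "label": label,
                         "waypoint_arc_m": wp_arc, "i_start": i,
                         "i_stop": i_stop, "t_start": t[i],
                         "t_end": t[min(i_stop, n - 1)]})
        ep_id += 1
        i = i_stop + sac_frames
    ep_df = pd.DataFrame(episodes)

    # ------------------------------------------------------------------
    # per-sample gaze: project each episode's fixed waypoint
    wp_arc_per_sample = np.full(n, np.nan)
    label = np.full(n, "", dtype=object)
    episode_id = np.full(n, -1)
    for ep in episodes:
        sl = slice(ep["i_start"], ep["i_stop"])
        wp_arc_per_sample[sl] = ep["waypoint_arc_m"]
        label[sl] = ep["label"]
        episode_id[sl] = ep["episode_id"]

    fix = episode_id >= 0
    world = np.zeros((n, 2))
    world[fix] = arc_to_world(midline, wp_arc_per_sample[fix])
    screen = np.full((n, 2), 0.5)
    scr_fix, behind = _project(cam, pos[fix], yaw[fix], world[fix])
    screen[fix] = scr_fix

    # saccade samples: linear screen-space interpolation between episodes
    is_saccade = np.zeros(n, dtype=bool)
    for k in range(1, len(episodes)):
        a, b = episodes[k - 1], episodes[k]
        g0, g1 = a["i_stop"] - 1, b["i_start"]
        for j in range(g0 + 1, min(g1, n)):
            frac = (j - g0) / (g1 - g0)
            screen[j] = (1 - frac) * screen[g0] + frac * screen[min(g1, n - 1)]
            is_saccade[j] = True
            label[j] = b["label"]
            episode_id[j] = b["episode_id"]
    # trailing unassigned samples (after the last episode) -> hold last gaze
    rest = label == ""
    if rest.any() and (~rest).any():
        last = np.where(~rest)[0][-1]
        screen[rest] = screen[last]
        label[rest] = label[last]

    screen = screen + _measurement_noise(cam, n, cfg, rng)
    confidence = rng.uniform(0.85, 1.0, n)

    # ------------------------------------------------------------------
    # artefact samples, drawn from the excludable classes
    n_noise = rng.binomial(n, cfg.noise_frac)
    if n_noise > 0:
        idx = rng.choice(n, size=n_noise, replace=False)
        kind = rng.choice(3, size=n_noise, p=[0.5, 0.25, 0.25])
        for j, k in zip(idx, kind):
            if k == 0:      # low pupil-detection confidence
                confidence[j] = rng.uniform(0.0, 0.6 - 1e-6)
                screen[j] = rng.uniform(0.0, 1.0, 2)
            elif k == 1:    # far off-road corner glance
                screen[j] = [rng.uniform(0.0, 0.06), rng.uniform(0.94, 1.0)]
            else:           # glance at an optical marker
                screen[j] = [0.5 + rng.uniform(-0.02, 0.02),
                             0.97 + rng.uniform(-0.02, 0.02)]
            label[j] = "noise"
            episode_id[j] = -1
            is_saccade[j] = False

    gaze = pd.DataFrame({"t": t, "screen_x": screen[:, 0],
                         "screen_y": screen[:, 1], "confidence": confidence})
    truth = pd.DataFrame({"t": t, "label": label, "is_saccade": is_saccade,
                          "episode_id": episode_id,
                          "waypoint_arc_m": wp_arc_per_sample})
    return gaze, truth, ep_df


def simulate_sawtooth_trace(rng: np.random.Generator, n_episodes: int = 30,
                            drift_deg_s: float = -9.0, jump_deg: float = 4.0,
                            dur_mean_s: float = 0.35, dur_sd_s: float = 0.05,
                            noise_deg: float = 0.5, saccade_frames: int = 2,
                            fs: float = FS):
    """Canonical optokinetic sawtooth in gaze-angle space.

    The idealised nystagmus pattern of waypoint tracking: the vertical
    gaze angle drifts at ``drift_deg_s`` while a point is pursued, then
    jumps back by ``jump_deg`` (emitted as ``saccade_frames`` linearly
    interpolated samples), with white angular noise added.  Unlike
    :func:`simulate_gaze` this bypasses the display geometry, so every
    saccade has a known, constant amplitude — the reference trace for
    segmentation-recovery checks.

    Returns ``(t, angles, truth)`` where ``angles`` is (n, 2) degrees
    and ``truth`` holds ``n_saccades``, the true per-episode durations
    and the episode-start sample indices.
    """
    t, v = [], []
    tt, base = 0.0, 0.0
    durations, starts = [], []
    for k in range(n_episodes):
        dur = max(rng.normal(dur_mean_s, dur_sd_s), 0.1)
        nf = max(int(round(dur * fs)), 3)
        starts.append(len(t))
        durations.append(nf / fs)
        for i in range(nf):
            t.append(tt)
            v.append(base + drift_deg_s * i / fs)
            tt += 1.0 / fs
        end = base + drift_deg_s * (nf - 1) / fs
        nxt = end + jump_deg
        if k < n_episodes - 1:
            for j in range(1, saccade_frames + 1):
                t.append(tt)
                v.append(end + j * (nxt - end) / (saccade_frames + 1))
                tt += 1.0 / fs
        base = nxt
    t = np.asarray(t)
    angles = np.column_stack([np.zeros_like(t), np.asarray(v)])
    if noise_deg > 0:
        angles = angles + rng.normal(0.0, noise_deg, angles.shape)
    truth = {"n_saccades": n_episodes - 1, "durations_s": np.asarray(durations),
             "episode_starts": np.asarray(starts)}
    return t, angles, truth


def trial_rng(seed: int, participant: int, mode: str, trial: int) -> np.random.Generator:
    """One reproducible stream per (seed, participant, mode, trial)."""
    mode_idx = {"Manual": 0, "Auto-Replay": 1, "Auto-Stock": 2}.get(mode, 9)
    return np.random.default_rng(
        np.random.SeedSequence([seed, participant, mode_idx, trial]))


def participant_offsets(cfg: SynthConfig) -> np.ndarray:
    """Between-participant offsets on the GF mean, N(0, participant_sd),
    centred to sum to zero so the population mean preview time is exactly
    ``gf_mean_th_s`` (the generator defines the ground truth)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    off = rng.normal(0.0, cfg.participant_sd_s, cfg.n_participants)
    return off - off.mean()


def simulate_dataset(cfg: SynthConfig,
                     track_cfg: TrackConfig | None = None,
                     cam: CameraModel | None = None,
                     window: TrialWindow | None = None) -> list[TrialData]:
    """Full dataset: n_participants x 3 modes x n_trials trials.

    Deterministic for a fixed ``cfg.seed`` (one RNG stream per trial),
    so regeneration is byte-identical.
    """
    track_cfg = track_cfg or TrackConfig()
    cam = cam or CameraModel()
    midline = build_midline(track_cfg)
    window = window or default_trial_window(track_cfg)
    offsets = participant_offsets(cfg)

    trials: list[TrialData] = []
    base_traj = simulate_trajectory(midline, window)
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        for mode in ("Manual", "Auto-Replay", "Auto-Stock"):
            for tr in range(cfg.n_trials):
                rng = trial_rng(cfg.seed, p, mode, tr)
                gaze, truth, eps = simulate_gaze(
                    base_traj, midline, cam, cfg, mode=mode, rng=rng,
                    gf_mean_override=cfg.gf_mean_th_s + offsets[p])
                veh = base_traj.copy()
                for df in (veh, gaze, truth):
                    df.insert(0, "participant", pid)
                    df.insert(1, "mode", mode)
                    df.insert(2, "trial", tr)
                trials.append(TrialData(participant=pid, mode=mode, trial=tr,
                                        vehicle=veh, gaze=gaze, truth=truth,
                                        episodes=eps))
    return trials
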