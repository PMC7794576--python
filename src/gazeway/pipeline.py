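"""End-to-end orchestration: synth -> TH -> mixture -> sequencing -> inference.

Each stage reads and writes tidy tables; ``run_all`` chains them,
fails fast with stage-labelled errors and records a manifest (config
snapshot, seed, output digests) so a run can be reproduced and
verified bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .camera import CameraModel, screen_to_angles_deg
from .headway import HeadwayConfig, estimate_time_headway
from .inference import PosteriorSummary, fit_condition_model, summarise_participants
from .mixture import DataSparsityError, GazeTHMixture, summarise_fit
from .segmentation import GazeSegmenter, saccade_th_stats, segments_to_frame
from .synth import SynthConfig, TrialData, simulate_dataset
from .track import TrackConfig, analysis_window, build_midline

MEASURES = ("median_th", "gf_mean", "ef_mean", "gf_weight",
            "launch_th", "land_th", "tracking_duration")


class StageError(RuntimeError):
    """Pipeline failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    camera: CameraModel = field(default_factory=CameraModel)
    approach_m: float = 40.0
    inference_seed: int = 0
    measures: tuple = MEASURES


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True, default=str))
        return path


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


# ----------------------------------------------------------------------


def run_th_stage(trials: list[TrialData], track_cfg: TrackConfig,
                 cam: CameraModel, approach_m: float = 40.0,
                 headway_cfg: HeadwayConfig = HeadwayConfig()) -> pd.DataFrame:
    """TH table over the analysed span (approach straight + bend)."""
    midline = build_midline(track_cfg)
    window = analysis_window(track_cfg, approach_m=approach_m)
    parts = []
    for tr in trials:
        if tr.gaze.empty:
            raise StageError("th", f"trial {tr.participant}/{tr.mode}/{tr.trial}"
                             " has no gaze samples")
        parts.append(estimate_time_headway(
            tr.vehicle, tr.gaze, midline, cam, window=window, cfg=headway_cfg))
    return pd.concat(parts, ignore_index=True)


def run_mixture_stage(th_table: pd.DataFrame, track_cfg: TrackConfig,
                      approach_m: float = 40.0):
    """Per participant x mode grid-initialised mixture fits on pooled
    included samples.  Returns (fits table, dict of fitted estimators)."""
    bend_entry_time = approach_m / track_cfg.speed_mps
    inc = th_table[~th_table["excluded"].astype(bool)]
    rows, fits = [], {}
    for (pid, mode), g in inc.groupby(["participant", "mode"], observed=True):
        X = g[["time_into_trial_s", "th_s"]].to_numpy()
        try:
            fit = GazeTHMixture(bend_entry_time_s=bend_entry_time).fit(X)
        except DataSparsityError as exc:
            warnings.warn(f"mixture fit skipped for {pid}/{mode}: {exc}")
            continue
        summ = summarise_fit(fit, X)
        fits[(pid, mode)] = fit
        rows.append({
            "participant": pid, "mode": mode,
            "mu_gf": fit.mu_gf_, "sigma_gf": fit.sigma_gf_,
            "c_ef": fit.c_ef_, "sigma_ef": fit.sigma_ef_,
            "w_gf": fit.weights_[0], "w_ef": fit.weights_[1],
            "w_noise": fit.weights_[2],
            "gf_mean_th": summ.gf_mean_th, "ef_mean_th": summ.ef_mean_th,
            "composed_mean_th": summ.composed_mean_th,
            "gf_weight": summ.gf_weight, "ef_weight": summ.ef_weight,
            "log_likelihood": fit.log_likelihood_, "n_iter": fit.n_iter_,
            "init_id": fit.init_id_, "n_samples": len(X),
            "inverted": summ.inverted,
        })
    if not rows:
        raise StageError("mixture", "no participant x mode cell had enough data")
    return pd.DataFrame(rows), fits


def run_sequence_stage(trials: list[TrialData], th_table: pd.DataFrame,
                       track_cfg: TrackConfig, cam: CameraModel,
                       approach_m: float = 40.0,
                       segmenter: GazeSegmenter | None = None):
    """Segment each trial's included gaze trace; collect saccade
    launch/land THs and tracking durations on the bend portion."""
    speed = track_cfg.speed_mps
    bend_window = (approach_m / speed,
                   (approach_m + np.pi * track_cfg.bend_radius_m) / speed)
    seg_rows, ev_rows, dur_rows = [], [], []
    for tr in trials:
        sub = th_table[(th_table.get("participant") == tr.participant)
                       & (th_table.get("mode") == tr.mode)
                       & (th_table.get("trial") == tr.trial)]
        if sub.empty:
            continue
        merged = sub.merge(tr.gaze[["t", "screen_x", "screen_y"]], on="t")
        inc = merged[~merged["excluded"].astype(bool)]
        if len(inc) < 5:
            continue
        angles = screen_to_angles_deg(cam, inc[["screen_x", "screen_y"]].to_numpy())
        seg = (segmenter or GazeSegmenter()).__class__(
            **(segmenter.get_params() if segmenter else {}))
        seg.fit((inc["t"].to_numpy(), angles))
        labels = dict(participant=tr.participant, mode=tr.mode, trial=tr.trial)
        seg_rows.append(segments_to_frame(seg.segments_, **labels))
        events, episodes = saccade_th_stats(seg.segments_, sub,
                                            bend_window=bend_window)
        for e in events:
            ev_rows.append({**labels, "launch_th": e.launch_th_s,
                            "land_th": e.land_th_s, "forward": e.forward})
        for ep in episodes:
            dur_rows.append({**labels, "duration_s": ep.duration_s})
    segments = pd.concat(seg_rows, ignore_index=True) if seg_rows else pd.DataFrame()
    events = pd.DataFrame(ev_rows, columns=["participant", "mode", "trial",
                                            "launch_th", "land_th", "forward"])
    durations = pd.DataFrame(dur_rows, columns=["participant", "mode", "trial",
                                                "duration_s"])
    return segments, events, durations


def build_participant_summaries(th_table: pd.DataFrame, fits_table: pd.DataFrame,
                                events: pd.DataFrame,
                                durations: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x mode x measure, medians for pooled
    sample/event measures and fitted values for mixture summaries."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parts = []
        inc = th_table[~th_table["excluded"].astype(bool)]
        parts.append(summarise_participants(inc, "th_s", "median_th"))
        for measure, col in [("gf_mean", "gf_mean_th"), ("ef_mean", "ef_mean_th"),
                             ("gf_weight", "gf_weight")]:
            sub = fits_table[["participant", "mode", col]].rename(
                columns={col: "value"}).copy()
            n_nan = sub["value"].isna().sum()
            if n_nan:
                warnings.warn(f"{measure}: {n_nan} participant x mode cells "
                              "had an empty cluster and were omitted")
            sub = sub.dropna(subset=["value"])
            sub["measure"] = measure
            parts.append(sub[["participant", "mode", "measure", "value"]])
        fwd = events[events["forward"]] if len(events) else events
        if len(fwd):
            parts.append(summarise_participants(fwd, "launch_th", "launch_th"))
            parts.append(summarise_participants(fwd, "land_th", "land_th"))
        if len(durations):
            parts.append(summarise_participants(durations, "duration_s",
                                                "tracking_duration"))
    return pd.concat(parts, ignore_index=True)


def run_inference_stage(summaries: pd.DataFrame, measures=MEASURES,
                        seed: int = 0) -> tuple[pd.DataFrame, dict]:
    posts: dict[str, PosteriorSummary] = {}
    frames = []
    for i, measure in enumerate(measures):
        sub = summaries[summaries["measure"] == measure]
        if sub.empty:
            warnings.warn(f"no summaries for measure {measure}; skipped")
            continue
        post = fit_condition_model(sub, measure=measure, seed=seed + i)
        posts[measure] = post
        frames.append(post.to_frame())
    if not frames:
        raise StageError("inference", "no measure had any summaries")
    return pd.concat(frames, ignore_index=True), posts


# ----------------------------------------------------------------------


def run_all(cfg: PipelineConfig, out_dir=None):
    """Execute every stage in order.  Returns (manifest, results dict);
    when ``out_dir`` is given all tables and the manifest are written
    there as CSV/JSON."""
    manifest = RunManifest(config=dataclasses.asdict(cfg), seed=cfg.synth.seed,
                           version=__version__)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            trials = simulate_dataset(cfg.synth, track_cfg=cfg.track,
                                      cam=cfg.camera)
        except Exception as exc:
            raise StageError("synth", str(exc)) from exc
        try:
            th_table = run_th_stage(trials, cfg.track, cfg.camera,
                                    cfg.approach_m)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("th", str(exc)) from exc
        try:
            fits_table, fits = run_mixture_stage(th_table, cfg.track,
                                                 cfg.approach_m)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("mixture", str(exc)) from exc
        try:
            segments, events, durations = run_sequence_stage(
                trials, th_table, cfg.track, cfg.camera, cfg.approach_m)
        except Exception as exc:
            raise StageError("sequence", str(exc)) from exc
        try:
            summaries = build_participant_summaries(th_table, fits_table,
                                                    events, durations)
            posterior_table, posteriors = run_inference_stage(
                summaries, cfg.measures, seed=cfg.inference_seed)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("inference", str(exc)) from exc
        caught = [str(w.message) for w in wlist]

    results = {
        "th_table": th_table, "fits_table": fits_table, "segments": segments,
        "events": events, "durations": durations, "summaries": summaries,
        "posterior_table": posterior_table,
    }
    manifest.warnings = caught
    manifest.digests = {k: _digest(v) for k, v in results.items()
                        if isinstance(v, pd.DataFrame)}
    results["fits"] = fits
    results["posteriors"] = posteriors

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("th_table", "fits_table", "segments", "events",
                     "durations", "summaries", "posterior_table"):
            results[name].to_csv(out / f"{name}.csv", index=False)
        manifest.to_json(out / "manifest.json")
    return manifest, results
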