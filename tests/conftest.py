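import numpy as np
import pytest

from gazeway.camera import CameraModel
from gazeway.headway import estimate_time_headway
from gazeway.pipeline import run_mixture_stage, run_th_stage
from gazeway.synth import SynthConfig, simulate_dataset, simulate_gaze, simulate_trajectory
from gazeway.track import TrackConfig, analysis_window, build_midline, default_trial_window


@pytest.fixture(scope="session")
def track_cfg():
    return TrackConfig()


@pytest.fixture(scope="session")
def midline(track_cfg):
    return build_midline(track_cfg)


@pytest.fixture(scope="session")
def cam():
    return CameraModel()


@pytest.fixture(scope="session")
def trajectory(midline, track_cfg):
    """One trial's 60 Hz vehicle states (approach + bend + exit straight)."""
    return simulate_trajectory(midline, default_trial_window(track_cfg))


@pytest.fixture(scope="session")
def one_trial(trajectory, midline, cam, track_cfg):
    """One clean-ish synthetic trial: gaze, ground truth and TH table."""
    cfg = SynthConfig(seed=7)
    gaze, truth, episodes = simulate_gaze(
        trajectory, midline, cam, cfg, mode="Manual",
        rng=np.random.default_rng(7))
    th = estimate_time_headway(trajectory, gaze, midline, cam,
                               window=analysis_window(track_cfg))
    return {"gaze": gaze, "truth": truth, "episodes": episodes, "th": th,
            "cfg": cfg}


@pytest.fixture(scope="session")
def default_dataset():
    """The full default synthetic study: 11 participants x 3 modes."""
    return simulate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_fits(default_dataset, track_cfg, cam):
    """TH table and per-cell mixture fits for the default study."""
    th = run_th_stage(default_dataset, track_cfg, cam)
    fits_table, fits = run_mixture_stage(th, track_cfg)
    return {"th_table": th, "fits_table": fits_table, "fits": fits}
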