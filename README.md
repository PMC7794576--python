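# gazeway

Analysis tools for **gaze time headway** during simulator driving:
how far ahead — in seconds of travel — a driver is looking, how that
preview distance decomposes into distinct fixation strategies, and how
it differs between manual and automated driving modes.

The package targets eye-tracking researchers working with
fixed-base driving simulators: it turns raw 60 Hz vehicle and gaze
logs into a time-headway signal on the track midline, decomposes that
signal with a fixed-slope regression mixture, parses the gaze trace
into tracking episodes and saccades, and runs Bayesian condition
contrasts — with a synthetic-data generator that reproduces the
assumed gaze phenomenology with full ground truth, so every stage can
be validated by parameter recovery.

## The model

Driving a bend, gaze mostly tracks *waypoints* on the future path 1–3 s
ahead: a saccade lands on a point in the world, the eyes pursue it for
~0.35 s while the vehicle approaches it, then a new saccade jumps
ahead (a "sawtooth", as in optokinetic nystagmus). Let `x` be time
into the trial (arc-length progress along the track midline divided by
speed) and `TH` the gaze time headway — the along-midline distance
from the vehicle to the *gaze midline reference* (the midline point
whose screen projection is nearest the gaze point), divided by speed.
In `(x, TH)` coordinates a fixated world point is a line of slope −1;
gaze that keeps a constant preview time is a line of slope 0. Gaze is
therefore modelled as a three-component regression mixture with
**fixed slopes**:

    GF    :  TH ~ Normal(mu_GF, sigma_GF)            (slope 0: guiding fixations)
    EF    :  TH ~ Normal(c_EF − x, sigma_EF)         (slope −1: bend-entry fixations)
    noise :  TH ~ Uniform(0, 8)                      (fixed outlier component)

with mixing weights on the simplex. `mu_GF` is the mean preview time
(seconds); `c_EF` is the time-along-midline position of a single
*principal attractor point* just past the bend entry. The four free
parameters (two intercepts, two standard deviations) plus the weights
are estimated by EM from a sparse grid of initial values, keeping the
highest-likelihood fit; each sample gets a responsibility vector
rather than a hard label. Saccade/tracking parsing uses exact
dynamic-programming segmented linear regression on the gaze angle
trace, and condition contrasts come from a hierarchical normal model
`value[p,c] ~ Normal(mu_c, sigma)` sampled with emcee (posterior
means, 95% HDIs, posterior mass above zero).

## Worked example

Fit the mixture to one simulated driver's pooled Manual-mode trials:

```python
import numpy as np
from gazeway import (CameraModel, GazeTHMixture, SynthConfig, TrackConfig,
                     build_midline, estimate_time_headway, simulate_gaze,
                     simulate_trajectory, summarise_fit)
from gazeway.track import analysis_window, default_trial_window

track = TrackConfig()            # two 120 m straights, 25 m bends, 8 m/s
midline = build_midline(track)
cam = CameraModel()              # eye 1.2 m up, 1 m from an 89x58 deg display

trajectory = simulate_trajectory(midline, default_trial_window(track))
cfg = SynthConfig()
samples = []
for trial in range(2, 6):
    gaze, truth, _ = simulate_gaze(trajectory, midline, cam, cfg, "Manual",
                                   rng=np.random.default_rng(trial))
    th = estimate_time_headway(trajectory, gaze, midline, cam,
                               window=analysis_window(track))
    samples.append(th.loc[~th.excluded, ["time_into_trial_s", "th_s"]])
X = np.vstack([s.to_numpy() for s in samples])

fit = GazeTHMixture(bend_entry_time_s=5.0).fit(X)
summary = summarise_fit(fit, X)
print(f"guiding-fixation mean TH : {fit.mu_gf_:.2f} s (sd {fit.sigma_gf_:.2f})")
print(f"entry-fixation attractor : {fit.c_ef_ - 5.0:.2f} s past bend entry")
print(f"cluster weights GF/EF    : {summary.gf_weight:.2f} / {summary.ef_weight:.2f}")
print(f"composed mean TH         : {summary.composed_mean_th:.2f} s")
```

Output:

```
guiding-fixation mean TH : 1.95 s (sd 0.33)
entry-fixation attractor : 1.09 s past bend entry
cluster weights GF/EF    : 0.98 / 0.02
composed mean TH         : 1.94 s
```

The generator placed guiding fixations at a mean preview of 2.0 s and
the attractor 1.0 s of travel past the bend entry; the fitted values
recover both through the full screen-projection and midline-mapping
chain. The composed mean (the noise-free weighted average of the two
cluster means) tracks the empirical mean of the included samples.

The same chain is available from a shell:

```bash
gazeway synth --out data/ --seed 1
gazeway th --vehicle data/vehicle.csv --gaze data/gaze.csv --out th.csv
gazeway mixfit --th-table th.csv --out-dir fits/
gazeway sequence --vehicle data/vehicle.csv --gaze data/gaze.csv \
        --th-table th.csv --out-dir seq/
gazeway infer --summaries summaries.csv --measure median_th --out post/ --seed 1
gazeway all --out-dir run/ --seed 1       # everything, with a manifest
```

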