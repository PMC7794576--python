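# Methods

This note documents the models and procedures implemented in
`gazeway`, the defaults they ship with, and the reasoning behind the
choices that were genuinely open.

## Track geometry and coordinates

The analysis track is a stadium curve: two straights of 120 m joined
by two semicircular bends of 25 m radius (road width 3 m, constant
speed 8 m/s). The midline is discretised at 0.05 m; cumulative chord
length agrees with the analytic perimeter `2L + 2πR ≈ 397.08 m` to
better than 1e-6 relative error, and linear interpolation between
vertices keeps the chord error on bends below 1e-5 m — negligible
against gaze noise. Arc 0 is the start of the first straight at
`(0, 0)`, travel is counter-clockwise, and all arc arithmetic wraps
modulo the perimeter. Time along the midline is arc length over
speed, so the trial clock and gaze time headway share units. The
analysed trial segment runs from 40 m before the bend entry to the
bend exit (the exit straight is simulated but excluded from
analysis); bend entry is therefore at 5.0 s into the trial and the
trial spans 158.5 m ≈ 19.8 s including the exit straight.

Nearest-point projection onto the midline refines the nearest-vertex
query with a projection onto the two adjacent polyline segments; exact
ties (such as the centre of a bend circle) resolve to the smallest arc
value.

## Gaze time headway estimation

Projecting gaze from the screen into the world is ill-conditioned
near the horizon: the projected ground distance diverges as the
vertical gaze angle approaches zero, so small calibration errors
produce unbounded headway estimates and skew means. The estimator
therefore never projects screen-to-world. Instead, the midline points
within a forward window of 0–8 s of travel are projected *world-to-
screen* through a pinhole model of the display (eye 1.2 m above the
ground plane, screen plane 1 m ahead, 89° × 58° field of view,
normalised screen coordinates), and each gaze sample is assigned the
candidate whose projection is nearest in screen coordinates — the
gaze midline reference. TH is the wrap-aware along-midline distance
from the vehicle's own midline foot point to the reference, divided
by speed; lane-position offsets are deliberately ignored. The
forward window bounds the search and prevents matches on the far side
of the oval; 8 s exceeds every preview value the analysis deals with.
Candidates are spaced 0.1 m apart, bounding the TH discretisation
error at 0.0125 s. Screen-distance ties resolve to the nearer
candidate.

Four exclusion filters run in a fixed order, each sample keeping the
first reason that fires: (1) pupil-detection confidence below 0.6;
(2) gaze outside the display surface; (3) gaze more than 20° of
visual angle from its midline reference (also raised when no forward
candidate is visible); (4) gaze inside one of five square optical
marker regions bordering the stimulus (side 0.05 of screen height —
the marker geometry is configurable since only their existence, not
their size, is fixed). The angular error metric is the visual angle
between the gaze ray and the reference ray through the camera model.
Gaze and vehicle streams are joined by nearest timestamp with at most
half a frame (1/120 s) of mismatch.

A known artefact of nearest-point mapping: where the projected
midline changes direction sharply (the bend entry seen from the
approach straight), reference points pile up at the corner, creating
a spurious density ridge along the corner's slope −1 line. It is
small (a few percent of samples under drift-like noise) but can
attract the entry-fixation cluster of the mixture when the true
attractor signal in a cell is weak; the grid fit's audit trail
(`candidate_log_likelihoods_`) makes such cells easy to inspect.

## The regression mixture

In (time-into-trial, TH) coordinates the mixture has a slope-0
Gaussian component (guiding fixations, free mean `mu_GF` and sd), a
slope −1 Gaussian component (entry fixations, free intercept `c_EF` —
the attractor's time-along-midline position — and sd), and a noise
component with *fixed* density. The noise density is uniform on
[0, 8 s] — the forward-window support — because a maximum-entropy flat
density cannot absorb structure from the two clusters, only
outliers; its weight remains free. One attractor component is fitted,
which counters overfitting on noisy cells; the class accepts any
initial grid, so variants with shifted attractor hypotheses are a
configuration away.

EM is fully deterministic. E-steps are computed in log space with
log-sum-exp; M-steps are the closed-form responsibility-weighted
means and standard deviations (for the EF component the intercept
estimate is the weighted mean of `TH + x`). Convergence is an
absolute log-likelihood change below 1e-6, capped at 500 iterations.
A component whose sd collapses below 0.01 s is pruned to weight zero
and flagged rather than allowed to chase a degenerate density spike.
Fits are refused below 50 samples — sparse cells bias the intercepts.
The default initialisation grid crosses `mu_GF ∈ {1.5, 2.0, 2.5}` s
with `c_EF ∈ bend-entry time + {0.5, 1.0, 1.5}` s (sds 0.5 s, weights
0.6/0.3/0.1), spanning the plausible preview and attractor ranges;
the highest-likelihood converged fit wins and all candidate
likelihoods are retained for audit. Because the two structural
components have different fixed slopes, there is no label-switching
ambiguity.

Cells are pooled per participant × driving mode across trials before
fitting. Cluster summaries report responsibility-weighted means of
the *observed* TH per cluster; the composed mean excludes the noise
component from its weight renormalisation (whether to include it was
open; excluding it makes the composed mean interpretable as the
noise-free preview and is flagged in the summary docstring).

## Gaze sequencing

Segmentation operates on gaze position converted to visual-angle
degrees (horizontal and vertical), not on TH — the parser should see
the oculomotor signal, with headway attached to events afterwards. An
exact dynamic programme minimises total OLS residual plus a penalty
per segment (O(n²) with O(1) per-window costs from prefix sums;
trial traces of ~900 frames take tens of milliseconds; gaps longer
than 3 frames split the trace). The default penalty of 6 deg² was
calibrated so that a pure-noise constant trace at 0.5° sd of trial
length yields exactly one segment across seeds.

Two-sample mid-saccade points are often cheaper for the DP to absorb
as edge outliers of the flanking tracking fits than to isolate as
their own segment. A refinement pass therefore inspects every
boundary where the two fitted lines disagree by more than 1° of
visual angle, searches over stripping up to two samples from each
side (each stripped sample is charged twice the local mean residual,
so only genuine outliers pay off), and promotes the stripped run to a
saccade segment whose speed is the fitted jump over its span.
Classification then labels a segment a saccade iff its mean angular
speed exceeds 40 deg/s *and* its duration is at most 0.12 s — fast
smooth drifts fail the duration criterion and stay tracking.
Consecutive same-kind tracking segments merge only when their fitted
lines agree at the boundary, so unresolved jumps do not inflate
inter-saccadic durations.

Saccade statistics are restricted to the bend portion of the track
(prolonged bend-entry fixations on the approach would confound the
waypoint-tracking analysis). Launch and land TH come from the nearest
included TH samples within two frames of the segment boundaries;
events missing either sample are dropped, and only forward saccades
(land > launch) enter the launch/land analysis. Saccades below about
2.5° of amplitude fall under the noise floor of any velocity-and-
penalty-based parser, ours included: synthetic recovery checks use
the canonical sawtooth trace whose jumps are all detectable, and the
pipeline's duration median on fully heterogeneous traces runs
slightly high (~0.38 s against a generative 0.35 s) because
micro-saccades merge into their neighbours.

## Condition inference

Per-participant summaries are medians for pooled sample- and
event-level measures (TH and duration distributions are
right-skewed); mixture summaries pass through as fitted values.
The condition model is `value[p,c] ~ Normal(mu_c, sigma)` with
weakly informative priors `mu_c ~ Normal(center, 1)` and
`sigma ~ HalfNormal(1)`; prior centres are 2.0 s for headway
measures, 0.4 s for durations and 0.5 for weights, reflecting the
established preview and tracking-duration ranges. Sigma is shared
across conditions by default; a per-condition variant sits behind a
flag. Posteriors are sampled with emcee using
differential-evolution moves: four *independent* ensembles of 16
walkers, 500 warm-up and 800 retained steps each (51 200 pooled
draws). R-hat is computed between the independent ensembles — a
stricter notion than splitting one ensemble's correlated walkers —
and gates at 1.01; failures raise with diagnostics attached.
Contrasts (Replay−Manual, Stock−Manual, Stock−Replay) are computed
per draw; intervals are 95% highest-density intervals and the
posterior mass above zero is reported per contrast. Under
model-true null simulation the 95% HDIs exclude zero in about 5% of
datasets (the suite checks 100 runs).

## The synthetic-data generator

The generator emulates the phenomenology the analysis assumes, with
full ground truth: sawtooth waypoint tracking (episode durations
N(0.35 s, 0.08²), preview draws N(2.0 s + mode shift, 0.3²)
truncated to (0.5, 6) s), a single bend-entry attractor 1.0 s of
travel past the entry that captures new episodes with probability
0.4 while the attractor is within 3.5 s ahead, 2-frame linear
screen-space saccades, 5% artefact samples, and mode shifts of
+0.17 s (Auto-Replay) and +0.22 s (Auto-Stock) on the preview mean,
with the same shift lengthening the attractor onset lead (the bend is
fixated earlier under automation). Eleven participants with
between-participant preview offsets N(0, 0.15 s) — drawn once and
centred to sum to zero so the population mean is exactly the
configured value — three modes, and (by default) two trials per cell
at 60 Hz.

Three parameterisation choices deserve note:

* **Preview anchoring.** `gf_mean_th_s` is the mean *emitted* TH of a
  tracking episode: the waypoint is placed so the TH at the episode's
  temporal midpoint equals the drawn value. Anchoring at episode
  start would bias the emitted marginal low by half a tracking
  duration (TH decays at slope −1 while tracking), making the
  nominal mean unrecoverable by construction.
* **Noise structure.** Measurement error is split into a slowly
  varying AR(1) component (RMS 1.5°, correlation time 3 s),
  standing in for miscalibration and drift between calibration
  anchors, and white frame-to-frame tremor (RMS 0.3°). Injecting the
  full 1.5° as white noise would be unphysical for an eye tracker and
  would obliterate the oculomotor structure the segmenter needs; the
  split leaves the TH marginals essentially unchanged.
* **Artefacts.** Off-task samples are drawn from the classes the
  exclusion filters remove — low confidence, far off-road corner
  glances, marker glances — so the realised exclusion fraction tracks
  the configured artefact rate. Robustness of the mixture to
  *included* outliers is exercised separately with uniform TH-space
  noise in its own tests.

Each trial has its own RNG stream derived from
(seed, participant, mode, trial), so datasets are byte-identical
under regeneration and individual trials can be regenerated in
isolation.

What the generator does **not** emulate — and what passing recovery
tests therefore do not establish for real data: steering dynamics and
lane deviation (the vehicle rides the midline exactly), head motion
and the marker-homography correction (gaze is generated directly in
screen coordinates), pupil-size and blink artefacts, lookahead
fixations beyond the single bend-entry attractor, and any coupling
between gaze and steering. Mixture recovery tolerances should be read
against the generator's own idealisations: its guiding-fixation
marginal is a mixture of decaying episodes rather than an exact
slope-0 Gaussian, which is precisely the approximation the slope-0
cluster makes.

## Problem sizes and runtimes

The default synthetic study is 11 participants × 3 modes × 2 trials
(66 trials, ~59 000 gaze samples), chosen so the full pipeline —
generation, headway estimation, 33 grid-initialised mixture fits,
segmentation and seven posterior fits — completes in about half a
minute while keeping every per-cell fit above 1 500 samples. The
segmentation recovery checks pool 20 sawtooth traces of 25 episodes;
the HDI calibration check simulates 100 null datasets. The end-to-end
reproduction script (`scripts/acceptance.py`) runs all of the above
in roughly six minutes.

## Known limitations

* Midline-mapped TH is not exactly unbiased under angular measurement
  error: the nearest-point geometry responds asymmetrically to gaze
  offsets along versus across the projected midline, and with the
  default drift noise the recovered population preview runs about
  0.02–0.05 s low of the generative 2.0 s depending on the noise
  realisation (it is exact when noise is switched off). The
  between-mode *shifts* are unaffected, since the bias is common to
  all modes.
* The nearest-point corner pileup at bend entry (above) can capture
  the EF component in cells where true attractor fixations are
  scarce, biasing the fitted attractor earlier by a few tenths of a
  second on single-trial fits; pooling trials per cell suppresses it.
* The EF mixing weight under-counts attractor samples whose TH lies
  inside the guiding band — maximum likelihood shares that overlap
  mass with the GF cluster. Cluster means are much less affected than
  weights.
* Micro-saccades below the angular noise floor are unrecoverable by
  the parser and slightly inflate tracking durations on fully
  heterogeneous traces.
* The condition model ignores the pairing of participants across
  modes; with participants present in all three modes this widens
  contrast intervals (conservative) but does not bias their means.
* Reading a deposited experiment's native file layout requires an
  adapter mapping its columns onto the vehicle/gaze table contracts in
  `gazeway.io`; only the CSV contracts themselves ship here.
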