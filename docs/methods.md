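# Methods

## Task model and segmentation

A trial is a uniformly sampled (nominally 100 Hz) 3-D needle-tip trajectory
with a synchronous binary flashback channel (an in-needle LED standing in
for visible blood return).  All metrics are computed on the *constrained
task*: the window from `t_entry`, the first sample at which the tip's
z-position drops below the skin plane, to `t_end`, the last recorded
sample.  First-crossing segmentation deliberately keeps re-emergences and
reinsertion attempts inside one window; a trial whose tip never crosses the
skin is unusable and is excluded, not repaired.  No debouncing is applied
to either the skin crossing or the flash channel by default (an optional
minimum-run filter exists for noisy real recordings); the literal rule is
the default because the flash-ratio extremes 0 and 1 must be achievable
exactly.

Flash intervals use a sample-and-hold convention: a run of `flash == 1`
samples extends to the timestamp of the first subsequent zero sample, and a
run reaching the final sample ends exactly at `t_end`.  Consequently an
uninterrupted flashback has FR = 1 and an absent one FR = 0, both to
machine precision.  A flashback confined to the single final sample makes
FR 0/0 and is reported as a degenerate trial rather than silently scored.

## Derivative estimation

Position and its first three derivatives are estimated per axis with a
third-order Savitzky–Golay filter — the lowest polynomial order carrying a
jerk estimate — at a configurable odd window span; {5, 25, 51, 101, 201}
samples is the default sweep (minimum through two seconds at 100 Hz).
Edges are handled by evaluating the polynomial fitted to the terminal
window (`mode="interp"`), never by padding or reflection: padding modes
distort jerk at the boundaries, which dominate short trials.  Derivative
scaling uses the empirical mean sample interval, not the nominal rate.
Records with more than 1% median timing jitter are rejected at
construction; an explicit linear-interpolation resampler is the escape
hatch, so non-uniform data can never flow through the filter silently.

The speed profile is the Euclidean norm of the velocity vector — not the
derivative of the scalar distance from the origin, which would be
origin-dependent.  Peak counting uses strict local maxima with a
configurable prominence floor (default 0, i.e. the literal rule, plus a
floor at 1e-12 of the peak speed so roundoff wiggles on analytically flat
profiles never count).  Note that the local cubic fits leave sub-mm/s
ripples at submovement junctions; analyses of composed noise-free
trajectories should use a small prominence floor if they want to count
submovements rather than filter artefacts.

## Smoothness metrics

**LDLJ** integrates the squared 3-D jerk-vector norm over the task window
by the trapezoidal rule, scales by T⁵/PL² to cancel units, and returns the
negative log.  The 3-D norm (rather than per-axis sums) makes the value
rotation-invariant.  A single minimum-jerk movement gives exactly
∫‖jerk‖²dt = 720·A²/T⁵ and PL = A, hence LDLJ = −ln 720 — the analytic
oracle asserted to 1% in the tests.  A dimensionless jerk below 1e-15
(floating-point noise; physical motion is ≥ 720) is reported as undefined
rather than logged.

**SPARC** takes the magnitude spectrum of the speed profile (FFT length:
record length rounded up to a power of two, shifted by a pad level of 4),
normalises by the DC value V(0), finds the adaptive cutoff ω_c — the
largest frequency at or below 2π·10 Hz where the normalised magnitude
still reaches 0.05 — and returns the negative arc length of the normalised
spectrum over [0, ω_c] with the frequency axis normalised by ω_c.  The
normalised axis alone contributes arc length 1, so SPARC ≤ −1 always, and
amplitude scaling cancels exactly.  Pad level, cutoff ceiling and amplitude
threshold follow the metric's published reference defaults and are
config-exposed.  The arc-length integrand is the canonical
√((1/ω_c)² + (dV̂/dω)²).

## Statistical analysis

Per window span, each process metric is transformed to tame skew and point
the same way (larger = better): −log T, −log PL, −log(Pks + 1) (the +1
handles zero-peak trials), LDLJ unchanged (already a log), and
−log(−SPARC), monotone increasing in SPARC (a config flag disables the
SPARC log).  Columns are then z-scored (zero mean, unit sample variance).
Each indicator (FR per trial; GRS and Exp per participant, broadcast to
trials) is regressed on each standardised metric by simple OLS.  Broadcast
pooling repeats the emulated study design; the clustering violation it
implies is documented, not corrected — mixed-effects reanalysis is out of
scope.

Pairwise slope contrasts use Tukey's adjustment: CI half-width
q_{α; r, n−r}·SE with the studentized-range quantile, r the number of
compared groups (5 metrics, or 5 spans) and n the common number of
observations.  SE is the pooled slope standard error
√(mean of the r squared SEs) by default — the residual variance pooled
across the compared regressions — with a per-pair variant behind
`variance="per_pair"`; the two coincide in a balanced design.  Under the
complete null with r = 5 and n = 779 this construction holds the
family-wise type-I error at the nominal 5% (verified by simulation in the
test suite).  Comparisons across spans refit on the trials available at
*every* span so the design stays balanced.

GRS is the sum of four Likert subscores (needle holding, needle movement,
flashback quality, overall quality); palpation is stored in the file
format but excluded from the default score because it does not reflect
needle motion.  The subscore set is configurable, since summed observer
scores are defined differently across studies.

## Synthetic cohort generator

Real cannulation recordings of this kind are restricted human-subjects
data, so the generator produces cohorts with the statistical structure the
analysis assumes.  Defaults: 52 participants × 16 trials (four per
fistula) at 100 Hz.  Each participant carries one latent skill scalar
s ∈ [0, 1] (truncated normal, mean 0.5, SD 0.2); each trial perturbs it
with jitter (SD 0.08) that drives both kinematics and flashback, so the
outcome indicator shares trial-level variance with the process metrics
while the observer and experience indicators, generated from participant
skill only, do not.

A trial is a pre-entry hold, a swift insertion thrust (~0.7 s, crossing
the skin into the fistula 15–25 mm below the start), an adjustment phase,
and a terminal levelling hold.  Skill shapes the adjustment phase in both
length and texture: settling time shrinks from ~1.25× to ~0.25× of a
5.5 s budget as skill rises, and its texture shifts from up to ten quick
jabs (0.3 s each, several mm, separated by arrests) to one or two slow
deliberate corrections (1.2 s).  Many brief sharp submovements are the
kinematic signature of intermittency that LDLJ and SPARC exist to detect;
pause samples hold position exactly constant so peak-count ground truth is
exact.  A lognormal *pace* multiplier (CV 0.2 per participant, 0.1 per
trial), independent of skill, stretches all durations: skilled performers
can still be slow and deliberate, which keeps task time an informative but
imperfect skill proxy, as in real cohorts.

Sensor noise is white Gaussian noise low-pass filtered to a configurable
bandwidth (default 15 Hz; the tracker's true spectrum is not
characterised, so this is surfaced in the spec file, not hard-coded) and
rescaled per axis so the mean absolute height of its local extrema equals
the trial's peak target exactly.  The cohort-level target averages
0.06 mm, with a lognormal trial-to-trial dispersion (CV 1.0):
electromagnetic trackers' jitter varies strongly with sensor pose and
environment, and that dispersion is what degrades the rank information of
noise-dominated minimal-smoothing estimates.  The flashback channel starts
a skill-dependent delay after entry and each quarter-second interval
afterwards goes dark independently with probability 0.5·(1−s), making the
flash ratio stochastically increasing in skill, exactly 1 at s = 1, and
exactly 0 when interruption is forced.

Observer ratings are discretised noisy skill with a shared rater-severity
bias (SD 0.3 on the latent scale — each participant is scored by a single
expert, so rater bias, not per-item scatter, limits reliability).
Experience is drawn with a configurable, by default weak (ρ = 0.15),
correlation to skill, clipped to 0–38 years around a mean of 11 (SD 8.6).
Cohort generation is a pure function of (spec, seed).

**What the generator does not emulate:** physiological tremor,
force/contact dynamics, tissue deformation, marker dropout, rater drift
over time, or learning across trials.  Passing tests on synthetic cohorts
therefore demonstrate that the pipeline recovers the structure it assumes
— not that real cannulation data has that structure.

## Problem sizes in the test suite

The statistical calibration uses 1000 null replicates at n = 779, r = 5.
The smoothing-effect check runs a 50-participant cohort at spans {5, 25};
the indicator-ordering check a 45-participant cohort across all five
spans.  These sizes give stable Monte-Carlo behaviour (the qualitative
conclusions were verified across independent seeds during development)
while keeping the default suite fast.

## Known limitations

* The broadcast regressions understate standard errors because trials are
  clustered within participants; the Tukey calibration holds under the
  i.i.d. null used in the test, not under clustering.
* LDLJ values at the minimal window span are dominated by the sensor-noise
  floor; they are reported as computed, and interpreting them as smoothness
  is exactly the pitfall the span-sweep analysis demonstrates.
* Savitzky–Golay smoothing attenuates submovements shorter than the window
  span, so squared-jerk integrals of fragmented motions are biased low at
  wide spans; the span sweep is a sensitivity analysis, not a search for a
  single correct span.
* FR's dispersion in synthetic cohorts (SD ≈ 0.15) is narrower than in
  real observational data; effect-map coefficients can widen it at the cost
  of a weaker skill link.
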