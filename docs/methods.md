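# Methods

## Stimulus protocol

The protocol is the fixed 53-light sequence over five horizontal LEDs (0°,
±35°, ±40°; negative = clockwise). The first central light is the head-
posture reference and stays lit 10 s; every other light flashes 0.1 s. Each
target flash is followed by a control flash at the same position after a
uniform 1.6–2.4 s lights-off interval, and the next target follows the
control after a uniform 0.8–1.2 s interval. The source only constrains these
intervals by their ranges; uniform draws are the simplest distribution
consistent with the bounds. Consecutive target positions define 52 gaze
shifts; 43 have amplitude 75° or 80° and are the analysed trials. The two
initial 0° lights are both counted as targets (the first flagged as the
reference), which is the only reading under which the printed 53-entry list
yields exactly 52 shifts.

## Forward model

Each gaze shift is built kinematically rather than from a biomechanical
plant:

- **Head velocity** is a minimum-jerk bell `v(t) = 30 H/T · s²(1−s)²`
  (`s = t/T`) with head excursion `H = head_fraction · amplitude`
  (default 0.9) and duration `T = 1.875 / peak_vel_scale_hz` (default
  0.436 s, giving ~300 deg/s peaks for 80° shifts — typical of vigorous
  large gaze shifts).
- **Terminal oscillation**: from the deceleration zero crossing a damped
  sinusoid `−A e^(−t/τ) sin(2πft)` is appended (default f = 2.5 Hz,
  τ = 0.15 s — a single prominent undershoot followed by a much smaller
  rebound). `A` is scaled so the sampled first undershoot equals exactly
  `ratio/100 × v_peak`.
- **Mismatch → ratio map**: `ratio_pct = ratio_gain_pct · |inertia_factor +
  goggles_inertia − internal_inertia|`. The linear map is the simplest
  strictly monotone choice vanishing at zero mismatch; no functional form is
  empirically established.
- **Eye channel** is eye-in-head position, constructed as (gaze − head)
  where gaze follows a faster minimum-jerk profile to the target. Gaze
  therefore lands exactly on the target, i.e. vestibulo-ocular
  counter-rotation during the head oscillation is implicit. During the
  oscillation, gaze speed is ~0 even though head speed is not — movement
  onset detection therefore keys on gaze speed.
- **Learning**: after every movement the internal inertia estimate moves a
  fraction `learning_rate` toward the actual inertia. Between sessions,
  adaptation acquired in unweighted1 carries over; everything learned while
  the helmet was on is attributed to the (visibly removed) helmet and
  discarded. Without this credit assignment a carried-over weighted-session
  model would make the third session's oscillations the largest, which is
  the opposite of what such experiments show.

### Calibration of the defaults

The defaults were set analytically so the injected session means of the
default cohort approximate 2.2 % (unweighted 1), 6.9 % (weighted) and 1.5 %
(unweighted 2): with per-trial mismatch decay `(1−λ)` per movement and 52
movements, the session-3/session-1 ratio fixes `learning_rate λ = 0.0073`,
and the session means then fix `ratio_gain_pct = 3.1` per mismatch unit and
`goggles_inertia = 0.85`. That last value is best read as a *lumped
effective* baseline mismatch — goggle mass plus any initial miscalibration
of the internal model — rather than a literal inertia increment; under the
linear mismatch→ratio map, unweighted oscillations of ~2 % cannot arise from
a physically "slight" goggle term alone.

Variability: a lognormal per-participant multiplier on the ratio gain
(σ = 0.35) and a lognormal per-trial multiplier on the injected ratio
(σ = 0.25), both mean-corrected, reproduce between-participant SDs of
roughly half the session mean, as in this paradigm. Measurement noise is
white, 1 deg/s on head velocity (inertial-sensor scale) and 0.05 deg on eye
position. Early/late mover rates default to the observed per-group rates
(patients 1.3 %/4.4 %, controls 0.3 %/5.1 %).

What the generator does **not** emulate: blinks and tracking dropouts,
vergence/torsion, head-free drift between trials, non-stationary noise, or
any genuine between-group difference (group effects enter only through
explicit parameters). Passing recovery tests therefore demonstrates the
pipeline's correctness on clean, well-specified signals, not robustness to
every artifact of real video-oculography.

## Signal processing

The Gaussian low-pass uses σ_t = √(ln 2)/(2π·f_c), which places the −3 dB
point of the amplitude response `exp(−2π²σ_t²f²)` at the cutoff (20 Hz);
the kernel is truncated at ±4σ, normalized, and applied zero-phase with
reflective padding. The bandwidth convention is a documented choice — the
source names only "20-Hz Gaussian low pass".

Head position is the cumulative trapezoid of head velocity, re-referenced by
subtracting the mean over the initial reference-light window.

Segmentation emits one window per large shift, nominally [target onset,
control onset]. Early/late handling replaces manual review with auditable
heuristics: if gaze speed (head velocity + eye-position derivative) exceeds
20 deg/s between the prior control light going off and target onset, the
window extends back to the prior control light (`extended_early`); if gaze
speed is still above threshold at control onset, or the movement only occurs
after it, the window extends to the next target onset (`extended_late`). A
recording with no movement at all yields 43 unextended segments. The
20-deg/s threshold is configurable; flagged trials are retained and the
flags persisted.

## Events and QC

Traces are rectified by the protocol's direction (wrong-way movements
become indeterminate rather than sign-flipped). Zero crossings are located
by linear interpolation between bracketing samples, ties toward the earlier
sample. If velocity never re-crosses zero after the undershoot, the window
end stands in for the second crossing and the trial stays determinate. Gaze
amplitude is the difference between gaze at window start and the mean over
the final 100 ms plateau.

The exclusion cascade runs strictly in order: indeterminate landmarks →
gaze amplitude < 40° → oscillation ratio beyond ±2 sample SD (n−1
denominator) of the within-session mean, single pass, non-strict boundary
(exactly 2 SD is kept; an all-identical session excludes nothing). Order
matters and is regression-tested. A session with no surviving trials raises
instead of imputing.

## Bayesian model comparison

The response is the participant × session mean ratio. Factors are coded by
orthonormal sum-to-zero contrasts; the subject intercept block is in every
model. Each block b gets `β_b ~ N(0, σ² g_b I)` with
`g_b ~ InvGamma(1/2, r_b²/2)` — Cauchy scale `r_fixed = 0.5` on fixed
effects and `r_random = 1.0` on subjects (common defaults of g-prior
ANOVA software), flat prior on the grand mean, Jeffreys on σ². Conditional
on g the marginal is available in closed form via the Woodbury identity;
the g-integral (1–4 dimensions) is evaluated by a Laplace approximation in
log g refined with importance sampling from a multivariate t (df 7), 2,000
draws by default, with the relative MC standard error reported in every
result. All Bayes factors are ratios to the subject-only null.

Inclusion Bayes factors use the matched-models scheme by default (models
containing an effect vs the same models without it, interaction models
excluded when judging a main effect); the all-models scheme is a flag.
The JZS t test integrates the g-representation by adaptive quadrature; a
quasi-Monte-Carlo backend (scrambled Sobol over the Cauchy effect-size
prior) provides an internal cross-check, and both agree with an independent
effect-size-space quadrature oracle to 1e−4.

The sequential design starts at 10 participants per group and adds 5 per
group per round until the monitored Bayes factor crosses 3 in either
direction or 20 per group is reached. The monitored quantity defaults to
the BF of the group-only model against the subject-only null — the model
comparison such studies report — with the inclusion BF available via
`criterion="inclusion"`.

Known limitation: the evidence-grade boundaries (3, 10, 30, 100) are
assigned half-open upward (a BF of exactly 3 counts as "substantial"); the
verbal scheme itself leaves the boundary assignment open.

## Problem sizes

The operating-characteristics suites use 200 replicates at 15 participants
per group (summary-level simulation) and the full-trace recovery check uses
4 participants per group — sizes at which the Monte-Carlo bands of the
tested proportions are a few percent wide, comfortably inside the asserted
margins, while the whole suite stays inexpensive to run.
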