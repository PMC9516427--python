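# Methods

## Coordinate convention and the intercept model

All data live in the laboratory frame: x anterior, y lateral, z vertical,
floor at z = 0, units meters, uniform sampling at `fs` Hz. A per-eye sample
is a gaze origin (eye position) and a unit gaze vector; a sample is either
fully present or fully missing (NaN in all channels, `valid = False`),
because losing either stream makes the intercept uncomputable.

The pipeline computes the floor intercept the way the acquisition chain
defines it: viewing angle `a` between the gaze vector and the downward
vertical, look-ahead `C = A_z·tan(a)`, intercept `D = A_x + C`. The same
formula is used for untreated and treated data so that treatment
comparisons are not confounded by the intercept computation (the treated
representation only carries `A_x`, `A_z` and `a`). The exact 3-D ray–plane
intersection (`geometry.floor_intercept`) is available and differs from the
angle path only through the lateral gaze component (≈ 0.5 mm at a 3 cm
inter-eye offset); it is tested against an independent bisection oracle at
1e-9 m. Viewing angles ≥ 90° never meet the floor and propagate as missing,
so upward gaze and data loss are handled uniformly.

Quality metrics are evaluated on the anterior–posterior coordinate only
(the protocol arranges targets along x; the Euclidean floor distance is
available behind `distance_mode="euclidean"`). The visual angle of a
target's MAE uses the segment-mean eye height and the look-ahead
`target_x − mean eye x`, with the span split symmetrically about the
target: `angle = atan((L + MAE/2)/h) − atan((L − MAE/2)/h)`. Its inverse is
solved by bracketed root finding on [0, 2L] to 1e-9 m. STD uses the n−1
denominator; RMS-S2S skips sample pairs spanning a gap; undefined metrics
propagate as NaN markers, never as zeros.

## Segmentation

The trial is a staircase: dwell plateaus joined by saccades. Viewing
periods are identified on **untreated** intercepts (mirroring the practice
of confirming periods against the raw trace before treatment), by a
deterministic rule in place of manual confirmation:

1. point-of-gaze speed = |central finite difference| (one-sided next to
   gaps and trial edges, undefined at missing samples);
2. transition candidates are (a) local maxima of the 3-sample
   median-filtered speed strictly above `median + k·MAD` (k = 5), and (b)
   significant jumps of the robust plateau level across dropout gaps —
   without (b), a saccade falling entirely inside a gap leaves no velocity
   peak and the plateau count comes out wrong;
3. candidates are scored by displacement, reduced by non-maximum
   suppression within 0.5 s (windows that nearly touch the winner are
   unioned — one saccade can fire both detectors), and the `n_targets − 1`
   strongest are kept; each window is widened to the flanking speed minima
   but never below the threshold;
4. segments are the intervals between windows, attributed to targets in
   temporal order; within a segment, residual fast samples are excluded by
   re-applying the `median + k·MAD` screen on the segment's own speed
   distribution (point-of-gaze noise grows with look-ahead distance, so a
   global threshold over-excludes far-target samples).

On noise-free synthetic data this recovers ≥ 97% of ground-truth fixation
samples with zero saccade leakage, and segment bounds match ground truth
within ±2 samples.

Eyes are screened per eye: a peak angular velocity (angle between
successive gaze samples × fs) strictly above 350 °/s — the expected peak
for the ~19.4° between-target amplitude on the main sequence — excludes
that eye from the report. Ties at the threshold are retained, since the
bound is itself approximate.

## Signal treatment

Filtering is a 4th-order low-pass Butterworth, applied forward–backward
(zero phase, the movement-science norm; the designed cutoff is not
re-adjusted for the second pass, so the dual-pass response is −6 dB at the
nominal cutoff) with single-pass available. The cutoff is either fixed or
selected per series by a residual-whiteness criterion: over a 0.5 Hz grid
from 1–15 Hz, choose the cutoff whose removed component (raw − filtered)
has lag-1 autocorrelation closest to zero, tie-breaking to the lower
frequency. The criterion function is exposed separately so alternatives can
be swapped in. Origin coordinates and the viewing angle are treated
per-series; the intercept is recomputed from treated components, never
filtered directly.

Gap filling bridges each interior gap with the unique quintic polynomial
matching position, velocity and acceleration at both gap edges, the
boundary state estimated by local least-squares fits over up to 8 valid
samples per side (cubic with ≥ 5 points, degrading to quadratic/linear with
less support) — the construction used by marker-trajectory gap-filling
tools. Boundary derivative terms are damped by `support/span` once the gap
outgrows the support, so very long bridges tend to a smooth step between
the boundary levels; unregularized derivative extrapolation over ~1 s of
jittered data produced unbounded intercept errors after `tan`
amplification. Valid samples are never altered; trends up to the fit degree
are reproduced exactly within the support span; gaps touching the trial
ends stay missing. In the quality pipeline only gaps of at most
`max_gap_fill` samples (default 5 = 0.1 s at 50 Hz) are repaired before
metrics.

### Gap-size study

For each (recording, eye) a baseline is built by treating the complete raw
components (quintic fill over all gaps, autocorrelation-cutoff filter),
recomputing the intercept, and re-masking originally-missing samples, so no
artificial point is ever scored. Cutoffs are selected once per component on
the baseline and reused for every gapped copy. For each gap size
(0–50 samples in steps of 5), single contiguous gaps are cut at random
positions at least 50 samples from the trial ends and treated identically;
the score is the mean absolute intercept difference from the baseline over
the gap window (a config option widens the window, preserving the
alternative reading of "either side of the gap"). The size-0 condition
instead compares treated against untreated data over the whole trial — the
processing-only deviation — matching its definition in the study design.
Gap positions are paired across sizes by common random numbers (one uniform
fraction per gap index mapped into each size's admissible range; the
per-size marginal stays uniform), which removes location-resampling noise
from the size comparison.

## Synthetic recordings

The generator emulates the study protocol: a standing observer (eye height
1.57 m, inter-eye lateral offset ±3 cm) fixates six floor targets at 1–6 m
sequentially over a 30 s, 1500-sample, 50 Hz trial. Design choices:

* **Schedule** — the nominal 2 s dwell per target and the 30 s trial are
  arithmetically incompatible for one pass over six targets; dwells
  therefore stretch uniformly to fill the trial (≈ 4.9 s each at defaults),
  honoring the protocol's "whole trial" phrasing, with `dwell_s` acting as
  the minimum (an infeasible schedule raises).
* **Noise is injected in angular space** (isotropic tangential jitter on
  the gaze vector, applied as an exact rotation), never in world space, so
  the non-linear growth of world-space error with look-ahead distance
  emerges from the geometry rather than being baked in. The default SD of
  0.2°/axis reproduces the precision scale reported for this kind of
  integration (RMS-S2S ~0.01 m at 1 m to ~0.12 m at 6 m). Real recordings
  additionally carry systematic, angle-dependent error (parallax,
  slippage, pupil-detection bias at large viewing angles) that the
  generator deliberately does not model; consequently synthetic MAE is
  jitter-limited and smaller than field-reported MAE, and the
  proximal-target inaccuracy seen in such systems does not occur here. A
  slow in-plane drift term is available (default off).
* **Saccades** follow a minimum-jerk angular trajectory between
  target-directed directions (spherical interpolation), with duration
  minimized subject to a peak-velocity cap scaled linearly with amplitude
  from 350 °/s at 20° — so the default generator never trips the 350 °/s
  screen, while a misconfigured cap reliably does.
* **Sway** — low-amplitude sinusoidal origin motion (5 mm horizontal,
  2.5 mm vertical, ≤ 0.5 Hz, random phase), since head and body were not
  constrained; gaze re-aims at the target every sample, so fixations stay
  exact in the noise-free limit.
* **Dropout** is a stationary two-state Markov chain: gap-start hazard
  1/70 per sample and geometric run length (mean 10 samples) give a
  stationary missing fraction of exactly 12.5%, matching the observed
  ~12.5% missing data; starting from the stationary law keeps the expected
  fraction unbiased at finite trial length. The run-length distribution is
  an assumption (only the mean and SD of missingness are known).

Every recording carries ground truth (per-sample state, true intercept,
segment bounds, dropout runs), so the pipeline is always tested against
independent truth, never against itself.

## What the tests do and do not show

Passing tests demonstrate that the geometry is exact, that the metrics
match independent oracles, that segmentation recovers a known protocol
under realistic jitter and dropout, and that the treatment chain is null on
clean data (< 1 mm MAE change) while its gap-filling error grows
monotonically with gap size on smooth data. They do not certify behavior
under systematic tracker error, slippage, locomotion, or non-staircase
gaze protocols — none of which the generator emulates.

Problem sizes used by the test and acceptance runs: cohorts of 3–11
synthetic recordings of 750–1500 samples; the gap study uses 3 smooth
single-fixation recordings × 2 eyes × 25 gaps per size (150 comparisons
per condition; the full design scales to 11 × 2 × 50 = 1100). The
monotonicity check runs on smooth, saccade-free recordings because gaps
overlapping a saccade produce heavy-tailed bridging errors that swamp the
mean at any desk-scale sample size (the original analysis controlled such
outliers by winsorizing, which is out of scope here).

## Numerical notes

* Readers renormalize gaze vectors within 1e-3 of unit length and reject
  beyond, naming the offending sample; internal tracks enforce 1e-6.
* Units are meters internally; `units_scale` on read converts millimeter
  exports. An axis-order remap is available on read.
* `floor_span_for_angle` raises when the requested angle would push the
  span's near edge behind the observer (angle ≥ atan(2L/h)).
* The residual-autocorrelation criterion returns NaN for numerically-zero
  residuals; a fully degenerate (constant) series selects the grid minimum
  with a warning.
* Filtering requires finite series; in the treatment chain edge gaps are
  bridged by holding the nearest valid value, then re-masked.
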