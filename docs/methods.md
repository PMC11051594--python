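# Methods

This note documents the models, numerical choices and known limitations
of the package; the README covers the overall pipeline.

## Experimental design being analyzed

A controlled exposure experiment (CEE) is a 30-min trial in three 10-min
phases: pre-exposure, exposure, post-exposure.  During the exposure
phase of a sonar trial, up to 24 pings of 1.6 s are transmitted every
25 s (3.5–4 kHz mid-frequency active sonar); control trials broadcast
nothing but carry *pseudo-ping* timestamps at the same offsets so every
ping-aligned statistic is computed identically for both arms.  Whistles
are detected automatically from up to three drifting recording buoys;
only the buoy closest to the focal group each minute is used, and
minutes where even the closest buoy exceeds 1.6 km are excluded
(detection probability of a typical whistle falls off sharply past that
range).

## Geometry

Distances use the haversine formula on a sphere of radius 6,371,000 m
(configurable).  Tracks are interpolated linearly and independently in
latitude and longitude in degrees — no projection — which is accurate to
well under a metre at the sub-kilometre ranges involved.  A *minute* is
the half-open interval `[60k, 60(k+1))`, evaluated at its start time;
every second of an excluded minute is masked.  Ties between equidistant
buoys break to the lexicographically lowest platform id.

## Counting

A whistle detection contributes to the 1-s bin containing its *start*
time only, so per-second counts sum to the number of surviving
detections regardless of fragment durations.  Harmonic-annotation
removal drops a detection when its full half-open extent
`[start, start+duration)` overlaps an annotation interval on the same
buoy; touching endpoints do not overlap.  Medians and interquartile
ranges use the linear-interpolation percentile convention (numpy
default, R type 7).

## Changepoint analysis

The raw counts are smoothed with a centred 5-s moving average (window
shrinking symmetrically at the edges, masked bins excluded from their
neighbours' averages), then segmented greedily by binary segmentation:

* **mean change** — segment cost is the residual sum of squares around
  the segment mean, i.e. twice the negative Gaussian log-likelihood
  with unit common variance.  This is the convention of the classical
  Normal mean-change statistic; it makes the analysis scale-dependent
  and is intended for raw count-scale data.
* **variance change** — segment cost is `n log σ̂²` with the variance
  taken around the global series mean (common mean, segment-specific
  variance), floored at 1e-12 for degenerate segments.

The per-changepoint penalty defaults to `3 log n` (MBIC-style); the
maximum number of changepoints defaults to `n/10` so busy series are not
truncated; the minimum segment length is 1 for mean changes and 2 for
variance changes (a sample variance needs two points).  Masked seconds
split the series into independent runs — a changepoint is never placed
across a gap.  Changepoint indices are slice boundaries (the left
segment is `series[:i]`).

Because the smoothing induces strong short-range autocorrelation that
the Gaussian cost does not model, detection behaviour depends on the
count level: at the whistle rates observed in control conditions
(roughly 0.3–4.6 whistles/s) a simulated switching process at 1 switch
per minute is recovered at about 0.9 detected changepoints per minute,
while much louder series over-segment — the same behaviour, including
the tendency to report dozens of changepoints per 10-min period on
intense whistling, as the segmentation tool the analysis emulates.

## Ping-aligned response windows

By default the *before* window ends at ping onset and the *after* window
starts at the ping **end** (onset + 1.6 s), because whistle elevations
occur once the transmission has finished, with suppression during the
transmission itself; alignment to the onset is available.  A window may
never contain an adjacent ping's transmission.  With 25-s ping spacing,
windows longer than ~11.7 s necessarily share seconds with the
neighbouring cycle's windows; the 20-s analysis requires this reuse, so
it is permitted by default and refused under a strict option.  Window
means use whole-second bins intersecting the window, over unmasked bins
only; a fully masked window drops that ping's record with a log entry.
First-ping fold changes with a zero before-count are reported as
undefined, never as infinity.

## Models

All models are fit by direct maximum likelihood (BFGS with a
derivative-free polish; standard errors from the pseudo-inverse of the
numerical observed information, so one flat direction — e.g. a separated
zero-inflation slope — does not destroy the rest of the table).

* **Negative binomial (10-min scale).**  NB2 parameterization,
  `Var = μ + μ²/θ`, log link.  Non-integer `periodDiff` values are
  rounded half-to-even to counts before fitting (the pre-rounding
  values are untouched in the data).  An optional per-experiment random
  intercept is integrated out by adaptive Gauss–Hermite quadrature (25
  nodes, grid centred on each group's conditional mode and scaled by its
  curvature); doubling the node count changes the maximized
  log-likelihood by well under 1e-4.
* **Zero-inflated Gaussian (20-s scale).**  Each observation has
  likelihood `π·1{y=0} + (1−π)·N(y; μ, σ²)` with logit `π` linear in the
  zero-inflation covariates.  Note the zero term adds the Gaussian
  *density* at 0 to the point mass (the convention of the mixed-model
  software this layer mirrors): when `μ` is within a standard deviation
  or two of zero, the two components compete and the point-mass weight
  is not estimated near the simulation truth — parameter-recovery
  checks therefore live in the regime where `N(0; μ, σ²)` is
  negligible.  With no exact zeros in the data the mixture is
  unidentifiable and the fit falls back to ordinary least squares with
  a warning.
* **Zero-inflated Gaussian with AR(1) (5-s scale).**  The non-zero
  observations of an experiment are jointly Gaussian with correlation
  `φ^|Δt|` in ping order, evaluated in O(n) by the Markov
  factorization; exact zeros contribute their marginal mixture term
  (a point mass has no natural serial correlation).  `φ` is estimated
  on the atanh scale with a delta-method standard error, and a warning
  is raised at the boundary `|φ̂| > 0.99`.  Combining the AR(1)
  structure with a random intercept is not supported.

Model selection is backward elimination on the fixed terms: at each step
the term whose removal lowers AIC the most is dropped, stopping when no
removal lowers AIC; candidates that fail to converge are skipped with a
log entry.  The report table lists every candidate with its AIC
difference to the selected model, and likelihood-ratio χ² tests
accompany each accepted drop.  Wald p-values are two-sided.  Note that
AIC elimination retains an inert covariate with probability
≈ P(χ²₁ > 2) ≈ 0.16; selection-consistency checks are stated
accordingly.  Both pooled (df = n₁+n₂−2) and Welch t-tests are provided
for the changepoint-difference comparison.

## Synthetic experiments

The generator mirrors the structure the analysis assumes:

* **Vocal states** follow a continuous-time Markov chain with
  exponential holding times, discretized to 1-s bins; the switch count
  over a trial is exactly Poisson(rate × duration).  Defaults: mean
  states switch 1.0/min, variance states 1/3.5 per min.
* **Counts** are Poisson given the state (negative-binomial behind a
  switch, with optional per-state dispersions so variance switching at a
  constant mean can be simulated); state intensities default to the
  0.3–4.6 whistles/s control range.  Detection fragments get uniform
  start times within their second and gamma-distributed sub-second
  durations; every buoy records the same whistle train (fragment times
  drawn independently per buoy), as all recorders within range detect
  the group.
* **Ping responses** multiply the intensity by `response_fold` for
  `response_duration_s` (default 5 s) after the transmission ends, with
  the excess decaying exponentially afterwards.  The decay constant is
  `response_decay_s / 3` (default 10/3 s), so the excess is ~95% gone
  10 s after the flat window — "abating within ~10 s" is qualitative,
  and the constant is configurable.  With suppression on, every second
  overlapping the 1.6-s transmission is zeroed (including the second
  straddling the transmission end).  Affected seconds are re-drawn from
  the scaled intensity; everything else is untouched, and a fold of 1
  with suppression off leaves counts bit-identical.
* **Tracks** are smooth random walks (persistent heading, per-minute
  turns) fixed once per minute, group at 1.5 m/s and buoys at 0.25 m/s
  by default; a "crossing" scenario launches one buoy radially outward
  from 1.4 km at a speed exceeding the group's, guaranteeing a crossing
  of the 1.6-km threshold.
* Controls reuse the sonar ping schedule verbatim as pseudo-pings with
  nothing injected.  All randomness flows from the config seed through
  named substreams, so bundles serialize byte-identically.

What the generator does **not** emulate: detector error rates varying
with noise, whistle-fragment double counting, group-size–dependent call
rates, received-level gradients, or any coupling between movement and
vocal state.  Passing tests therefore demonstrate the pipeline's
correctness on data satisfying the model assumptions, not detector
robustness on field recordings.

## Problem sizes used in the test suite

Stochastic contracts are checked at sizes chosen to keep the suite
responsive while leaving Monte-Carlo error well below the tolerances:
10,000 replicates for the switching-process mean, 10,000 replicate pings
for the injection-profile integral, 50 seeded replicates for the
changepoint-rate recoveries and for each multi-scale pipeline property
(9 control + 9 sonar full-length experiments per replicate, chosen-model
fits), 200 replicates for the type-I-error rate of the NB Wald test, and
n = 40 experiments × 24 pings for the AR(1) mixture recovery.

## Known limitations

* The changepoint layer's unit-variance mean-cost makes changepoint
  counts scale-dependent; standardizing the series would change them.
* The zero-inflation density-at-zero convention (above) biases the
  mixture split when the Gaussian mean is near zero; this is inherited
  from the model definition, not a numerical artifact.
* Combined with strong AR(1) correlation — which weakens the
  identification of the global mean — the mixture likelihood can
  possess a second mode in which the point mass is emptied (π → 0) and
  the zeros are absorbed by the Gaussian density term, with the mean
  drifting toward the zeros.  In the ping-change application the zeros
  sit near the centre of the response distribution, where the
  likelihood is well behaved; recovery simulations far from that regime
  can land in the degenerate mode.
* The NB random-intercept model is weakly identified when every group
  contributes a single observation (as the 10-min response table does);
  it is provided because the full model specification calls for it, but
  the selected model in that layout is typically the fixed-effects one.
* Received levels are metadata only; no propagation modeling is done.
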