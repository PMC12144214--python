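# Methods

This note records the modelling and numerical choices behind `divestates`,
what the synthetic-data generator does and does not emulate, and the known
limitations of each stage.

## Dive detection and boundary interpolation

A dive is a maximal run of readings strictly deeper than the dive threshold
(default 3 m — the conventional cut-off separating surface behaviour from
diving in hard-shelled turtles, and the package default throughout). On
5-minute data the raw run boundaries quantise dive duration to multiples of
300 s, so boundary times are refined: between the bracketing surface reading
and the first (last) in-dive reading, depth is interpolated linearly on a
10 s grid anchored at the surface reading, and the start (end) is the
earliest (latest) grid time at which interpolated depth reaches the
threshold. Both conventions are ≥, so the boundary depth always lies within
one grid step's worth of slope above the threshold.

Dives whose interior spans an inter-reading gap larger than 1.5× the nominal
sampling interval are flagged `internal_gap` and excluded downstream: a
missing transmission inside a dive makes its metrics unreliable. The factor
1.5 (exposed as `DiveConfig.gap_factor`) distinguishes a genuinely missing
reading from ordinary timing jitter.

Phase labelling runs on the same 10 s grid: the bottom phase is the single
contiguous span between the first and last grid point strictly deeper than
80 % of the dive's maximum depth ("over 80 %" is read as strict; the effect
is at most one grid step). Grid points before the span are descent, after it
ascent, so the three phase durations always sum to the dive duration within
one grid step. Mid-dive excursions above the 80 % line remain part of the
bottom span by construction; the peak-splitting stage, not the phase
labeller, is responsible for deciding whether such an excursion is really
two dives.

## Zero-offset correction

Pressure sensors drift slowly, so "surface" readings wander away from 0 m.
The offset is estimated in three rolling passes over the depth series: a
centred 5th-percentile over 3 h windows, a running minimum over 12 h (4×
window), and a median smooth over 3 h; the estimate is subtracted and depths
clamped at ≥ 0. The middle lower-envelope pass matters: during bouts of long
resting dives (70-minute dives separated by 2–3 minute surface intervals, a
realistic resting pattern) a 3 h window can contain almost no surface
readings and a bare window-quantile overestimates the offset by metres. An
air-breather must surface within the wider envelope window, which anchors
the estimate to the true sensor zero while still tracking drift that is slow
relative to half a day — the regime of real sensor drift, which accumulates
over weeks. All three window lengths and the quantile are arguments of
`zero_offset_correct`.

Degenerate input (deployment shorter than one window) falls back to a single
global quantile offset, with a warning.

## Dive splitting

At 300 s sampling, two fast successive dives whose surfacing falls wholly
between samples merge into one record containing a *peak*: a reading (or a
run of equal readings — a plateau) shallower than both neighbours. Peaks
with prominence (min of adjacent depths minus peak depth) over 1 m are
candidates. The kinematic test computes the ascent rate into the peak and
descent rate out of it from the adjacent readings; if either rate would
cover the remaining depth to the 3 m threshold within one sampling interval,
an unobserved surfacing was possible and the record is split. The implied
threshold-crossing times (ascent-based preferred when both rates qualify)
become the first half's end and second half's start. Plateaus —
ascend–hold–descend patterns — split unconditionally, at the boundary
between the first two plateau readings; the speed test is still computed and
recorded on the decision object. A peak already at or above the threshold
indicates a mis-merged boundary and always splits.

Splitting never modifies recorded samples, only boundaries; each half is
re-labelled, the recursion re-examines the halves (capped at depth 4 per
original record to guarantee termination), and a half that would end up with
no readings abandons the split. In-dive time can only shrink, and the dive
count only grow; re-application is a no-op.

On trapezoidal renderings of realistic dive sequences (see below) the
split recall — the fraction of true > 10 m dives recovered one-to-one after
splitting a 300 s resampling — exceeds 0.9, which is the package's working
acceptance bar for this stage.

## Features and transform

Per dive: maximum depth (m), bottom time (s), dive time (s) and post-dive
surface interval (s, the gap to the next dive's start; the deployment's last
dive is dropped for lack of one). Exclusions, applied in priority order and
reported as counts: `internal_gap`, `first_day` (dives starting within 24 h
of deployment, a handling-effect guard) and `shallow` (maximum depth ≤ 10 m,
below which coarse sampling under-detects dives — the resolution-validation
stage is the empirical basis for this cut-off).

Surface interval, maximum depth and dive time are right-skewed and take a
natural log first (values floored at ε = 1 s so a zero-length interval
produced by splitting cannot blow up); bottom time is left on its raw scale
because zero is a meaningful and common value. All four are then min–max
scaled to [0, 1] with ranges pooled over the entire dataset — one transform,
one HMM, all individuals — and the fitted ranges are persisted
(`TransformSpec`, YAML) so held-out data transforms identically. Log-then-
scale order makes the scaled feature an affine image of the log feature, so
the [0, 1] guarantee applies to what the HMM actually sees.

## Hidden Markov model

Emissions are independent Gaussians per feature within a state (diagonal
covariance), the conventional choice for multivariate dive metrics; the
parameter count is (K−1) + K(K−1) + 2·K·4. Sequences are trips: chains do
not bridge deployment boundaries or track gaps over 7 days, since a Markov
dependence across a multi-day void is not meaningful. All sequences share
(π, Γ, μ, σ).

Fitting is Baum–Welch EM with scaled forward/backward recursions (per-step
normalisation plus a per-observation shift of the emission log-densities, so
likelihoods of long sequences cannot underflow); the inner recursions are
numba-compiled. Initialisation per restart: means drawn by k-means++-style
sampling of observations, a pooled per-feature standard deviation, and
Dirichlet(1) draws for π and the rows of Γ. Convergence is a relative
log-likelihood change below 1e-6, capped at 500 iterations; emission scales
are floored at 1e-4 and flagged if the floor binds; a non-finite likelihood
marks the restart non-converged. Restart r of a selection run uses seed
`base_seed + r`, so any individual fit can be reproduced in isolation. For
each state count in 2–5 the lowest-AIC converged restart is retained; the
AIC table is reported, and the final choice among state counts is left to
the user (statistical criteria alone tend to over-split behavioural states;
biological interpretability is the intended tie-breaker).

Decoding provides Viterbi paths (first-index tie-break on exact ties) and
forward–backward posteriors. Canonical labelling is pure post-processing on
raw-scale decoded means: State 1 = largest mean bottom time, State 2 =
deepest, State 4 = shallowest, State 3 = the remainder; if two criteria pick
the same state the fallback orders by depth (deepest = 2, shallowest = 4,
longer-bottom middle state = 1) and the summary flags that the fallback was
used. Label permutations leave the likelihood and AIC unchanged.

## Resolution validation

`compare_resolutions` point-resamples a 1 s series at 300 s, detects dives
at both resolutions (detection only — splitting is not applied in this
comparison, so the test isolates what coarse sampling alone loses), pools
maximum depths > 10 m into half-open 10 m bins, and applies Fisher's exact
test to the 2×K table. The two-sided p uses the probability-ordering rule
(total null probability of tables no more probable than the observed one):
2×2 tables sum the hypergeometric support; 2×K tables are fully enumerated
when the total is ≤ 200 and the composition count is manageable (≤ 2e6),
otherwise a Monte-Carlo estimate conditional on both margins is returned
with its standard error and seed. Point sampling can only miss threshold
crossings, so the low-resolution count is never larger — the interesting
question the test answers is whether the *surviving* dives are depth-biased.

## Seasonality

Monthly counts of dives in a focal state (one model per state, focal versus
all others) per individual are modelled as binomial with a logit link on a
cyclic cubic regression spline of month. The basis uses 6 knots equally
spaced on [1, 13] with the last wrapping onto the first (5 free columns,
built from the periodic natural-spline interpolation system), so the fitted
curve and its first two derivatives are periodic across the December–January
boundary and constants are represented exactly. Individuals enter as fixed
intercept offsets against a reference individual — a deliberate
simplification of random intercepts that keeps the model an ordinary GLM;
with tens of individuals each observed over many months the fixed- and
random-intercept population curves are close, and the package's acceptance
surface for this stage is seasonal-shape recovery (a simulated sinusoidal
occupancy peak is located within ±1 month; flat occupancy yields a curve
with range < 0.05), not variance-component estimation. No autoregressive
residual term is fitted. Complete separation or non-convergence falls back
to a lightly ridge-penalised fit (α = 1e-6), flagged on the result.

Exact rotation equivariance (same deviance, rotated curve) holds for month
rotations that are multiples of the knot spacing (12/5 months); integer-month
rotations perturb the deviance slightly because the knots stay fixed.

The move-persistence association replaces Tukey contrasts on a GLM with
pairwise two-proportion z-tests under a Holm adjustment — conservative,
assumption-light and dependency-free; states with fewer than 2 dives are
excluded and flagged.

## The synthetic generator

The generator is the package's test bed and defines the conditions under
which the pipeline's guarantees are stated. It emulates: a first-order
4-state Markov chain over dives; per-state lognormal distributions (log-scale
separation between states) of maximum depth, bottom-time fraction, dive time
and surface interval; rendering to continuous traces with trapezoidal
geometry (linear descent, hold, linear ascent — the hold sized so time spent
deeper than 80 % of maximum depth equals the drawn bottom time, degrading to
a vee when that is impossible); linear sensor drift; point resampling (the
tag reports instantaneous depth per slot; on-board dynamic-range compression
is deliberately not emulated); optional monthly modulation of state
occupancy (cosine reweighting of transition columns, off by default so the
base chain is exactly homogeneous); and Argos tracks as correlated-heading
random walks salted with labelled near-duplicates, class-Z fixes and speed
spikes.

The default configuration mirrors the qualitative state structure of
loggerhead dive modes: State 1 intermediate depth (~30 m), the longest
bottom and dive times (~4,200 s), short surface intervals; State 2 deepest
(~90 m) with long surface intervals; State 3 intermediate depth, least
bottom time, shortest dives, longest surface intervals; State 4 shallowest
(~16 m) with the shortest surface intervals. Its transition matrix is
strongly diagonal and the initial distribution favours State 3.

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about field data: dynamic-range-dependent depth
quantisation, non-trapezoidal dive shapes (wiggles, skews, S-profiles),
depth-dependent sensor noise, Argos error ellipses, tag fouling, or
behavioural processes beyond a first-order chain. Parameter-recovery results
in particular inherit the generator's assumption that emissions really are
independent lognormals within state.

## Problem sizes and numerics

The package's own verification runs use: a 30-day, 1 s deployment
(~2.6 M samples, ~750 dives) for the reconstruction round trip; 5,000
simulated dives and 20 EM restarts for parameter recovery (transition
entries and transformed emission means recovered within ±0.05); 200 random
small instances (T ≤ 6, ≤ 3 states) for exhaustive-enumeration checks of the
forward likelihood and Viterbi path at 1e-8; 100,000 Monte-Carlo tables for
Fisher agreement within 3 standard errors; and 20 individuals × 12 months ×
100 dives for seasonal-shape recovery. These sizes give stable results
across seeds while keeping a full verification run to a few minutes on one
CPU.
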