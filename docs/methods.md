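# Methods

`dyadmove` is a simulation-and-inference framework for a specific question
in movement ecology: when two animals' trajectories are correlated, can the
standard dyadic-interaction methods tell *social* interaction apart from a
shared response to the *physical* landscape?  The package simulates pairs
of individuals under controlled scenarios in which the truth is known, runs
three inference methods on the resulting tracks, and measures their false-
and true-positive rates.

## The agent-based movement model

Two individuals move in discrete time inside a square arena with
reflecting borders.  Movement is a biased correlated random walk: at each
time step an individual draws `n_candidates` candidate steps, with turning
angles from a von Mises distribution centred on the current heading
(concentration `kappa = 4`, strong directional persistence) and step
lengths from a gamma distribution (`shape = 6`, `scale = 0.15`, so the mean
step is 0.9 length units).  One candidate is then selected according to the
active scenario:

* **A.a** — habitat quality rises linearly west to east; the two
  individuals start side by side near the west edge and climb the gradient
  in parallel.
* **A.b** — habitat quality rises from the borders towards the centre; the
  individuals start at opposite border midpoints and converge on the
  centre.
* **B** — a patchy landscape generated by octave-summed Perlin gradient
  noise; both individuals start at a shared random location and climb to
  nearby habitat peaks.
* **C** — a homogeneous matrix with a fraction of cells converted to
  impassable barriers (the highest-valued cells of a Perlin field); no
  habitat preference, but candidates landing in barrier cells are
  discarded (with a bounded redraw budget, then the individual waits one
  step).
* **D** — no landscape effect; each individual weights candidates by
  `exp(-beta_soc * distance to the partner)`, producing a bonded pair.

Habitat selection in A/B uses weight `exp(beta_env * habitat)` with the
default `beta_env = inf`, i.e. the candidate in the best cell within the
perceptual range is always taken (random tie-break).  In scenarios A–C the
two individuals never sense each other; any correlation between their
tracks is environmentally induced.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| arena size | 100 x 100 length units | cells of size 1 make landscape features commensurate with the 0.9-unit step, so habitat selection acts at every step |
| grid | 100 x 100 cells | as above |
| `n_steps` | 1000 | a realistic high-resolution telemetry deployment; also the length at which the DI permutation test reaches full power on scenario-D pairs (see calibration below) |
| `n_candidates` | 10 | enough candidates that the argmax bias is strong without being a line search |
| `perceptual_range` | 5 | a few step lengths |
| `beta_soc` | 10 | calibrated so that all three methods detect the scenario-D interaction in essentially every replicate, the regime the study design requires ("power ~ 1"); the attraction is strong enough that the pair stays within ~1–2 units |
| Perlin noise | 4 octaves, base frequency 4/width, persistence 0.5 | patches of roughly 1/8 arena width |
| barrier threshold | exact empirical quantile | any requested barrier fraction is realised to within one cell; ties broken by cell index |

The scenario-D calibration deserves a note: a mutually attracted pair in
this model becomes a tightly bonded unit that wanders slowly; its heading
cohesion (what DI measures) saturates around `di_theta ~ 0.2` regardless of
attraction strength.  Detection power therefore comes from track length,
not from `beta_soc` alone; 1000-step tracks with `beta_soc = 10` give DI
power 1.00 across independent replicate batches, while 500-step tracks cap
near 0.9.

Each individual consumes its own random stream split from the master seed,
so simulations are bit-reproducible and perturbing one individual's
parameters does not alter the other's draws.

## Dynamic interaction index

For simultaneous steps with headings `theta_1t, theta_2t` and lengths
`d_1t, d_2t`,

    g_t = cos(theta_1t - theta_2t)
    f_t = 1 - (|d_1t - d_2t| / (d_1t + d_2t)) ** delta      (f_t = 1 if both lengths are 0)
    DI  = mean_t ( g_t * f_t ),

with `delta = 1` by default; `di_theta` and `di_d` are the means of the
two factors.  DI lies in [-1, 1]: cohesive movement is positive, opposing
movement negative, independent movement near zero.

Significance comes from a permutation test: the second track's step series
(headings and lengths) is circularly time-shifted, preserving each track's
autocorrelation while destroying cross-track simultaneity.  Two details
matter:

* shifts smaller than the tracks' correlation time barely decouple the
  pair, so shifts below `n/20` steps are excluded from the null;
* the test is one-sided toward cohesion by default (`alternative =
  "greater"`), matching the attraction/avoidance split reported by the
  reference implementation of this test; the two-sided variant is
  available.

The p-value uses the add-one rule `(1 + exceedances) / (1 + n_perm)` with
999 permutations by default.

## Step-selection functions

Each observed step of the focal individual is compared with 20 available
steps sharing its start point, drawn from the ML-fitted gamma step-length
and von Mises turning-angle distributions of the observed track (the first
observed step is dropped; its turning angle is undefined).  Available
endpoints are reflected into the arena so covariates are defined
everywhere.  Candidate endpoints carry up to three covariates:

* `landscape` — habitat value of the containing cell;
* `dist` — Euclidean distance from the endpoint to the partner's fix at
  the step's *target* time, negated by default so a positive coefficient
  means attraction;
* `od` — the partner's occurrence distribution evaluated at the endpoint.

The occurrence distribution is a Gaussian kernel density over the
partner's fixes.  Its default bandwidth is the partner's **mean step
length** ("movement" bandwidth): an occurrence distribution derived from a
movement model is smooth at the scale of the movement between fixes, not
at the scale of the whole home range.  (Silverman's rule with an
autocorrelation-adjusted effective sample size is available as an option;
applied to strongly autocorrelated fixes the movement bandwidth both
calibrates the null SSF-OD test, 6% rejections on independent pairs, and
preserves scenario-D power.)  The covariate uses the smooth KDE evaluated
exactly at candidate endpoints — a raster-staircase lookup would inject
cell-scale artefacts into the selection model.

Selection coefficients are estimated by conditional logistic regression
(one used among 21 candidates per stratum), maximising

    prod_strata  exp(b'x_used) / sum_candidates exp(b'x_j)

by Newton iteration with step-halving (relative log-likelihood tolerance
1e-9, at most 100 iterations), Wald standard errors from the observed
information, and two-sided normal p-values.  Covariates are z-scored
across all candidates before fitting by default.  A covariate with no
within-stratum variation raises a dedicated error.  An optional
bending-energy penalty supports penalised smooth terms inside the model,
and an optional block-sandwich covariance is available for serially
correlated data.

### Model structures

* **Full** — interaction covariate (od or dist) plus `landscape`.
* **Individual** — interaction covariate only (no environmental data
  available).
* **Spatial+** — the Individual model after the Spatial+ correction.

## Spatial+

Spatial confounding: the interaction covariate is itself a smooth function
of space, so its effect cannot be separated from unmeasured spatial
drivers.  The correction has two stages:

1. the covariate is regressed on a penalised thin-plate regression spline
   of the candidate coordinates — radial basis `r^2 log r` at 100 knots
   (k-means centroids of the candidate cloud) plus unpenalised
   `{1, x, y}`, the knot-polynomial constraint absorbed by a null-space
   reparameterisation, the smoothing weight chosen by GCV;
2. the SSF is fitted with the stage-1 residuals as the corrected
   interaction covariate **plus a free thin-plate smooth of the
   coordinates re-estimated inside the conditional likelihood** (same
   basis, bending-energy penalty, weight chosen by conditional AIC).

The residual coefficient is the corrected interaction estimate.  The
outcome-model smooth matters: with it, the spurious scenario-B DIST effect
(z ~ 8 uncorrected) collapses to zero, whereas pairing the residual with
the fixed stage-1 fitted values (a single covariate) leaves the spurious
effect intact.  Unpenalised, the 100-column smooth overfits the
conditional likelihood and inflates the residual's Wald statistic; the
penalty restores null calibration.

The stage-1 GAM is fitted over *all* candidate endpoints (used and
available pooled) because the conditional likelihood needs corrected
covariate values at every candidate.

## Evaluation harness

A replicate is *correct* when the interaction estimate is non-significant
(alpha = 0.05) in scenarios A.a/A.b/B/C (true negative) and significant
with attraction sign in scenario D (true positive).  Per scenario the
harness runs `n_reps = 20` replicates; exclusion rules mirror the study
design: scenario C fits no Full model (no environmental covariate is
extracted); the Full model drops the interaction covariate when its
correlation with `landscape` at used steps exceeds 0.7 in magnitude
(refitting landscape-only); SSF-OD models are skipped when the partner's
occurrence density is numerically zero at more than 99% of candidates (no
overlapping space use).

The scenario-C sweep runs one simulation per barrier proportion 0 to 0.50
in steps of 0.005 plus 20 repetitions at 0.70 (121 runs), fits the
Individual and Spatial+ structures for both SSFs, and regresses the binary
outcome (1 = non-significant interaction, i.e. correct) on the barrier
proportion with a logistic model.  With this coding a rising
false-positive rate gives a negative slope on the printed scale.  Complete
separation is flagged and the slope reported from a ridge-penalised
fallback.

## What the generator does and does not emulate

The synthetic tracks are regular, error-free fixes of exactly two
individuals with stationary movement parameters.  Real telemetry adds
location error, irregular sampling, behavioural state switching, and more
than one potential partner — none of which are modelled, so passing tests
here demonstrate correctness of the methods under the idealised data-
generating process, not robustness to field data.  Landscapes are static
rasters; resources do not deplete and barriers do not move.

## Numerical choices

* Half-open raster cells with a lower-left origin; nearest-cell lookup for
  habitat (trajectories live in continuous space, rasters are piecewise
  constant).
* Barrier threshold as an exact empirical quantile with index-order tie
  breaks.
* Conditional-logit Newton falls back to least-squares steps on singular
  information; covariance by explicit inversion with non-negativity
  clipping.
* Thin-plate penalty eigen-clipped to positive semi-definite (roundoff
  guard); coordinates rescaled to the unit box before basis construction;
  a 1e-9-scaled ridge on the radial block only (exact polynomial surfaces
  stay exact).
* Degenerate inputs raise typed errors: all-equal step lengths or mean
  resultant length at 1 (distribution fitting), constant-within-stratum
  covariates (conditional logit), zero-variance fixes (occurrence
  distribution), misaligned time grids (DI).

## Known limitations

* **Spatial+ with the occurrence-distribution covariate is
  anti-conservative on revisit-heavy tracks.**  After residualisation the
  OD covariate's only remaining content is sub-smoother-scale spatial
  structure.  Selection that tracks the landscape at fine scales (argmax
  habitat choice, barrier avoidance) correlates with exactly that
  structure, and because a track revisits the same places, the
  within-stratum contrasts are serially correlated at all lags — the Wald
  test then over-rejects (roughly a third of independent-pair nulls; and
  at extreme barrier fractions the corrected SSF-OD still flags spurious
  interactions, so the scenario-C Spatial+ slope for SSF-OD remains
  negative rather than null).  The same fine-scale channel is what gives
  Spatial+-OD its scenario-D power, so no estimability guard can separate
  them.  The DIST covariate does not suffer from this (it is smooth at
  step scale) and its Spatial+ correction behaves as designed.
* In this package's geometry the scenario-A.b individuals eventually meet
  at the central resource, so their paths overlap late in the track and
  the SSF-OD overlap rule does not exclude A.b (the reference study's
  tracks apparently ended before meeting).
* The scenario-A.a/B false-positive mechanisms include a temporal
  (co-drift) component that no spatial correction can remove; the
  Spatial+ repair demonstrated here is of the spatially structured part.
* The occurrence distribution is a fixed-bandwidth KDE, not a
  Brownian-bridge estimator; "dynamic" sliding-window ODs are not
  implemented (whole-track OD only).

## Problem sizes used by the test-suite

Monte-Carlo sizes in `tests/` are chosen for a fast, deterministic suite:
the barrier sweep runs the 0.01-step grid with 10 extreme repetitions (61
runs; the full 0.005-step design with 20 extreme repetitions is what
`scripts/acceptance.py` executes), null calibration uses 200 independent
pairs of 500 steps with 199 permutations, and power/repair checks use 20
replicates at full track length.
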