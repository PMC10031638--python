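# Methods

This note documents the statistical models, estimation choices, default
settings and known limitations of `eventdep`.

## Response model

Test trials are binary items under a three-parameter logistic model with
all discriminations fixed to 1 and a common guessing floor:

    P(u_ij = 1 | θ_i) = γ + (1 − γ) σ(θ_i − β_j),    σ(x) = 1/(1+e^{−x}).

Fixing the discriminations is justified by the random composition of the
event triplets; fixing γ to the reciprocal of the number of response
alternatives (default 1/6) encodes blind guessing in the forced-choice
format.  The latent trait is Normal(0, σ²) with the mean pinned at 0 for
identification and the variance free.

**Estimation.**  Marginal maximum likelihood.  The trait is written as
θ = s·z with z standard normal and integrated on a fixed Gauss–Hermite
grid (default 61 nodes), so the discretised likelihood is an ordinary
finite mixture and the EM ascent is exactly monotone — the fitter records
the per-iteration marginal log-likelihood and the tests assert
non-decrease.  The M-step takes damped Fisher-scoring steps for each β_j
and for the scale s, halving any step that fails to improve the expected
complete-data log-likelihood (a generalised EM).  Convergence is declared
when successive marginal log-likelihoods differ by less than `tol`
(default 1e-5).  Difficulties are clipped to |β| ≤ 8 to keep
near-degenerate items finite; an item whose observed responses are
constant raises an error naming it, because its difficulty is not
estimable.  Missing responses drop out of the likelihood
(missing-at-random), which is what the judgement-subset and
presentation-order analyses rely on.  Person scores are EAP means on the
quadrature grid; they feed the residual analysis and tolerate arbitrary
missingness.  The likelihood was cross-checked against brute-force
adaptive quadrature on a two-person toy (agreement to 1e-6).

## Residual dependency

Residuals are u_ij − P̂(u_ij = 1 | θ̂_i) at the EAP scores.  Q3 for an
item pair is the Pearson correlation of the two items' residuals across
the persons observing both; its expectation under local independence is
−1/(I−1), with I the number of items in the fit, and the bias correction
adds that amount to every entry.  The dependency index is

    D = (1/K) Σ_within Q3* − (1/L) Σ_between Q3*

over within-event (K) and between-event (L) unordered pairs, optionally
restricted to the pairs whose two items share one loop condition
(between-event pairs then also come from that condition only, matching
per-condition reporting).

**Missingness rules.**  Correlations are pairwise-complete with a
minimum of 10 jointly observed persons per pair (configurable); pairs
below the threshold, or with a degenerate residual vector, are undefined
and drop out of both means with K and L adjusted.  When a subset
analysis silences whole items they are removed from the refit, and the
bias correction uses the reduced item count — the correction derives
from the fitted model, so I follows the fit.  (Reusing the full-design
I is available via the `n_items_bias` argument for comparison.)

**Judgement subsets.**  D for a remember/know/no-recognition subset is
computed by declaring non-matching responses missing and *refitting* the
model on the subset before the residual analysis.  The refit reading is
consistent with the presentation-order analysis, which explicitly fits
separate models to the two order cases.

## Bifactor model

Each person carries a general trait plus one specific trait per event,
all independent, loadings fixed at 1:

    η_ij = θ_i + τ_{i,e(j)} − β_j,   θ ~ N(0, v_g),   τ_e ~ N(0, v_{c(e)}).

Specific-trait variances are constrained equal across the events of one
condition (events are randomly generated, hence exchangeable), and those
per-condition variances are the model's measure of within-event
dependency.  The variance-only parameterisation is the minimal one that
the power analysis manipulates ("differences in event-specific trait
variances"); free loadings, cross-loadings and correlated specific
traits are out of scope.

**Estimation.**  Conditional on the general trait the events are
independent, so the marginal likelihood collapses to a 1-D outer
quadrature (general trait, default 31 nodes) times per-event 1-D inner
quadratures (specific traits, default 21 nodes).  EM again parameterises
the trait *scales* on fixed grids; the M-step does damped scoring for
β, the general scale, and each condition's event scale.  Event scales
are floored just above 0 (at exactly 0 the score vanishes identically);
estimates at the floor are reported as variance 0 with a boundary flag.
A condition with fewer than two events triggers a weak-identification
warning.  Setting all event variances to 0 reproduces the unidimensional
log-likelihood to numerical precision (tested), and the bifactor
log-likelihood dominates the nested unidimensional fit.

## Bootstrap inference

All p values are add-one proportions, p = (1 + #{null ≥ obs})/(1 + B),
never exactly zero; two-tailed p is 2·min(lower, upper) capped at 1
(the standard symmetric rule).  The default B is 1000; at least 1000
samples are recommended to keep the Monte-Carlo error of p small, and
every routine exposes B for scaled-down runs.

* **Null of local independence** (two-tailed): B datasets from the
  unidimensional fit (difficulties from the data, trait drawn at the
  estimated variance); D recomputed per dataset with a full refit.
* **Condition differences** (one-tailed): B datasets per focal condition
  from the bifactor fit with *every* event variance set to the focal
  condition's estimate; the null statistic is Ddiff = D(a) − D(b).
  Each condition of the pair serves as focal; the headline p is the
  maximum of the two focal p values (the conservative combination; the
  per-focal results are also returned).  A contrast in which both
  observed D are negative is returned as *not tested*.
* **Judgement subsets**: bootstrap datasets receive independent
  multinomial R/K/N labels at the empirical proportions before
  subsetting and refitting.
* **Presentation order**: D is conditioned on whether an association
  involving the animate element was studied first by declaring
  non-matching events' responses missing and refitting; the bootstrap
  re-applies the masking event-wise at the per-condition observed
  proportion.  Conditions in which every *presented* association
  involves the animate element are excluded (order regarding animacy is
  undefined there).

Bootstrap replicates that produce a degenerate dataset (a zero-variance
item) are redrawn up to three times and otherwise dropped; more than 5%
failures aborts the test.  Holm's step-down adjustment (via statsmodels)
handles multiple contrasts.

Complete-data bootstrap replicates are refit by a vectorised EM that
processes the whole replicate stack with batched linear algebra; it has
the same fixed point as the reference fitter (tested to ~5e-3 in the
parameters) and exists purely for speed.  Bootstrap refits use a coarser
grid (default 15–21 nodes) and a looser tolerance (1e-3); D was checked
to be insensitive to these settings at the 1e-5 level.

## Synthetic experiments

The generator reproduces the statistical skeleton of the three designs:

* events are element triplets (animal–object–location, or
  transport–tool–location for non-animacy conditions) randomly assigned
  to loop conditions (closed loop; three open loops, each excluding one
  association, whose trial is the inference trial);
* per event one of the two cue→target rotation cycles is chosen at
  random, the three items land in the three test blocks in random
  order, and events containing an animate element get a random
  animate-first flag;
* responses come from the bifactor model; remember/know/no-recognition
  labels are independent multinomial draws when proportions are given.

Presets cover the three experiments: 4 conditions × 15 events (n = 180);
2 × 4 conditions × 8 events (n = 210); and the two between-subjects
groups of the 2 × 4 mixed design at 15 events (n = 130 per group).
Generating difficulties default to Uniform(−1, 1) and the general trait
variance to 1 — unremarkable mid-range values for a memory test with a
guessing floor; the pilot-calibrated difficulties behind the original
sample-size planning are not public, so reproduced power values are
approximate by construction.  Presentation-level details with no
footprint in the response model (primacy buffers, filler phase, trial
spacing, word stimuli) are deliberately not modelled: the generator
emulates the response-generating process, not the stimulus stream.  In
particular, passing tests say nothing about serial-position effects,
item-content effects, or non-normal trait distributions in real data.

**Power analysis.**  Each replicate draws a fresh design and fresh
difficulties, simulates a study at the requested per-condition event
variances, runs the difference test on the focal contrast, and scores a
rejection at α (one-tailed by construction of the test); not-tested
replicates count as non-rejections.  The estimate comes with a
Clopper–Pearson 95% interval.

## Default problem sizes

Full-fidelity analyses (B = 1000; 61/31×21 quadrature nodes) are what
the CLI defaults to for single datasets.  The test suite and
`scripts/acceptance.py` use desk-scale settings chosen so the whole
suite runs on one core in well under half an hour: power at 12–14 outer
replicates with B = 99, calibration at 150 replicates with B = 99, and
coarser bootstrap grids as above.  At these sizes the binomial
uncertainty of a power estimate is roughly ±0.25, which the acceptance
checks account for explicitly; cluster-scale runs (1000 × 1000) use the
same code paths with larger arguments.

## Known limitations

* Only pairwise condition contrasts are supported; the bootstrap has no
  omnibus test.
* Floor or ceiling performance makes D unreliable (as it does for any
  dependency measure), and constant items cannot be fit at all.
* D is robust to, but not immune from, model misspecification: both
  within- and between-event correlations shift together, and small
  shifts in D and p remain possible.
* p values inherit Monte-Carlo error of order 1/√B.
* The bifactor fitter estimates variances only; if real data demanded
  free loadings the model would need extending.
* EM convergence for near-zero event variances is slow (fraction of
  missing information close to 1); the fitter reports `converged=False`
  with usable partial estimates when the iteration cap bites first.
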