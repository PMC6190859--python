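# Methods

This note documents the models, algorithms, default parameters and numerical
choices behind `sinktrace`, and what the synthetic benchmark does and does not
establish.

## The source-tracking model

A sink community of N reads over T OTUs is modelled as a mixture of V known
source environments plus one Unknown source. Each read i carries a latent
source label z_i sampled by collapsed Gibbs:

    P(z_i = v | z_-i) ∝ (n_v^(-i) + β) · P(x_i | v)

* Known sources have fixed OTU distributions estimated from pooled training
  counts m_v with additive smoothing:
  P(t | v) = (m_vt + α₁) / (m_v· + α₁T).
* The Unknown source re-estimates its OTU distribution every step from the
  reads currently assigned to it:
  P(t | Unknown) = (u_t^(-i) + α₂N) / (u_·^(-i) + α₂NT).
* n_v counts current assignments to source v; the symmetric Dirichlet(β)
  prior on mixing proportions enters through the n_v + β term.

Defaults are the reference-implementation defaults: α₁ = 0.001, α₂ = 0.1,
β = 10, ten restarts with one retained draw each, 100 burn-in sweeps,
thinning 1. Training samples are rarefied to 10,000 reads; sinks are left
unrarefied so that low-abundance OTUs of possible fecal origin stay visible.
Each sink read is initialized at a uniformly random source and one sweep
visits reads in fixed index order; per-sink seeds derive from the run seed,
making runs bit-reproducible. The per-read inner loop is JIT-compiled with
numba.

Estimates: the mixing proportion of source v is the mean of n_v/N over
retained draws (sd across draws is reported alongside). The per-OTU source
posterior averages, over retained draws, the fraction of an OTU's reads
assigned to each source, then normalizes each observed OTU's row to one per
sink; OTUs without sink reads are excluded rather than NaN-filled.

The sampler's stationary distribution admits exhaustive enumeration on tiny
instances (≤6 reads, ≤3 sources); the test suite checks agreement of
posterior means and per-read marginals with that oracle to 0.02. One model
subtlety the tests acknowledge: a sink composed entirely of one OTU private
to source A is *not* forced to A when the Unknown source is enabled — a novel
single-OTU cluster is a legitimate Unknown explanation — so the degenerate
limit is asserted with the Unknown disabled.

## Library construction

Three background strategies share identical fecal/sewage sources and differ
only in the background source:

* **WB** — no background water source.
* **LB** — water sampled at the sink's own location, filtered by the FIB rule
  (E. coli < 25 MPN/100 ml and coliforms < 100 MPN/100 ml, strict
  inequalities; missing FIB values exclude the sample with a warning) and by
  a preliminary source-tracking screen retaining candidates with ≥ 0.99
  estimated non-fecal (background + Unknown) assignment probability.
* **DM** — background chosen by Dirichlet-multinomial mixture (DMM)
  clustering of the screened candidate pool together with the sink; between
  2 and 8 components are fitted, ranked by the Laplace model-selection score,
  and the ranking is walked until the sink's component contains 10–25 water
  communities, which become the background. If no fit qualifies, the
  selection falls back to the n_max candidates nearest the sink by
  responsibility similarity and is flagged in provenance.

The preliminary screen runs each candidate against the fecal sources *plus a
provisional background source formed by the remaining candidates*
(leave-one-out). With heavy water–fecal OTU overlap, a fecal-only screen
would push shared water reads into fecal sources and no candidate could reach
0.99 non-fecal probability; competing against a genuine water source restores
the intended semantics of the rule.

Library invariants are enforced at construction and fail loudly: 10–25
samples per source and > 15,000 reads per sample. Oversized sources are
trimmed deterministically by dropping the newest samples from the
most-represented location first (ties broken by reverse-sorted id).

### DMM fitting and the Laplace score

The k-component DMM is fitted by EM. The E-step computes responsibilities
from component Dirichlet-multinomial likelihoods (multinomial coefficient
omitted — it cancels everywhere) and mixture weights. The M-step maximizes
each component's weighted DM log-likelihood over log-Dirichlet parameters by
L-BFGS-B with analytic gradients, warm-started across iterations and
initialized by moment matching; an M-step result is kept only if it does not
decrease the objective, so the observed-data log-likelihood trace is
non-decreasing. Initial responsibilities come from k-means on square-root
relative abundances. Convergence: relative log-likelihood change < 1e-6, cap
100 iterations (non-convergence warns and returns the best iterate).

The Laplace score approximates the negative log model evidence at the fitted
mode under a flat prior on the Dirichlet parameters:

    score = −logL − (d/2)·log 2π + ½·log|H|,    lower is better,

with d = k·T + (k−1) and H the negative Hessian in (per-component Dirichlet
parameters, free mixture weights). Both blocks are diagonal-plus-rank-one, so
log-determinants are exact via the matrix determinant lemma. Working in
α-space (not log-α) matters: components that zero out an OTU have very large
curvature there, which penalizes extra components instead of rewarding flat
directions. Near-singular directions are floored at 1e-12 and the fit
flagged. On planted 2- and 3-component mixtures the score's minimum sits at
the true k (10/10 seeds in the acceptance suite).

## Signal scoring

For a fitted sink and source, the attributed OTU count n_otus counts OTUs
with posterior > 0.1 toward that source (the visualization floor, which also
matches the worked accuracy examples), and n_accurate counts OTUs at ≥ 0.7
("source-accurate" OTUs; the ≥ convention follows the accuracy-counting text
and both thresholds are configurable). accuracy = n_accurate / n_otus,
undefined when nothing is attributed. Contamination calls require a source
proportion > 0.3% excluding the background source, with the Unknown source
included on request; total contamination sums non-background proportions, so
with Unknown included it is exactly one minus the background share.

Read-reassignment accounting between two runs of the same sink assigns each
read the argmax source of its OTU's posterior in each run and cross-tabulates
(source_a, source_b, phylum) read counts; OTUs with tied argmax in either run
are dropped, as no single origin can be assigned.

## Hierarchical Bayesian models

**Model 1 (multivariate GLMM).** Six responses per sink: the three
log-transformed total contaminations (identity link, Gaussian) and three FIB
counts (log link, Poisson). g(m_ij) = β_jk + u_ij with β_jk = β_j + u_jk and
u_i ~ MVN(0, Σ); the correlation matrix of Σ is the estimand of interest and
also absorbs overdispersion on the count side (the stated Poisson-with-
correlated-residual choice; a negative-binomial observation model was
considered and rejected as redundant given the observation-level residual).
Data preparation drops the later of any same-location pair sampled < 48 h
apart, floors FIB < 1 to zero, and floors zero contaminations at half the
smallest nonzero value of their response before the log (configurable to
drop zeros instead).

**Model 2 (source accuracy).** Per signal l, n_accurate is Poisson with log
link and offset log(n_otus): g(m_l) = a_l + β_ik + β_lm + β₁x₁l + β₂x₂l,
with nested sample-within-location random effects β_ik = β_k + u_ik,
β_k = β₀ + u_k. x₁/x₂ mark DM/LB libraries against the WB baseline;
exp(β₁), exp(β₂) are accuracy rate ratios. Signals below 0.3% proportion or
with zero attributed OTUs are excluded.

**Priors** (both models): half-Cauchy(0, 5) on all standard deviations
(positive truncation of the stated Cauchy, the standard reading for scale
parameters), Normal(0, variance 10) on coefficients, LKJ(η = 1) on the
correlation matrix. Default schedule: 8 chains × 1,000 iterations with the
first 500 discarded. Split-R̂ and ESS are computed for every tracked
parameter (via arviz); a fit with max R̂ > 1.05 is flagged, never silently
accepted.

**Sampler.** Metropolis-within-Gibbs, chosen because no gradient-based PPL
is part of this package's dependency set and the models are small:

* Gaussian-response location coefficients and all global coefficients have
  exact Gaussian conditionals.
* Count-response coefficients and the latent count residuals use adaptive
  random-walk MH (Robbins-Monro step adaptation during burn-in only, so the
  retained chain is a fixed kernel); the latent update is vectorized across
  samples with three inner repetitions.
* Σ: for n ≥ 2p+3 an independence MH step proposes from
  inverse-Wishart(n−p−1, UᵀU), which matches the Gaussian likelihood of the
  residual matrix exactly, so acceptance depends only on the prior ratio and
  mixing is near-ideal. For smaller n no inverse-Wishart proposal can
  dominate the prior-dominated target (importance weights are unbounded), so
  an adaptive random walk on the Cholesky factor (log-diagonal, with the
  exact Jacobian) is used instead; these tiny-n fits mix more slowly and are
  routinely flagged by R̂ — the flag is the intended behaviour.
* Funnel-breaking moves: exact recentering Gibbs steps along every
  likelihood-invariant translation ridge (intercepts vs random effects,
  count coefficients vs their latent residuals) and a non-centered
  interweaving move that rescales location effects jointly with their
  half-Cauchy scale.

Parameter recovery is the primary check: a planted 0.8 inter-response
correlation is recovered within ±0.15 at n = 150 (20-seed average) and a
planted rate ratio of 3.8 within ±0.6 at 500 signals.

## Synthetic scenario

The generator emulates the statistical structure the analysis assumes, with
ground truth retained for every draw:

* **Sources** — eight fecal/sewage environments, 12 samples × 20,000 reads
  each. Each source occupies a planted OTU support of 100 OTUs: a private
  block plus a fraction shared with the 250-OTU water block (sewage 0.80,
  dog 0.70, wild bird/pig 0.30, horse 0.25, cow/sheep 0.20, calf 0.10 —
  mirroring the reported ordering of water overlap). Shared OTUs get 0.3×
  the Dirichlet weight of private ones: fecal communities share *presence*
  with water while their read mass concentrates in source-specific taxa.
  Per-sample profiles are Dirichlet(60 × source mean); reads are multinomial.
* **Water** — three locations × 20 samples × 20,000 reads. Each location has
  a Dirichlet(1) baseline over the water block; samples apply logistic-normal
  drift of sd 0.5, sized to reproduce the strong between-season swings in
  order abundance that raw-water surveys report. Collection dates are spaced
  96 h apart so the 48 h exclusion rule fires only when a scenario plants
  violations.
* **Sinks** — ten sinks across the locations: five clean (pure background)
  and five mixed with sewage at 0.5, 1, 2, 5 and 10%. Each sink draws a
  fresh drifted water profile for its location; reads are drawn
  component-first so read-level origin labels are exact.
* **FIB** — MPN counts are negative-binomial (size 8) with log-mean affine
  in true contamination: baselines 2 / 30 / 1 and slopes 30 / 25 / 20 for
  E. coli / coliforms / enterococci, giving clean water that passes the
  background screen ≥ 95% of the time and contamination-event-scale counts
  at 10% contamination.

What passing tests on this scenario show: the estimator recovers planted
mixing proportions, background selection finds the planted clusters, and the
three qualitative findings (background libraries shrink spurious
contamination on clean sinks by more than tenfold, raise source accuracy,
and restore positive FIB correlation) follow from overlap structure alone.
What they do not show: robustness to taxonomy misassignment, chimeras or
compositional biases of real 16S data, to source communities that drift over
time, or to backgrounds not representable as logistic-normal perturbations;
real-data magnitudes (correlation sizes, OTU counts) are not reproduced,
only directions.

## Problem sizes and runtime choices

Desk-scale sizes are used throughout the test suite and the acceptance
script: the default scenario above (~800 OTUs, 166 communities), sampler
oracle instances small enough for exhaustive enumeration, reduced Gibbs
schedules where only an argmax is needed (library LOO-CV uses 3 restarts ×
50 burn-in sweeps), and MCMC at 4 chains × 600 iterations for the recovery
studies. These sizes are the package's own benchmark design; all thresholds,
priors and sampler defaults stay at their stated values everywhere.

## Known limitations

* The Unknown-source construction (α₂ scaled by sink depth) follows the
  reference sampler; it makes the Unknown share depend on sink depth, which
  is inherited behaviour rather than a modelling choice.
* The Laplace score uses a flat-prior approximation with boundary flooring;
  it is a ranking device, not a calibrated evidence estimate.
* Model 1's covariance sampler is slow-mixing below ~15 samples and will
  flag R̂; with 6 responses and few sinks the correlation posterior is wide.
* The DMM M-step optimizes all T Dirichlet parameters per component; very
  large OTU spaces (≫10⁴) would need sparsity handling that is not
  implemented.
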