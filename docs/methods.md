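# Methods

## Model

The estimand at every level is a comorbidity-treatment interaction on a
standardized outcome scale: the difference in treatment effect between
participants with and without a single comorbidity.  Inputs are trial-level
estimates `y_z` with known sampling SDs `s_z`; patient-level data never
enter the pipeline (they appear only in a test oracle for the SE formula).

Full (ontology-structured) model, trials z in drugs d in ATC level-5
classes c:

    y_z     ~ N(mu_z,    s_z^2)
    mu_z    ~ N(beta_d,  tau_d^2)
    beta_d  ~ N(gamma_c, sigma_c^2)
    gamma_c ~ N(alpha,   zeta^2)
    alpha   ~ N(0, 2^2)
    tau_d, sigma_c, zeta ~ half-N(0, 1^2), independent

Single-drug comparator, per drug: the two lowest levels with
`beta_d ~ N(0, 2^2)` and `tau_d ~ half-N(0, 1^2)`.

Scale-parameter granularity follows the model's subscripts: one `sigma_c`
per class and one `tau_d` per drug, each with its own prior.  A drug with a
single trial therefore has a `tau_d` informed almost entirely by its prior;
this is deliberate — it is the mechanism by which class-level information
dominates for data-poor drugs, and no special-casing is applied.

The location prior SD of 2 encodes the expectation that interactions are
uncommon and modest on a standardized scale; the half-normal unit-scale
priors are weakly informative relative to the between-level SDs used in the
simulation scenarios (0.05–0.25), so the fitted model is not handed the
generating values.

## Inference engine

The sampler is a blocked Gibbs scheme designed so that its two halves are
each exact:

1. **Locations.** The trial means `mu_z` are marginalised analytically
   (`y_z ~ N(beta_d, s_z^2 + tau_d^2)`); given the scales, the remaining
   location vector (alpha, gamma, beta) is jointly Gaussian and is drawn
   *exactly* each sweep by collapsing upward (per-drug Gaussian summaries,
   then per-class summaries) and sampling top-down
   (alpha, then gamma | alpha, then beta | gamma).  Location draws therefore
   have no autocorrelation given the scales.
2. **Scales.** `tau_d`, `sigma_c`, `zeta` have non-conjugate half-normal
   priors and are updated by univariate slice sampling (stepping-out +
   shrinkage) vectorised across drugs/classes, followed by an interweaved
   re-update in the non-centered parameterisation: holding the standardized
   deviations `(beta_d - gamma_c)/sigma_c` (resp. `(gamma_c - alpha)/zeta`)
   fixed, the conditional of the scale is a positive-truncated normal and is
   drawn exactly.  The interweaving breaks the location-scale "funnel" that
   otherwise makes `sigma_c` mix poorly in classes with few drugs
   (default-network fit: minimum bulk ESS rose from ~90 to ~680 per 5000
   draws).

Every kernel carries a leading replicate axis, so a batch of independent
datasets sharing one network is fitted in a single vectorised pass; the
replicates are conditionally independent, so this is an implementation
detail, not an approximation.  The single-drug models for all drugs are
likewise fitted simultaneously (they share no parameters).

Correctness is established two ways, both in the test suite:

- **Conjugate oracle.** With all scales fixed the model is jointly Gaussian;
  `fit_conjugate_oracle` computes the exact posterior of all locations
  (including `mu`) by one precision-matrix solve.  Sampler posteriors match
  it (drug-effect means within 0.005, SDs within 2%) on 20 random small
  networks.
- **Simulation-based calibration.** 500 datasets generated from the model's
  own priors on a 30-trial network yield 95% credible-interval coverage of
  the drug effects within three binomial MCSEs of 0.95.

Defaults: 2 chains x (500 warm-up + 2500 kept) sweeps for single quality
fits, with split-chain R-hat <= 1.01 and bulk ESS >= 400 required per
reported parameter (arviz diagnostics); results exceeding the thresholds
are returned flagged with a warning, never silently.  Batch fits use
1 chain x (350 + 1250) and store only drug-level draws — sufficient for the
point estimates and equal-tailed 95% intervals consumed downstream, and the
residual Monte Carlo noise in per-replicate summaries is an order of
magnitude below the between-replicate variation that the performance
measures estimate.  Equal-tailed intervals are used throughout.

## Data generation

Each scenario draws, per replicate: class effects
`gamma_c = alpha_sim + N(0, sd_class^2)` around the overall effect
(−0.1 standardized units), drug effects around their class, trial effects
around their drug, and observed estimates `y_z` around the trial effect
with SD `s_z = 2/sqrt(n_z p (1-p))` — the least-squares interaction SE for
a balanced two-arm trial with unit outcome SD, enrollment `n_z` and
comorbidity prevalence `p` (default 0.20; 0.10 and 0.50 as sensitivity
settings).  Prevalence enters only through `s_z`; no subgroup counts are
materialised.  The nine standard scenarios set the three SDs to 0.05
everywhere (all-low), 0.15 (all-medium), 0.25 (all-high), or raise one
level to 0.15/0.25 with the others at 0.05.

Seeding is counter-based: replicate `i` of a batch always uses the child
seed `(base_seed, 0, i)`, so batches are reproducible, parallelisable and
resumable by replicate index regardless of batch boundaries, and the same
replicates are fitted by both models (paired comparisons).

## The stand-in network

The published network of non-insulin glucose-lowering drug trials is
described by aggregates only; the packaged default network
(`data/default_network.csv`, regenerable bit-for-bit from
`ontopool._standin`) matches them exactly — 161 trials, 24 drugs, 7
classes, 210,046 participants, minimum enrollment 300 — and reproduces the
structural features the model's behaviour depends on: a right-skewed
trials-per-drug distribution (three single-trial drugs, three drugs with
>= 15 trials), class sizes from one drug (biguanides) to six (DPP-4
inhibitors), right-skewed enrollments (median 920, maximum 8,400) with
large outcome-trial programmes for the DPP-4/GLP-1/SGLT-2 classes and
small sulfonylurea and meglitinide trials, and one drug (taspoglutide,
placeholder code A10BX90) with a single 449-participant trial.
Enrollments are drawn from drug-size-dependent lognormals and rescaled to
hit the published total exactly.

What this stand-in cannot do: quantities that depend on the *particular*
allocation of trials to drugs — the published numeric values of coverage,
relative precision and (R)MSE per scenario — are not reproduced, only their
orderings (precision gain largest under high trial-level variation;
full-model coverage below single-drug coverage under all-level variation;
exclusive detections concentrated in the full model and in drugs with few
or small trials).  Pooled bias is allocation-robust and is reproduced
numerically.  Replacing the stand-in CSV with the real trial table makes
the structure-dependent cells comparable as well.

Passing tests on simulated data show the estimator behaves as designed
under the generating model; they do not address real-data complications
(inconsistent comorbidity definitions, missing covariates, aggregate-only
trials, non-exchangeable classes), which are out of scope.

## Performance evaluation

Measures pool all (replicate, drug) estimates with equal weight — the
convention of stacked estimates in standard simulation-study tooling; a
trials-per-drug weighting is not applied (the published table does not
state one).  Definitions:

- bias: mean(est − truth); MCSE sd/√N.
- MSE: mean((est − truth)^2); MCSE sd/√N; RMSE = √MSE with delta-method
  MCSE `mcse_MSE / (2·√MSE)`.
- relative precision: `100·((empSE_single/empSE_full)^2 − 1)` with the
  empirical SE taken as the SD of the point estimates across pooled records
  (an errors-based variant is available via `center="errors"`); MCSE by
  leave-one-replicate-out jackknife, which respects the pairing of both
  models on the same datasets.
- coverage: proportion of equal-tailed 95% intervals containing the
  replicate's true drug effect; exact binomial MCSE.
- detection classes: per drug, the proportions of replicates in which both
  models' intervals exclude zero / single only / full only / neither,
  conditioned by default on replicates whose true drug effect is −0.10 or
  more extreme in the simulated (negative) direction; the conditioning
  threshold is configurable and can be disabled.

## Problem sizes and numerical choices

The packaged evaluation runs use 250 replicates for the pooled-bias
results and 100 replicates for ordering checks (the headline study design
is 1000 replicates per scenario, available by configuration); at 250
replicates the pooled bias MCSE on the default network is under 0.002 in
the highest-variation scenario.  Slice updates use width 0.25 with
stepping-out capped at 60 steps; truncated-normal draws clip the uniform
variate away from 0/1 for tail safety; `interaction_se` requires prevalence
strictly inside (0,1) and the conjugate oracle rejects singular precision
matrices (possible only with degenerate fixed scales).  Networks are
re-indexed internally so trials are contiguous by drug and drugs by class
(segment-sum reductions); results are mapped back to input order, and
relabeling drugs or classes permutes but does not change posterior
summaries.

## Design choices on open points

- The same replicate datasets are fitted by both models (paired reuse);
  the alternative — independent draws per model — only inflates comparison
  MCSEs.
- Equal-tailed 95% intervals (a tail convention is not otherwise pinned
  down).
- Detection conditioning "−0.10 or larger" is read as `truth <= −0.10`,
  i.e. effects at least as large as the overall effect in the simulated
  direction, applied per replicate.
- Shared-scale variants (one tau or sigma for all units) are not provided;
  the per-unit scales follow the model definition, and sensitivity to this
  choice is better explored by editing the model than by a config switch.
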