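# Methods

## Scope

`bayespbpk` couples a generic whole-body physiologically-based
pharmacokinetic (PBPK) model to a two-level hierarchical Bayesian model of
a study population, fits the joint parameter distribution with a
block-wise Metropolis–Hastings (MH) sampler, and post-processes the
posterior into a population dependency structure that drives virtual-
population simulations and visual predictive checks (VPCs).  The package
is demonstrated on the public 12-subject theophylline study, which it
ships as a fixture.

## The PBPK model

The body is a flow circuit of 22 compartments: 19 tissues (lung, brain,
heart, muscle, bone, skin, fat, kidney, liver, stomach, small and large
intestine, pancreas, spleen, gonads, thymus, adrenals, salivary glands and
a rest-of-body pool) plus arterial blood, venous blood and the portal
vein.  Venous blood passes through the lung to the arterial pool; every
tissue receives arterial blood at its regional flow; the splanchnic organs
drain into the portal vein and on into the liver; everything returns to
the venous pool.  An oral dose enters the stomach lumen and moves through
a transit chain of five intestinal lumen segments; each segment absorbs
drug into the gut wall at a first-order rate `k_abs = intP * (SA/V)`,
where `intP` (dm/min) is the intestinal permeability and `SA/V` an
effective surface-to-volume ratio of 2.2e4 /dm that folds in mucosal
surface enhancement.  Gastric emptying is `1/GET`, segment transit
`5/ITT`.  Drug leaving the last segment is counted as unabsorbed.

Each tissue is a single well-stirred (perfusion-limited) space.  The full
four-subcompartment structure (plasma, red cells, interstitial,
intracellular) is collapsed into one effective space per organ with a
tissue-to-plasma partition coefficient

    Kp = (w_t + Lq*l_t + B*p_t) / (w_p + Lq*l_p + B*p_p)

computed from tissue composition (water/neutral-lipid/binding-protein
volume fractions `w, l, p`), the membrane affinity `Lq = 10^logMA`
(reduced to the neutral species for ionisable compounds) and a protein
affinity `B` anchored so that the plasma bound/unbound ratio reproduces
the measured plasma fraction unbound `fu`.  A tissue with plasma
composition therefore has `Kp = 1` exactly.  The composition table is a
documented fixture with literature-plausible values for lean human
tissue; its `p` columns are *binding-protein-equivalent* fractions, not
total protein.

Both clearance routes are first order.  The rate coefficient acting on
the organ amount is `spec * fu / Kp`, which at the well-stirred limit
yields a total organ clearance of `specCL * V_liver * fu` (hepatic
CYP1A2-mediated metabolism) and `specTS * V_kidney * fu` (renal tubular
secretion).  This product structure — a specific, per-litre rate times an
organ volume — is what allows the data to constrain the *product* while
leaving the factors anticorrelated in the posterior.

For a fixed parameter vector the system is linear and time invariant,
`dx/dt = A x` over compartment amounts (mg, minutes internally).  Columns
of `A` sum to zero by construction (eliminated, unabsorbed and excreted
drug accumulate in explicit sink states), so total mass is conserved to
machine precision.  The default solver propagates the state with matrix
exponentials, which is exact for a linear system: when all inter-sample
intervals are integer multiples of a common base step (true for clinical
schedules), one `expm(A h)` is computed and the other propagators are
assembled by binary squaring — stable because `expm(A h)` of a
mass-conserving generator is column-stochastic.  A BDF integrator
(`method="bdf"`, default tolerances 1e-8/1e-10 mg) is available as an
independent numerical route and agrees with the exponential path to
better than 1e-9 relative in the tests.

Out of scope by design: enterohepatic recirculation, saturable
(Michaelis–Menten) kinetics, transporters, metabolites and
dissolution-limited absorption.

## Covariate model and the population database

Population knowledge per parameter lives on an age x gender grid of mean
`M` and SD `S` with linear age interpolation and no extrapolation.
Normal parameters (19 organ volumes, 13 regional flows, hematocrit) are
modelled as `theta = M + S b` with `b` a standard-normal random effect;
organ volumes additionally scale with body height as
`theta = M r^a + S r^a b`, `r = H/Hbar(A,G)` and `a` an organ-specific
allometric exponent.  Lognormal parameters (GET, ITT, intP, specCL,
specTS) use the same linear model on the log scale.  Body weight is
defined as the sum of the 19 organ volumes (unit tissue density) and
serves simultaneously as observed data and as the constraint target
during sampling.

The packaged grid covers healthy adults (20–50 y, both genders) with
literature-plausible means, CVs of roughly 15–30 % and bounds at
mean x [0.3, 3] for the database-backed parameters; intP and the two
specific clearances carry two-orders-of-magnitude bounds because they are
a priori uninformed.  The grid is fixture data, versioned with the
package; it does not claim to reproduce any proprietary database, and no
acceptance check depends on matching one.

## Hierarchical model and priors

Observations follow a proportional error model: each plasma concentration
`Y` is normal with mean equal to the model output and SD `sigma * Y_model`;
the single urinary endpoint (cumulative fraction of dose excreted
unchanged at 36 h, fixture value 0.10) enters with the same form at a
fixed 5 % relative SD and is excluded from the estimation of `sigma^2`.
Pre-dose samples and non-positive concentrations are excluded from the
likelihood — the relative error is undefined against the model's
exactly-zero pre-dose output.

The joint state is `[theta_1..theta_N | theta_G | sigma^2 | M | S]` with
N individuals x K = 38 individual parameters, L = 2 global substance
parameters (logMA and fu), and one population mean and SD per individual
parameter: `N K + L + 2K + 1` scalars, 535 for the 12-subject study.

Priors (all on the sampling scale — natural for normal, log for lognormal
parameters, where every individual prior is a truncated normal):

* individual parameters: truncated normal with covariate-scaled `(M, S)`;
* globals: truncated uniform (logMA in [-2, 2], fu in [0.3, 0.9]);
* `M` hyperpriors: truncated normal around the database value with
  CV 20 % (multiplicatively, SD = log 1.2, for lognormal parameters),
  truncated at ±2 SD with a positive floor; for the uninformed
  parameters, truncated uniform over ±2 orders of magnitude around the
  start value;
* `S` hyperpriors: truncated normal with CV 50 % truncated at ±2 SD
  (floored), or, for the uninformed parameters, inverse-gamma
  (shape 1, scale 0.22) on the SD itself, truncated to (0, 1.5];
* `sigma^2`: the scale-invariant density `1/sigma^2` on [1e-6, 1].

The per-individual covariate scaling of the *sampled* `(M, S)` is the
affine map `M_i = a M + c`, `S_i = d S`, where `a, c, d` carry the height
ratio to the allometric power and the grid's relative age/gender factors
(additively on the log scale for lognormal parameters).  The sampled
moments are referenced to the cohort's reference covariates (first
subject by default).

## Sampler

One iteration visits each block once, in a fixed order: individuals
1..N, the globals together with `sigma^2`, two `M` half-blocks and two
`S` half-blocks (split by alternating parameter index).  Each scalar in
a block is proposed independently from a truncated normal centred at the
current value; the acceptance ratio carries the full asymmetric-proposal
(Hastings) correction.  Only the individual blocks and the global block
require PBPK evaluations (one simulation per individual), so a full
iteration costs 2N simulations.

The pure block-wise random-walk scheme mixes very slowly on a centred
hierarchy at desk scale: a population mean `M_k` can only track the
diffusing group mean of the N individual values, population SDs behave
analogously in the scale direction, and the likelihood carries exact
ridges (total clearance is `spec * V_organ * fu`, so the global fraction
unbound trades off against the clearance levels, and each specific rate
against its organ volume).  One additional block per iteration therefore
performs a *location-scale group move* that walks along these directions
while leaving the standardised random effects invariant:

* a translation `M' = M + delta`, `theta' = theta + a delta` (correlated
  `delta` drawn with a between-run-adapted, shrinkage-regularised
  Cholesky factor of the pre-run M covariance);
* a rescaling `S' = S exp(eps)` with the random-effect residuals scaled
  accordingly (log-Jacobian `(N+1) sum(eps)`);
* product-invariant shears: the fraction unbound moves multiplicatively
  while the specCL/specTS levels co-shift by the opposite log amount, and
  the liver/kidney volume columns (theta, M, S) scale multiplicatively
  while their specific rates shift oppositely (log-Jacobians `d` and
  `(N+2) gamma`).

Per individual the volume component of the group move is absorbed by the
widest-bounded organ so the body-weight sum stays exact; the innovations
are symmetric, so the acceptance ratio is the posterior ratio times the
stated Jacobians.  Correctness of the whole move family is verified by a
prior-sampling run (likelihood disabled): the chain's marginal moments of
the population means match their truncated hyperpriors within
Monte-Carlo error.

Organ volumes are proposed with the sequential sum-constrained sweep:
organs are processed in ascending order of static bound width (ties
broken by name), each organ's bounds are tightened dynamically against
the remaining body weight so the sweep always stays feasible, and the
final organ receives the exact remainder.  The proposal density of the
move is the product of the sequential truncated-normal densities under
the dynamic bounds of the respective sweep (forward and reverse; the
ordering depends only on static bounds, so both sweeps visit organs
identically), and the remainder organ contributes no density term.  The
feasible reading of the dynamic bound pair is `lower* = max(lower,
BW_rem − sum of remaining uppers)` and `upper* = min(upper, BW_rem − sum
of remaining lowers)`.  The correctness of the move is verified against
rejection sampling on a three-organ toy target.

Proposal scales are adapted only *between* runs.  After each pre-run the
per-scalar SD is set to a per-block fraction (2.38/sqrt(block dimension),
capped at 0.8) of the empirical chain SD; each block's fraction is
additionally steered by its observed acceptance towards the classic 0.234
random-walk optimum, because in a centred hierarchy the conditional
widths are systematically narrower than the marginal chain SDs.  Adapted
SDs are floored at one tenth of the previous value so a short pre-run
cannot collapse a block's scale.  Start values of a run are the last
state of the previous run.  Initial proposal SDs are scaled to the
conditional widths (prior SD for individual parameters, `S/sqrt(N)` for
population means, `S/sqrt(2N)` for population SDs).

A single seeded generator stream drives the whole run serially; chains
are bit-reproducible for a fixed seed.  Convergence is monitored with the
split-in-two Gelman–Rubin statistic on a fixed set of quantities: the
population mean and SD of the nine exemplary parameters (intP, specCL,
specTS, GET, ITT, and the fat/kidney/liver/muscle volumes) plus
`sigma^2`.  Thinning draws Z states uniformly without replacement from
the post-burn-in chain.

Two built-in profiles exist: `cluster` (10^6 iterations, 2x10^5 burn-in,
Z = 500 — cluster scale, not run in this repository) and `desk`
(3x10^4 iterations after pre-runs of 300/600/900, first third discarded,
Z = 500), sized so a full positive-control fit completes in minutes on
one CPU.  At desk scale the slowest hierarchical modes (population means
and SDs, which must co-move with all individual parameters) retain split
R-hat values well above 1.05; this is a run-length limitation of the
centred random-walk scheme, not a correctness defect — the sampler is
exact on conjugate and constrained toy targets, and the original
cluster-scale configuration used 5–30x more iterations.

## Posterior dependency structure and generation

For each of the Z thinned draws the random effects are recovered by
inverting the covariate model with that draw's own population moments,
`b = (theta − M_i)/S_i` on the sampling scale.  The population dependency
model is the equal-weight Gaussian mixture over subsamples with component
mean `mean_i b` and component covariance the sample covariance across the
N individuals (rank at most N−1; handled by spectral square roots with
negative eigenvalues clipped at 1e-10 of the largest).  A new virtual
individual draws a subsample uniformly, a random-effects vector from its
component, and maps it through the covariate model with the same draw's
moments and global parameters, so hyperparameter uncertainty propagates
into population simulations; out-of-bounds vectors are redrawn (at most
100 attempts, then an error).

Population correlations are the per-subsample Pearson correlations of
the random effects across individuals.  Their uncertainty is summarised
two ways — the 2.5/97.5 percentiles of the Z per-subsample values and the
mean of the per-subsample Fisher confidence intervals — because the
published construction is ambiguous; significance is a two-sided
one-sample t-test of the Fisher-z values against zero at alpha = 0.05.
Intraindividual (posterior) correlations are computed across draws for a
fixed subject and are a distinct quantity.  Marginal summaries report the
geometric mean `exp(mean(log x))`, the natural-scale CV, and a Gaussian
KDE with Silverman bandwidth reflected at the truncation bounds and
renormalised over the bounded support.

## Visual predictive checks

A VPC replicate simulates all study subjects once (each at its own
covariates and dose) at the nominal schedule and records the 5th/50th/
95th percentile curves across subjects (type-7 quantiles throughout);
bands are the 2.5/97.5 percentiles of each statistic across replicates.
Sources: `posterior` (mixture generation as above), `prior` (independent
draws from the database moments, with a lognormal of geometric SD 1.5
standing in for the uninformed parameters), and `map` (population
parameters fixed at the stored draw with the highest joint posterior
density — no separate optimisation — and independent standard-normal
random effects).  Measurement noise is excluded by default
(`include_noise=True` adds it).  Failed replicates are excluded and
counted.

## Synthetic data

`generate_positive_control` draws `(M, S)` from the hyperpriors — with
normal (log-scale, SD log 1.2) stand-ins for the uninformed population
means, and inverse-gamma S draws truncated to the catalogue bounds —
then independent standard-normal random effects per subject, heights from
N(mean height, 7 cm) clipped to [160, 195], body weight as the sum of the
generated volumes, dose 4.5 mg/kg, simulation at the theophylline design
(10 positive sampling times plus the 36-h urine endpoint) and
multiplicative noise `(1 + eps)`, `eps ~ N(0, noise_cv^2)` with
`noise_cv = 0.10` by default.  The full generating truth is stored and
replay is byte-identical per seed.  `generate_correlated_population`
additionally imposes a prescribed (PSD-checked) correlation on the random
effects.  What the generator does *not* emulate: assay quantification
limits, dosing-time deviations, model misspecification (e.g. the
dissolution-limited absorption visible in one real subject) — so passing
positive-control tests demonstrates self-consistency of the inference
machinery, not accuracy on misspecified real data.

## The theophylline fixture

The packaged CSV reproduces verbatim the public-domain 12-subject
theophylline study (11 plasma samples each, oral dose recorded per kg,
body weights) as distributed with R's `datasets` package; the loader
checks a SHA-256 checksum.  The study reports no ages or heights: all
subjects are assigned age 30 and heights drawn once from a fixed,
documented seed such that BMI falls in [19, 25] (the fixture's heights
are its own, not those of any other analysis).  Doses are converted to
absolute mg.  A shared urinary endpoint (0.10 at 36 h, 5 % relative SD)
is attached to every subject.

## Numerical choices

* Truncated-normal sampling by inverse CDF on `Phi`-transformed bounds;
  clipped at 1e-15 to avoid tail overflow.
* Degenerate dynamic bounds (width < 1e-13) collapse to a point mass with
  zero density contribution.
* `R-hat` with zero within-chain variance is reported as NaN, not
  silently 1.
* KDE integrates to 1 over the truncated support within 1e-3 (tested by
  quadrature); truncated priors integrate to 1 within 1e-6.
* All tolerances used in tests are stated in the tests themselves;
  Monte-Carlo assertions use 3 standard errors with conservative
  effective-sample-size allowances.

## Known limitations

* Desk-scale chains do not reach R-hat <= 1.05 on the slowest population
  hyperparameters (see Sampler above); cluster-scale run lengths are
  configured but not exercised here.  For the same reason short chains
  understate the magnitude of posterior dependency structure: the
  population correlations computed from a desk-scale fit of the packaged
  study recover the expected signs but not yet their full-scale
  magnitudes.
* The effective-Kp organ model is a documented simplification of a
  subcompartment-resolved distribution model; absolute tissue
  concentrations are therefore approximate even though plasma PK is
  structurally faithful.
* The covariate model is only exercised for a covariate-homogeneous adult
  cohort; mixed-age cohorts use the documented ratio/shift scaling of the
  sampled moments, which is untested against any external reference.
* Parallel per-individual evaluation is a contract of the design but the
  implementation is serial.
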