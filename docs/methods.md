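# Methods

`heatfish` reimplements, on synthetic data, a complete analysis of how
two decades of whole-ecosystem heating changed growth, mortality, and size
structure in a pair of reproductively isolated Eurasian perch populations —
one in an artificially heated enclosed bay, one in an adjacent reference
area at natural temperature.  This note documents the models, the
generative assumptions of the synthetic data, the sampler, and the design
choices that were genuinely open.

## Models

### Size-at-age (von Bertalanffy)

Length at catch is modelled on the log scale with a Student-t likelihood,

    log L_i ~ Student-t(nu, log[ L_inf_j (1 - exp(-K_j (t_i - t0))) ], sigma)

with `L_inf` and `K` varying among cohorts `j` around area-level
hyper-means.  Cohort deviations of `L_inf` and `K` are independent normals
(no correlation is modelled between them); `t0` is a per-area fixed effect.
Eight variants arise from letting each of `L_inf`, `K`, `t0` be shared or
area-specific; variants are compared by PSIS-LOO.  Only length and age *at
catch* enter this model — back-calculated lengths would require a second,
within-individual level of the hierarchy for little gain at ~5 observations
per fish.

Priors: `mu_Linf ~ N(45, 20)` cm, `mu_K ~ N(0.2, 0.1)` /yr,
`t0 ~ N(-0.5, 1)` yr, `nu ~ Gamma(2, 0.1)`, and half-Student-t(3, 0, 2.5)
on every scale parameter.  Positivity of `L_inf` and `K` is enforced by
sampling their logs, with the stated priors applied on the natural scale
through the change-of-variables Jacobian, so the priors remain exactly as
written while the log inside the likelihood stays defined.

### Growth-at-size (allometric)

Annual specific growth `G = 100 (log L_{t+1} - log L_t)` (%/yr, natural
logs), attached to the geometric mean length of the interval, follows

    G_i ~ Student-t(nu, alpha_{j[i]} * L_i^theta, sigma)

with `alpha` varying across individuals nested in cohorts (two normal
levels) and `theta` shared or area-specific (two variants).  Priors:
`mu_alpha ~ N(500, 100)`, `theta ~ N(-1.2, 0.3)`, half-t(3, 0, 13.3) on
the three scale parameters.

### Catch-curve mortality

Under exponential decline `N_t = N0 exp(-Z t)` and catch proportional to
abundance, log CPUE is linear in age with slope `-Z`.  Binned catch is
converted to catch-at-age through area-specific age-length keys (ALKs)
built from the aged subsample; the expansion conserves total catch
exactly.  Because small fish are not representatively caught, only ages on
the descending right limb enter the regression: the modal age and older,
with the mode computed per area on year-pooled mean CPUE (the year-pooled
modal-age convention is our choice; pooling is the stabler of the two
obvious readings).  The regression is

    log CPUE_i ~ Student-t(nu, (b0 + u0_j) heat + (b1 + u1_j) ref
                               + (b2 + u2_j) age + (b3 + u3_j) age*heat, sigma)

with cohort (`year - age`) deviations under a zero-mean MVN with estimated
SDs and correlations, flat priors on the coefficients, `nu ~ Gamma(2, 0.1)`
and half-t(3, 0, 2.5) scales.  `Z_ref = -b2`, `Z_heat = -(b2 + b3)`;
annual mortality is `1 - exp(-Z)`.  Variants without the interaction and
with deviations restricted to the intercepts are available and compared by
LOO.  A classical OLS slope estimator (`catch_curve_slope_ols`) serves as
an independent cross-check; on exactly log-linear data the Bayesian
posterior is degenerate (the likelihood grows without bound as the
residual scale goes to zero), so exact-recovery checks use the OLS
estimator, which reproduces the slope to machine precision.

### Size spectrum (MLEbin)

Body sizes follow a bounded power law with density proportional to `x^b` on
`[xmin, xmax]`.  For binned counts the exact bin probabilities

    P(bin j) = (e_{j+1}^(b+1) - e_j^(b+1)) / (xmax^(b+1) - xmin^(b+1))

(log form at b = -1) give a multinomial likelihood that respects the
unknown position of each fish within its bin.  The exponent is maximized by
bounded 1-D optimization; the 95% CI is the profile-likelihood set at a
drop of 1.92 log-likelihood units.  All years are pooled before fitting.
Length classes are converted to mass with `W = a L^b` (defaults a = 0.01,
b = 3.0 — generic fusiform-fish values, a package choice); 1 cm classes are
first merged onto the 2.5 cm grid by proportional width overlap.  The
fitted exponent is that of the individual size distribution, recorded under
the size-spectrum label gamma; the biomass-spectrum exponent (`b + 1`) is
stored in the fit metadata.

### Mean size and age (lognormal)

Length-class midpoints (CPUE-weighted) and expanded integer ages are
modelled as `y ~ LogNormal(mu, sigma)` with year-varying area intercepts
under a correlated bivariate normal, flat priors on coefficients and
half-t(3, 0, 2.5) scales.  The full catch is used (no descending-limb
filter), assuming equal catchability between areas.  Area differences are
computed on the natural scale via `exp(mu + sigma^2/2)` with year effects
omitted; this expected-value difference is necessarily narrower than the
posterior-predictive difference, which adds observation noise — a property
the tests assert.  Midpoints are the minimal assumption for the unknown
within-class lengths; weights enter as frequency multipliers of the
likelihood.

## Inference

No gradient-based PPL is a dependency of this package; the sampler in
`bayes_engine` is written for exactly this model family:

* **Scalar parameters**: one-at-a-time adaptive random-walk Metropolis
  (target acceptance 0.44), plus one joint adaptive-Metropolis move per
  iteration over the whole scalar vector using the running empirical
  covariance (target 0.234), which handles cross-parameter correlations
  such as t0 with the growth coefficients.
* **Latent blocks** (cohort, individual, year effects): all units of a
  block propose simultaneously and accept independently on their per-unit
  conditional densities — valid because units are conditionally independent
  given the rest.  Multivariate units (the paired `(log L_inf, log K)`
  cohort blocks, the MVN cohort vectors of the catch curve) use per-unit
  proposal covariances learned during warmup, which aligns proposals with
  the strong within-cohort L_inf-K ridge.
* **Tailored joint moves** where the posterior has a known slow manifold:
  a t0 shear (shift t0, rescale every cohort K to keep length at the mean
  observed age fixed), a collective L_inf scale move (multiply an area's
  L_inf hyper-mean and cohort values by a common factor, re-solving each
  cohort K to hold length at the mean age fixed, with the exact Jacobian),
  the analogous alpha-theta shear pivoted at the mean log length, and
  interweaving moves that rescale a level's deviations together with its SD
  to cross variance-component funnels.  All are deterministic bijections
  applied to symmetric innovations, accepted with the posterior ratio times
  the Jacobian determinant.

The sampling contract is 3 chains, 4000 iterations per chain, first half
discarded as warmup (the source analysis states 4000 iterations per chain
without a warmup split; half is the conventional reading).  Convergence
requires split-R-hat < 1.1 for every stored parameter; non-convergence is
flagged on the result and logged, never silently dropped.  Model comparison
uses PSIS-LOO elpd through `arviz`, with Pareto-k >= 0.7 reported as a
warning; a brute-force exact leave-one-out refit backs the PSIS estimate in
the tests.  The correlation matrices of MVN group effects are parametrized
by tanh of unconstrained partial correlations (vine construction) with a
uniform prior on each partial correlation — identical to a uniform
correlation prior in the 2x2 case and close to LKJ(1) in higher dimension.

## Synthetic data

The generator produces the structure the models assume, at the reported
posterior medians as defaults: heated vs reference `L_inf` 45.7/39.4 cm,
`K` 0.19/0.15 /yr, `t0 = -0.5` yr, `Z` 0.73/0.62 /yr, `alpha` 512/433,
`theta` -1.13/-1.18; cohorts 1981-1997, catch years 1987-2003, with 2.5 cm
length classes (1 cm in 2001-2003, merged back to 2.5 cm in analysis).

Choices the source does not state, fixed once:

* Between-cohort SDs `sigma_Linf = 2.0` cm, `sigma_K = 0.015` /yr (5% and
  8% CV).  Moderate cohort variation; large values would make hyper-mean
  recovery at a few hundred fish per area dominated by cohort-sampling
  noise rather than inference quality.
* Observation noise on log length: Student-t with `nu = 5`,
  `sigma = 0.08` (~8% length CV, heavy-tailed).
* Gillnet selectivity: a dome in log length with mode 15 cm and spread 0.6
  (any unimodal curve exercises the descending-limb logic; the true mesh
  selectivity is unknown).
* Lifespans are exponential at the area's Z; deaths fall between birthdays
  and a fish is sampled at its last attained integer age, which makes the
  age composition within a catch year decline exactly as `exp(-Z age)`.
* Annulus radii are exact inversions `r_a = R (L_a / L_s)^(1/s)` of the
  true birthday lengths (`s = 0.861`, `kappa = 20` — kappa cancels in
  back-calculation and matters only here), so with noise and jitter off,
  back-calculation round-trips to the true lengths exactly.  Optional
  multiplicative radius jitter breaks the exactness on request.
* The aged subsample is age-stratified (the field protocol aged a random
  or stratified subset): evenly across ages, randomly within an age.  This
  enriches the rare old fish that identify `L_inf` without selecting on
  length within an age, which would bias length-at-age.
* The allometric growth generator draws
  `alpha_id = alpha_area + u_cohort + v_id` with SDs 30 and 40 and adds
  Student-t noise of scale 4 %/yr to `G`; lengths along trajectories come
  from the area's mean VBGE curve.  1200 individuals per area is the
  default (emulating the ~2400 back-calculated individuals of the study);
  the checks run at 600/area.

What the generator does *not* emulate: density dependence, individual
growth autocorrelation beyond the individual intercept, size-selective
mortality, gear saturation, ageing error, or measurement error on radii
(unless jitter is enabled).  Passing recovery tests therefore demonstrate
that the estimation chain is correct and well calibrated for data of this
structure and size — not that the original field estimates are right.

### Two deliberate deviations in the end-to-end pipeline

* The pipeline's allometric stage fits growth data from the allometric
  generator, not the back-calculated increments of the VBGE fish.  VBGE
  radii are exact inversions, so within an individual the G-L increments
  are deterministic and follow the VBGE trajectory curvature; fitting the
  individual-intercept growth model to them estimates the *within*-
  trajectory slope (theta near -1.5 with an inflated alpha scale) rather
  than the size scaling the model is built to contrast.  Back-calculation
  still runs on the fish records and is validated by the round-trip
  property.
* The parameter-recovery simulations use an 8-cohort window (1984-1991)
  inside the full span, so every cohort has two-sided age coverage.  With
  the full 1981-1997 span the late cohorts are seen only at young ages and
  their `L_inf`/`K` drift along the ridge — reproducing a pathology the
  original analysis itself reports for its 1995-1997 cohorts — which makes
  the full span unsuitable for a recovery benchmark.

## Problem sizes and numerical choices

Recovery checks use 500 aged fish per area (VBGE), ~5400 growth
observations (allometric, 600 individuals/area), 15 years x ages 2-8
(catch curve), and 10 scaled-down replicates of ~70 recruits/cohort over
5 cohorts for the LOO variant selection; the end-to-end demo simulates 400
recruits per cohort over the full design.  MLEbin optimization is bounded
Brent on [-10, 5] with 1e-8 tolerance and profile-CI roots by bisection;
a 1e-3 grid search is the test oracle.  Zero-CPUE cells are dropped before
logs (with a count logged); ALK rows with no aged fish are imputed from
the nearest populated length class; degenerate single-fish cohorts are
retained and shrink toward the hyper-mean.  Credible intervals are
equal-tailed quantiles; the point estimate is always the posterior median.

## Known limitations

* The Metropolis-within-Gibbs sampler needs the tailored joint moves to
  mix on the VBGE ridge; a variant with a genuinely new slow manifold
  (e.g. strongly informative cohort-level priors) may require a new move.
* The `varying='all'` catch-curve variant (4-D correlated cohort effects)
  mixes more slowly than the selected intercepts-only variant when the
  generating process has no cohort-varying slopes and its SD posteriors
  pile near zero; it is used for LOO comparison, where this is benign, and
  its convergence flag reports the state honestly.
* Percent differences and size-at-age ratios evaluated at the default
  generator parameters differ from some derived quantities the original
  study prints where those depended on unprinted fitted values (notably
  area-specific t0); the package asserts directions, not those magnitudes.
* `prior_predictive_lengths` scales the half-t priors of the cohort-level
  SDs for plausibility of the *generative* check; it is a diagnostic
  helper, not the fitted model's prior.
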