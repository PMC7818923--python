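# Methods

## Model

Six sequential IVF outcomes are modelled per treatment cycle, in temporal
order: oocyte count (O), embryo count after fertilisation (M), two
embryo-level ordinal quality grades — cell evenness (E) and degree of
fragmentation (F), coincident in time — and two binary outcomes among
cycles reaching transfer: double embryo transfer (D) and live birth (L).

* **O** — Poisson with log link. The patient-level latent intercept
  z<sup>O</sup> gives a Poisson-lognormal marginal, capturing the strong
  between-patient overdispersion of oocyte yield (marginal mean
  e<sup>xβ+θ²/2</sup>, variance exceeding the mean).
* **M** — Poisson with an offset log y<sup>O</sup>, so e<sup>xβ+z</sup> is a
  per-oocyte fertilisation rate. The submodel covers cycles whose oocytes
  were mixed/injected with sperm; oocytes not mixed are treated as unable
  to fertilise (they are almost always degenerate), so the offset uses the
  full retrieved count.
* **E, F** — proportional-odds cumulative logit over grades 1–4 with three
  strictly increasing thresholds each and a patient-level latent intercept,
  identified by the clustering of embryos within patients. The linear
  predictor enters with a negative sign, so positive coefficients raise
  grades. Per-grade (non-proportional) coefficients are out of scope: the
  type layout reserves them, but every code path assumes constant effects.
* **D, L** — latent probit: the outcome is the sign of xβ + z with
  z of unit variance, which is exactly a probit regression marginally and
  lets the binary submodels correlate with the rest through z.

The per-cycle latent vector is MVN(0, Σ) with
Σ = diag(θ<sub>O</sub>, θ<sub>M</sub>, θ<sub>E</sub>, θ<sub>F</sub>, 1, 1) ·
R · diag(…), R a correlation matrix with 15 free entries η (row-wise upper
triangle in outcome order; the matrix is treated as symmetric with the
upper triangle authoritative). η = 0 recovers six independent submodels —
the "separate models" baseline — which the test suite exploits as a
factorisation oracle.

Patients who fail at a stage leave all downstream submodels; their
remaining latent components carry prior-only contributions and are
sampled from (or integrated under) their conditional MVN distribution.

### Covariates and scaling

Baseline covariates: age and partner age (linear, standardised for
fitting by cohort mean/SD and reported per year), attempt number as a
four-category factor (first attempt reference; attempts ≥ 4 pooled at
read time because the categories are sparse), and, in the grading
submodels only, the embryo-level ICSI flag (sperm injected into egg).
In the *dynamic* setting the realised upstream outcomes additionally
enter downstream submodels: the oocyte count and the fertilisation rate
(defined as y<sup>M</sup>/y<sup>O</sup>) into E, F, D, L; the patient's
mean evenness and mean fragmentation grades into D and L; and DET into L.
Dynamic outcome covariates are standardised by training-cohort statistics
as well — a package choice made for sampler stability, recorded in the
cohort's `covariate_scaling` so predictions evaluate linear predictors on
the identical scale.

### Priors

N(0, 1000²) on count/ordinal coefficients and ordinal thresholds
(effectively flat); N(0, 2²) on probit coefficients — weakly informative,
appropriate because the probit latent scale is pinned at 1; half-Cauchy(0,
2.5) on the free latent SDs; LKJ(1) — uniform over valid correlation
matrices — on the latent correlations.

## Sampler

No external MCMC backend is assumed; `ivfjoint.inference` implements a
blocked Gibbs/Metropolis scheme:

* **Probit blocks (D, L)** — Albert–Chib data augmentation: the latent
  utility is drawn from a truncated normal on the side dictated by the
  observed indicator, conditioned on the other latent components through
  the MVN conditionals, and the coefficients are then drawn from their
  conjugate normal posterior. Five augmentation sub-draws per stored
  iteration remove essentially all autocorrelation in these blocks. This
  is the "sample the probit latents explicitly, deterministic sign rule"
  side of the likelihood contract; the analytic-marginalisation route is
  implemented in `ivfjoint.likelihood` and the two are tested against
  each other.
* **Count/ordinal coefficient blocks** — random-walk Metropolis with an
  empirical-covariance proposal adapted during warmup, followed by a
  component-wise refinement sweep (which rescues sparse dummy columns) and
  a likelihood-invariant *recentring* move that shifts the intercept (or
  the threshold vector) against the latent column — the slowest posterior
  direction otherwise.
* **Patient latents** — per-patient scalar random-walk Metropolis,
  vectorised across patients, with per-component adaptive steps; patients
  outside a submodel's population get exact conditional-prior draws.
* **Latent SDs** — log-scale Metropolis plus a joint (θ, z) multiplicative
  rescaling move with the a<sup>n+1</sup> Jacobian, which traverses the
  funnel geometry that single-site updates explore slowly.
* **Correlations** — element-wise Metropolis with positive-definiteness
  rejection; under LKJ(1) the prior contributes nothing inside the valid
  set. `FitConfig.fix_eta` freezes them (e.g. at zero).

Defaults: 3 chains, warmup equal to the sampling iterations (warmup-only
adaptation), convergence flagged — never silently accepted — when any
split-R̂ exceeds 1.05. At n = 300 cycles a 3 × 1500 joint fit takes about
half a minute on one CPU and reaches max R̂ ≈ 1.03; the known imprecision
of the dynamic joint model is treated as behaviour, not error, with
`check_dynamic_precision` emitting a warning when joint posterior SDs of
outcome-covariate coefficients exceed 5× their separate-fit counterparts.

## Synthetic cohorts

`simulate_cohort` runs the generative chain forwards and is the only data
source for tests (the motivating clinical dataset is not shareable). The
stated world it emulates, and its limits:

* Default coefficients are the pre-treatment joint point estimates
  reported for the motivating clinic cohort (oocyte intercept 2.10, age
  −0.04/yr; fertilisation intercept −0.95; evenness thresholds −4.35,
  −1.38, 1.33; fragmentation −5.11, −2.44, −0.33; DET intercept 0.13; LBE
  intercept −0.49; …). The latent SDs/correlations were not reported
  (supplementary material unavailable), so θ = (0.5, 0.3, 0.8, 0.9) and
  η = 0 except a 0.2 D–L entry are documented placeholders chosen for
  realistic overdispersion — **not** estimates.
* Covariates match the published baseline table: age ≈ rounded
  TruncNormal(33, 4.4²) on [21, 43], partner age ≈ TruncNormal(35.5,
  5.2²) on [19, 72] (medians/IQRs match), attempt probabilities (0.720,
  0.223, 0.050, 0.008), and cycle-level ICSI Bernoulli(0.5) (no published
  prevalence; roughly half of UK cycles use ICSI).
* The embryo count is truncated at the oocyte count for data validity,
  although the fitted likelihood is untruncated Poisson; at the default
  rates (≈ 0.39 embryos per oocyte) the truncated mass is negligible.
* Transfer is deterministic (any embryo ⇒ transfer) by default; the model
  does not describe the embryos-but-no-transfer transition, so an
  optional thinning probability reproduces the observed gap instead.
* DET is forced to 0 when only one embryo exists — a generator-side
  realism rule absent from the fitted submodel.
* The number of gradable embryos is equated with the fertilisation count;
  whether the clinical count was further filtered is unknowable from the
  published summaries.
* Not simulated: multiple cycles per woman, miscarriage vs implantation
  failure, twin births, frozen cycles, embryo selection.

A green test against this generator therefore establishes internal
consistency of model, sampler and predictions under the stated world; it
says nothing about clinical transportability.

## Prediction and denominators

Predictions are whole-cycle posterior-predictive simulations with
deterministic failure propagation: a draw with zero oocytes has no
embryos, no grades, no transfer and no live birth. Two accounting
conventions are first-class: *per cycle started* (upstream failure is a
downstream non-event — the treatment-policy reading) and *per stage
reached*; embryo grades are always conditional on embryos existing.
Latents may be drawn from their fitted MVN (`latents_included=True`) or
set to zero; both readings are supported and the caller must choose.
In dynamic prediction the observed prefix is fixed in the output and
feeds downstream covariates; the remaining stages' latents are *not*
filtered on the observed outcomes — conditioning flows through covariates
only, matching the covariate-based dynamic submodels. Joint-event
probabilities report the mean over all draws with a 2.5/97.5 percentile
interval of the per-posterior-draw predicted cohort proportion (not a
draw-level binomial interval).

Grade predictions for a new patient are reported per hypothetical embryo
(one grade distribution) rather than per simulated embryo, unless the
caller works with the full per-embryo simulation.

## Evaluation

RMSE for counts and grades (grades numeric 1–4; point prediction the
posterior-predictive median, switchable to the mean), Brier score and
Mann–Whitney AUC with a DeLong 95% CI for DET and LBE. Binary metrics are
computed over transfer-reaching cycles — the population those submodels
are fitted to — and the report records the denominator. In-sample scoring
is permitted but always labelled: it checks mean calibration machinery
and does not constitute validation.

## Numerical choices

* Probability normalisation asserted to 1e-12; ordinal probabilities
  floored at 1e-300 before logs.
* Covariance validity is checked by Cholesky with no jitter: a
  non-positive-definite correlation combination is an error, never
  silently repaired.
* Truncated-normal draws use inverse-CDF sampling with probabilities
  clipped to [1e-15, 1 − 1e-15].
* Log Poisson rates are capped at ~13.8 (rate 1e6) in the generator as a
  pure overflow guard, far above any plausible value.
* The latent-integrated likelihood (`gh_marginal_loglik`) uses ≥ 40-node
  Gauss–Hermite quadrature per count/ordinal latent dimension after a
  Cholesky transform; probit dimensions are integrated exactly through
  the conditional normal CDF (including the bivariate orthant case),
  because quadrature against their discontinuous indicator converges only
  at O(1/nodes). The result is the same integral, evaluated stably.
* Ties in the AUC are handled by midranks; the empty-conditioning case of
  the MVN conditional returns the marginal.

## Known limitations

* No residual embryo-level correlation between the two grading scales
  beyond the shared patient latents: the model implicitly equates the
  within-embryo and between-embryo evenness–fragmentation relationship.
* One cycle per woman; no three-level (embryos within cycles within
  women) extension.
* The dropout process itself is not modelled; missingness-at-random is
  addressed only through joint modelling/covariate conditioning.
* The Metropolis sampler targets desk-scale problems (hundreds of
  cycles); full clinic-scale joint fits with free correlations and
  outcome covariates remain expensive, and correlation parameters mix
  more slowly than coefficients (watch their R̂).
* Mean embryo grade is a crude summary for the transfer submodels; the
  best available grades would better reflect embryo selection.
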