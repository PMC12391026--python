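# Methods

## The model and the metric

A germination trial exposes `n` seeds of one species to each of three
photoperiod treatments — short day (6 h light / 18 h dark), equal day
(12 h / 12 h) and long day (18 h / 6 h) — and records the number of
germinants per treatment. Counts are modelled per species as binomial with a
logit link and the equal-day treatment as reference:

    logit P(germinate) = μ0 + β1·[long] + β2·[short]

β1 and β2 are log-odds contrasts of the long- and short-day treatments
against the equal-day reference. The photoperiod sensitivity metric is

    PSM = sqrt( (β1² + β2² + (β1 − β2)²) / 3 )

This is algebraically the root sum of squared deviations of the three
treatment linear predictors {0, β1, β2} about their mean — i.e. √3 times
their population standard deviation. We implement the formula as written
above; describing it loosely as "the standard deviation of the treatment
means" overstates by that √3 factor, and the formula is the definition.
PSM = 0 exactly when germination is identical across treatments, and it is
invariant to relabeling long ↔ short and to negating both contrasts.

The contrasts are deliberately kept on the logit (linear-predictor) scale
rather than the probability scale: probability differences are bounded by 1,
which would be incompatible with the regularization behaviour described
next (contrast magnitudes approaching 5).

## Regularized estimation under separation

Species with zero (or complete) germination in a treatment make the
unpenalized logistic MLE infinite. We therefore estimate the posterior mode
under independent zero-centred Student-t priors: Cauchy (df = 1) with scale
2.5 on each treatment contrast and Cauchy with scale 10 on the intercept —
the weakly-informative default of Gelman et al. (2008). Dummies are raw 0/1
with no centering or rescaling, so the coefficients remain directly
interpretable as treatment-vs-equal contrasts and feed the metric without
transformation.

Optimisation is damped Newton on the penalized log-posterior: the Newton
system is ridge-stabilised when the negative Hessian loses positive
definiteness (the Cauchy prior is log-concave only near the origin), each
step is halved until the objective is non-decreasing, and convergence is
declared when the score max-norm falls below 1e-8 or the step below 1e-10
(cap 250 iterations; in practice fewer than 20). The reported covariance is
the inverse negative Hessian of the log-posterior at the mode — the
*penalized* curvature, which stays finite under separation.

With a single separated cell against informative cells at ≤ 30 seeds per
treatment, the Cauchy(2.5) prior keeps |β| below 5 (e.g. 15/30, 15/30, 0/30
gives |β2| ≈ 4.42). When cells are separated in *opposite* directions (e.g.
0/30, 0/30, 30/30) the long-vs-short contrast is a difference of two
runaway cells penalized only logarithmically, and its mode can exceed 5
(≈ 10.4 in that example) while remaining finite; such species carry
essentially no interior information and the estimate should be read as
"very large", not as a calibrated magnitude.

## Bootstrap uncertainty, weights and classification

The metric's standard error is a parametric bootstrap: 10,000 coefficient
vectors (default) are drawn from a multivariate normal centred at the MAP
with the full 3×3 posterior covariance — the intercept dimension is included
so intercept–slope correlation propagates into the slope margins — the
metric is evaluated on each draw, and the sample standard deviation (n − 1)
is reported. Draws are bit-reproducible for a fixed seed; per-species RNG
streams are keyed on the species name so adding a species never perturbs the
others. For small covariances this SE agrees with the delta-method value
|∇PSM|·Σ·|∇PSM|^{1/2}, with ∇PSM = ((2β1 − β2), (2β2 − β1)) / (3·PSM).
Covariances are symmetrised and eigenvalues in [−1e−10, 0) are clipped to
zero before sampling; genuinely negative eigenvalues are an error. A
degenerate all-zero covariance yields SE exactly 0 and a flagged
(NaN) weight; otherwise the downstream weight is 1/SE².

Direction and significance use two-sided Wald z-tests at α = 0.05
(configurable) on the three contrasts β1, β2 and β1 − β2, uncorrected. A
species is *significant* when any test rejects. Significant species are
classified long-day (short-day) when that treatment's fitted probability is
the strict maximum, and intermediate when the equal-day probability strictly
exceeds both extremes with at least one significantly negative contrast.
The sign attached to the metric is +1 when fitted germination under long
days is at least that under short days, −1 otherwise, so intermediate
species inherit the sign of their larger extreme and exact ties resolve
to +1. The three uncorrected 5% tests bound the family-wise null error rate
at 15%; shrinkage pushes the realised rate lower (≈ 11% in the packaged
calibration at 30 seeds/treatment).

## Inclusion filter

Species are excluded from downstream analysis when germination is below 5%
in **every** treatment, or when fewer than five seeds germinated across the
three treatments combined. Both inequalities are strict — exactly 5% or
exactly five germinants retains the species — and percentages are computed
from counts aggregated per treatment, not per dish. When both rules fire
the all-treatments-low-percent reason is reported. Note the two rules
overlap but neither implies the other: 4/100 in each treatment fails only
the percentage rule; 4/30, 0/30, 0/30 fails only the count rule.

## Association models

One model per predictor (no multiple regression). The continuous response
(the metric, which is non-negative) is fit with a Gamma GLM with log link,
weighted by 1/SE². The Gamma family's canonical reciprocal link is
numerically fragile with inverse-variance weights and an unconstrained
positive mean, so the log link is used. Seed mass enters log10-transformed,
latitude as absolute degrees, and the climber growth form is dropped before
a growth-form fit (rare class). Model-level inference is a likelihood-ratio
chi-square of the predictor model against the intercept-only model with the
same weights, computed as the scaled deviance difference
(D_null − D_full)/φ̂_full with df equal to the number of added parameters;
R² is the deviance pseudo-R², 1 − D_full/D_null, clipped to [0, 1]. Both
are invariant to rescaling all weights by a constant. Exact-zero responses
are incompatible with a Gamma likelihood and raise an error by default; an
explicit `zero_offset` (e.g. 1e−6, added to every response) is available as
a documented opt-in.

The categorical flowering-photoperiodism response is binarised — day-neutral
is insensitive; long-day, short-day and "other photoperiod" are sensitive —
and fit with an ordinary binomial logit GLM on one predictor at a time,
reported with the same pseudo-R²/LRT summary.

## Phylogenetic signal

The trait covariance implied by a rooted tree with branch lengths is
C[i,j] = shared root-to-MRCA path length (the Brownian-motion covariance).
Pagel's λ rescales the off-diagonal of C while keeping the diagonal fixed;
it is estimated by profile maximum likelihood (GLS mean and rate profiled
out in closed form) with bounded scalar search on [0, 1] to 1e−6, and its
p-value is the chi-square(1) upper tail of the likelihood ratio against
λ = 0. The boundary-mixture correction for the null on the edge of the
parameter space is deliberately not applied (matching common practice);
λ > 1 is not attempted because megatree prunes are generally
non-ultrametric. Blomberg's K is the observed MSE₀/MSE ratio — tip
deviations from the GLS (phylogenetically corrected) mean, raw versus
C-weighted — divided by its Brownian expectation
(tr C − n/Σ C⁻¹) / (n − 1); its p-value is one-tailed from random tip
permutations with the add-one rule (1 + #{K_perm ≥ K_obs})/(N + 1), 999
permutations by default. Species measured at multiple sites are averaged
before any tree work. Both statistics were cross-checked against
phytools::phylosig on fixed small trees (agreement to 1e−6 on K and to the
optimizer tolerance on λ).

## Synthetic data

The generator defines the study conditions the tests probe: ~67 species per
study, 6–50 seeds per treatment, collection latitudes 16–36° S (stored as
negative degrees), log10 seed mass ~ N(0.5, 1) mg, LAI ~ U(0, 6), alpine
with probability 0.3, growth forms herb/shrub/tree/climber at
0.40/0.33/0.24/0.03, and flowering categories at the literature mix
45:50:32:8. Germination counts are binomial draws from per-species true
treatment probabilities, whose implied true metric comes from the same
formula applied to logit differences. Trees are pure-birth (Yule)
simulations; because the simulator stops at the instant of the final birth,
every tip is extended by one further exponential waiting time (a common
extension, preserving ultrametricity) so the covariance is nonsingular.
Tip traits are multivariate normal with the λ-transformed tree covariance.

What the generator does *not* emulate: within-dish correlation and dish
effects, dormancy and viability loss, time-to-germination dynamics,
non-ultrametric megatree branch-length noise, and trait measurement error.
Passing calibration on this substrate therefore demonstrates the
correctness and internal calibration of the estimators under the stated
binomial/Brownian models, not robustness to those field realities.

## Problem sizes in the packaged checks

The packaged calibration runs use 500 null species at 30 seeds/treatment
for the false-positive rate, 20 species at 500 seeds/treatment for metric
recovery (MAE < 0.15 logits), 50 replicate 100-tip trees for λ/K recovery,
200 replicate 200-species studies for Gamma-GLM null p-value uniformity,
and 100,000 bootstrap draws for the delta-method comparison. These sizes
give Monte-Carlo error comfortably below each acceptance band.

## Known limitations

* The MAP + curvature summary is not a full posterior; credible intervals
  on the metric are out of scope.
* The Wald classification rule is one reasonable formalisation of
  "significantly day-length responsive"; alternatives (e.g. requiring both
  contrasts for intermediate species) would shift borderline cases.
* Doubly-separated species (all cells 0 or n) produce finite but
  prior-dominated contrasts; their bootstrap SEs are large and their
  weights correspondingly small, which is the intended behaviour.
* The Gamma association model conditions on estimated weights; it does not
  propagate uncertainty in the weights themselves.
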