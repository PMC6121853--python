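# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the test suite does and does not establish.

## Visual model

**Grid.** All spectra are resampled (linear interpolation, no
extrapolation) to a single working grid, 300–750 nm at 1 nm, before any
computation. A single grid removes silent misalignment between
reflectance, irradiance and sensitivity curves; 1 nm is finer than the
structure of any curve involved, so trapezoidal quadrature error is
negligible (the test suite bounds it at 0.1 % against a 10×-finer
reference on smooth spectra).

**Receptor sensitivities.** Measured cone sensitivities are not bundled;
sensitivities are synthesized from the standard A1 visual-pigment nomogram
(α-band rational-exponential template plus the Gaussian β-band,
peak-normalized). The default trichromat uses λmax = 455, 530, 565 nm with
relative densities 1 : 2 : 2 — a plausible configuration for a
shallow-water cichlid, exposed as configuration, not asserted as a species
measurement.

**Noise.** Weber fractions follow ω_i = ν/√η_i. The system noise ν is set
so that the longest-wavelength chromatic receptor has ω = 0.05, the
field's customary anchor value; the luminance channel also uses ω = 0.05.
The luminance channel defaults to the peak-normalized sum of the two
longest-wavelength sensitivities (double-cone convention) and can be
overridden with an explicit receptor.

**Adaptation and signals.** Catches are normalized to an ideal white
(R ≡ 1) under the same illuminant (von Kries). The adaptation reference is
configurable in principle by adapting against any reflectance via the same
machinery; ideal white is the default because no background substrate
spectrum is bundled. Receptor signals are logarithmic, f = ln q, the
appropriate regime for suprathreshold contrasts spanning the black-to-white
intensity range. Catches are clamped at 1e−9 and reflectances at 1e−6
before logs so near-black patches stay finite.

**Chromatic distance.** For n = 2 and n = 3 chromatic channels the
published receptor-noise-limited closed forms are used verbatim. For
general n the implementation minimizes the noise-weighted squared distance
over the achromatic (equal-shift) direction,
ΔS² = min_c Σ_i (Δf_i − c)²/ω_i², which is algebraically identical to the
closed forms at n = 2, 3 (verified in tests against an independent
projection-matrix oracle to 1e−9).

**Light field.** Ambient irradiance at depth follows Beer–Lambert decay
through a diffuse attenuation coefficient K(λ). The synthetic K is
U-shaped with its minimum in the 450–550 nm clear-water window, so light
at depth concentrates where blue structural colors reflect. Default depth
is 10 m. K(λ) is stored in the `transmission` slot of the spectrum
container; for that reason transmission-kind values are not bounded above
by 1 (reflectance and sensitivity are).

## Facial pattern and adjacency

Five patches: black horizontal stripe (the dynamic signal), black vertical
stripe (static reference), white, blue, yellow. The default adjacency map
encodes a face in which the white bands border both black stripes and
blue, and the yellow eye-region patch borders both stripes and blue — in
particular the complementary blue/yellow pair is adjacent, the classic
conspicuousness design of placing opponent colors side by side. The two
black stripes do not touch, and white and yellow sit on opposite sides of
the horizontal stripe, so h–v and white–yellow are the nonadjacent pairs.
This map was chosen over a sketch in which blue and yellow are nonadjacent
because flat black and white patches carry almost no chromatic contrast:
any map that buckets the blue–yellow pair as nonadjacent makes the mean
nonadjacent ΔS exceed the adjacent mean, contradicting the design
principle the adjacency test is meant to detect. The map is a plain
configuration object and can be replaced wholesale.

## Mixed models

All linear mixed models are REML random-intercept models (statsmodels
`MixedLM`). The package adds three pieces on top:

* **Per-term Wald F-tests.** A term's columns are tested jointly with the
  fixed-effect covariance; for variance-component (crossed random
  intercepts) models the fixed-effect covariance is recomputed by GLS from
  the fitted variance components, because the covariance statsmodels
  reports for those models comes from the joint-likelihood Hessian and is
  unreliable near variance boundaries.
* **Containment denominator df.** Effects varying within groups are tested
  against `n_obs − n_groups − p_within`; purely between-group effects
  against `n_groups − p_between`. On the balanced two-rows-per-subject
  designs used here this reproduces the familiar paired-design df (e.g.
  F(1, 9) at 10 subjects).
* **Sequential (type-I) variance partition.** "Percent variance explained"
  is the incremental sum of squares of each fixed term, in the fixed order
  adjacency → stripe → interaction, divided by the total centred SS of the
  (transformed) response. Sequential SS was chosen over alternatives
  because it is exactly reproducible and sums to the total explained by
  the fixed design; on near-orthogonal balanced designs the orderings
  agree.

Achromatic contrasts and bout counts are square-root transformed before
fitting (both are right-skewed; bouts are overdispersed counts); residual
normality is summarized by a Shapiro–Wilk statistic carried in every fit.
Latency is left untransformed by default, with a log option.

**Binomial GLMM.** statsmodels has no frequentist binomial GLMM, so the
random-intercept logit model is fitted by direct maximum likelihood with
21-node Gauss–Hermite quadrature over the group effect; the stripe–outcome
test is a single-df likelihood-ratio test between nested fits. Complete
separation (a predictor that perfectly classifies the outcome, e.g. every
loser pale and every winner dark) is detected up front; the model then
falls back to a bias-reduced (Jeffreys-prior penalized, Firth-type)
logistic fit, flagged in the result.

**Rank tests.** Within-pair size matching uses the paired signed-rank test
(the dyads are matched by construction, so a paired procedure is the
correct choice even where an unpaired test might be named informally);
exact null distribution up to 25 untied pairs, normal approximation with
continuity correction beyond. Per-patch-pair contrast changes between
stripe states use two-sided Mann–Whitney tests with Benjamini–Hochberg
adjustment, the FDR family being the set of pair types within one contrast
kind (chromatic or achromatic), matching the per-panel flagging
convention.

**Post-hoc treatment contrasts.** The three pairwise treatment comparisons
(darkened–control, paled–control, darkened–paled) are tested single-step:
each statistic is a fitted-contrast t ratio (marginal over sex, equal
weights), and adjusted p-values come from the joint multivariate *t*
distribution of the three statistics with the treatment term's containment
denominator df. A plain normal (z) reference was measured to be liberal at
the study's ~24 subjects (familywise error ≈ 0.10 at nominal 0.05); the
multivariate-t single-step keeps the simulated familywise error within
binomial error of nominal, which the acceptance suite checks over 500 null
replicates. The CDF integrator is quasi-Monte Carlo and runs with a fixed
internal seed so results are bit-reproducible.

## Synthetic study conditions

The generator's defaults are the study conditions everything is tested
under; they are synthetic values chosen to mirror the qualitative
structure of the system being emulated, not measurements.

| parameter | default | rationale |
|---|---|---|
| spectra fish per state | 10 | small spectral sample typical of such studies |
| contest dyads | 20 | typical staged-contest sample |
| mirror-trial fish | 24 | two trials each → 48 trials |
| stripe reflectance dark / pale | 0.04 / 0.30 | melanic black ≈ 4 %; paling raises reflectance several-fold |
| white / blue / yellow | 0.80 flat (slight warm tilt) / Gaussian at 470 nm / long-pass at 520 nm | broadband reflector, structural blue, carotenoid-like yellow |
| spectral noise | smooth multiplicative, sd 0.05 | between-individual + measurement variation |
| size→win logit slope | 6 per cm | larger fish reliably wins at matching tightness 0.25 cm |
| paling probability loser / winner | 0.9 / 0.1 | losers pale, winners mostly stay dark |
| bout multipliers control/paled/darkened | 1.0 / 1.5 / 2.6 | both cheating directions punished, bluffing hardest |
| latency multipliers darkened/paled | 1/1.7 / 1/1.2 | faster attack on stronger signals |
| bouts distribution | Poisson-lognormal, individual sd 0.3 | overdispersion that motivates the sqrt transform |
| trial duration | 600 s | latency right-censoring point |

Bout counts are Poisson-lognormal rather than plain Poisson so that the
square-root transform the model applies has real work to do. Censored
latencies (no attack within the trial) are excluded from latency models
and latency fold-effect means but always counted and reported; bout
outputs never depend on censoring. Fold-effect confidence intervals use a
percentile bootstrap resampling fish (clusters), 2000 draws, seeded.

Determinism: every generated entity draws from a generator seeded by the
config seed plus a stable hash of its identity (fish, state, patch…), so
datasets are bit-reproducible and insensitive to generation order.

**What the generator does not emulate:** realistic spectral shapes beyond
the qualitative classes above (no measured reflectance library), ocular
media transmission (hook present, default off), sex differences (none are
generated, so sex terms in the models are true nulls), behavioral
dependence between the two fish of a dyad beyond the winner/loser rate
asymmetry, and any within-trial time structure of aggression. Passing
tests therefore demonstrate that the machinery is correct and calibrated
under the assumed structure — not that real measurements would show these
effect sizes.

## Degenerate inputs and tie-breaks

* Identical spectra in a pair → ΔS = ΔL = 0 exactly.
* A fish/state cell missing an adjacency category is dropped from
  aggregation with a warning.
* All-zero within-pair differences → matching test reports p = 1.
* Noise-free mirror trials (all responses equal) → post-hoc z = 0,
  adjusted p = 1 rather than 0/0.
* Rank tests with fewer than 2 observations per group are skipped with a
  warning.
* A treatment level absent from trial data raises an error naming it.

## Problem sizes in the checked runs

The acceptance script runs the pipeline at the default study conditions
above. Calibration tests in the suite use 500 null replicates per
inferential path (20 fish / 20 pairs / 24 fish respectively) and recovery
tests use 200 replicates at n = 20 fish, one run at 500 mirror-trial fish,
and one run at 1000 dyads — sizes at which the checked tolerances are
comfortably identifiable.

## Known limitations

* Denominator df use containment; software using Satterthwaite or
  Kenward–Roger approximations will report slightly different df (and
  p-values) on unbalanced designs such as the two-of-three trial
  assignment.
* The variance-explained percentages depend on the sequential term order
  (adjacency first); this is a documented convention, not an estimate of
  unique contributions.
* The binomial GLMM's pair random intercept is weakly identified when each
  pair contributes exactly one winner and one loser; the likelihood-ratio
  test for the stripe term remains calibrated (checked by simulation), but
  the variance estimate itself should not be interpreted.
* Winner determination is an input label, not modeled; stripe intensity is
  a binary by-eye category, not a continuous measurement.
* No spatial pattern metrics: adjacency is a pairwise relation, patches
  are given, and viewing distance, acuity and pattern geometry are out of
  scope.
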