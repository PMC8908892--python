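# Methods

This note documents the statistical models, numerical choices and known
limitations of `raylife`. It describes what the code computes; every number
quoted as an outcome here is produced by the test suite or the acceptance
script, not asserted independently.

## Growth model

Disc width (DW, cm) at vertebral age t (years, integer band counts; "less
than one year" is age 0 exactly) follows one of three families parameterised
by the asymptotic disc width DW∞, the size at birth DW_birth and the growth
coefficient k (yr⁻¹). All three satisfy DW(0) = DW_birth and DW(t) → DW∞.
The von Bertalanffy curve is used in its size-at-birth form,
DW_birth + (DW∞ − DW_birth)(1 − e^(−kt)): the increment to the asymptote
enters with a positive sign, which is the standard increasing form (the
alternative sign convention produces a curve that shrinks with age and is
inconsistent with a fitted asymptote above the birth size).

Observations are modelled as DW_i ~ Normal(DW(t_i), σ) i.i.d., with σ (cm)
estimated jointly. A Gaussian error on the measurement scale is the simplest
model consistent with continuous disc-width data and yields the pointwise
log-likelihood matrix that PSIS-LOO requires. Sexes are pooled by default;
the fitting functions accept any observation subset for stratified runs.

Priors (weakly informative, centred on the literature values for the
species): DW_birth ~ lognormal(ln 10, 1), DW∞ ~ lognormal(ln 34, 1),
k ~ lognormal(−1, 1) — i.e. a normal(−1, 1) on ln k, keeping k positive with
a median of e⁻¹ ≈ 0.37 yr⁻¹ — and σ ~ half-normal(0, 5 cm). Draws with
DW∞ ≤ DW_birth receive zero posterior mass.

## Sampler

Parameters are sampled by adaptive Gaussian random-walk Metropolis on the
unconstrained scale (positive parameters log-transformed, with the Jacobian
term included). Four chains of 3,500 iterations each discard 1,000 warm-up
draws, retaining 10,000 draws total. During warm-up only:

- the global step scale is multiplied by exp(rate − 0.3) every 50 iterations,
  chasing a ~0.3 acceptance rate;
- from the warm-up midpoint, the proposal covariance is re-estimated every
  window from the warm-up draws after the first quarter (which absorbs the
  transient), with a 1e−10 ridge; when the covariance first replaces the
  initial diagonal, the scale is re-baselined to 2.38/√d.

After warm-up the proposal is frozen, so retained draws form a genuine
Markov chain. Chain seeds are spawned from the config seed
(`numpy.random.SeedSequence`), making every fit bit-reproducible. A warm-up
with zero acceptances raises a diagnostic error rather than returning an
unusable chain.

Convergence is summarised by split-chain R-hat and an autocorrelation-based
ESS (both via ArviZ; ESS is capped at the retained draw count, and constant
chains are flagged rather than crashing). Posterior summaries are medians
with equal-tailed 95% credible intervals. With the default protocol the
growth fits typically show R-hat ≲ 1.01 and ESS of a few hundred per
parameter, which is ample for median/interval summaries; a longer chain
protocol can be configured where more is wanted.

## Model comparison

PSIS-LOO is computed from the retained pointwise log-likelihood matrix
(ArviZ implementation of Pareto-smoothed importance sampling), reported as
LOOIC = −2·elpd_loo with SE equal to twice the elpd standard error, and
per-observation Pareto-k diagnostics (k > 0.7 flagged). Models are ranked by
LOOIC; when every pairwise |ΔLOOIC| < 2 the comparison is flagged
"indistinguishable" — differences below two deviance units are not reliable
evidence of different predictive ability. The implementation is checked
against brute-force exact leave-one-out refits on a conjugate toy model.

## Maturity ogive

Binary maturity (pre-coded from gonad inspection; "unknown" records are
excluded) is modelled as Bernoulli with logit P = a + b·DW and priors
normal(10, 5) on both a and b. This prior location is positive while fitted
intercepts for increasing ogives are negative; with n in the tens the
likelihood dominates and the prior acts only as mild regularisation, so the
stated prior is kept as-is. DW50 = −a/b is evaluated per retained draw; the
reported point estimate is the posterior median of those draws and the
interval the draw-wise 2.5/97.5 percentiles, which propagates the posterior
correlation of (a, b). The alternative point estimate −median(a)/median(b)
is exposed separately and may differ slightly. Male, female and combined
strata are fitted independently (distinct derived seeds). Age-at-maturity
inverts the selected growth curve at DW50 in closed form.

## Diet

Life stages: YOY (age < 1), adult (mature and DW ≥ DW50, ties to adult),
juvenile otherwise; unaged specimens are never classified YOY. Six fixed
prey groups are used throughout; "unidentified" is retained as a group.

%W_a for a prey group is the per-stomach percentage of predator body mass
(100·W_a/W_body) averaged over stomachs containing food — the formula is
defined per individual, so averaging individual percentages is the default
aggregation; a pooled alternative (100·ΣW_a/ΣW_body) is available. %F_a is
the percentage of food-containing stomachs with the group. HI_a = %F_a + %W_a
and IOI_a = 100·HI_a/ΣHI, so IOI sums to 100 within each stratum by
construction; strata with only empty stomachs are skipped with a warning.

PERMANOVA partitions squared Bray–Curtis dissimilarities between per-stomach
mass-proportion profiles (one-way design): SS_total = Σ_{i<j} d²_{ij}/n,
SS_within summed per group over group size, pseudo-F = (SS_b/(g−1)) /
(SS_w/(n−g)). The p-value uses seeded label permutations with the add-one
rule p = (#{F* ≥ F} + 1)/(n_perm + 1), so 999 permutations give a floor of
0.001. The response (mass, count, presence) and distance (Bray–Curtis,
Euclidean) are configurable because the published analyses of this kind
rarely state them; mass proportions with Bray–Curtis are the vegan-style
default. Pairwise tests run on each pair's sub-matrix in lexicographic order
and report raw and Holm-adjusted p-values (reported raw p-values in the
field suggest no adjustment, so both are given).

## Synthetic data generator

The generator emulates a ~71-specimen coastal whipray study: integer ages
0–7 from a truncated-geometric distribution calibrated to mean 1.8 years
(young-heavy sampling); disc widths from the true growth curve plus
Normal(0, σ = 1.5 cm) noise, floored at 1 cm (with the default curve the
floor is never active); a 1:1 sex ratio; Bernoulli maturity from sex-specific
ogives (male a = −19.25, b = 0.95; female a = −13.64, b = 0.56); body mass
from a fitted allometry mass ≈ 0.016·DW^3.28 g with 10% lognormal noise,
spanning roughly 59–1,200 g over 12–31 cm; and stomach contents drawn per
stage and group as Bernoulli occurrence, Gamma mass and 1+negative-binomial
count. Occurrence probabilities and the crustacean/polychaete mass and count
means are calibrated to the per-stage stomach summaries of the motivating
study (e.g. adult crustacean occurrence 23/24); the remaining groups use
plausible soft-bottom values chosen once. Profiles differ by stage, so an
ontogenetic shift exists by construction.

What the generator does not emulate: spatial structure among sampling sites
(locations are labels), ageing error in band counts, sex differences in
growth, digestion-state biases in prey masses, and correlations between
stomach fullness and body size. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those field realities.

## Problem sizes and test design

Recovery checks use the study-scale design throughout: n = 71 size-at-age
observations per replicate (20 replicates per growth family), n = 35 for
male-ogive DW50 recovery, and the default 4 × 3,500 chain protocol.
PERMANOVA calibration uses 200 null replicates of 24 stomachs at 199
permutations; the p-floor check uses 999. The LOOIC-equivalence property is
evaluated over five seeds with all three families fitted per seed.

## Known limitations

- The sampler is random-walk Metropolis, not HMC/NUTS; for these low-
  dimensional posteriors that is adequate but less efficient per draw.
- With a single old specimen in a young-heavy design, DW∞ for slow-asymptote
  families (von Bertalanffy) is weakly identified; its wide credible
  intervals are a faithful reflection, not a defect.
- DW50 draw-wise ratios are unstable if the slope posterior crosses zero;
  with informative data (both classes present across sizes) this does not
  occur, and single-class data are rejected outright.
- The IOI depends on the %W aggregation convention when body masses vary
  strongly; both conventions are implemented and the choice is recorded in
  the run log via the config hash.
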