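# Methods

This package re-implements, as tested and reusable code, the statistical
chain used to establish that a candidate gene underlies a quantitative trait
locus (QTL): simulation of the segregating populations, mixed-model trait
adjustment, the quantitative complementation test, F2 group comparisons,
relative expression quantification by 2^-ddCt, and the four-component causal
inference test (CIT) linking genotype, expression and trait.  No per-animal
data from the motivating study are published, so a synthetic-data module is
a first-class component: it generates cohorts with the genetic, covariate
and mediation structure the analyses assume, and every operating
characteristic reported here is computed from those simulations at run time.

## Generative model

Two cross designs are simulated.

**Four-way cross** (default n = 352, 44 litters). Each animal draws one
allele at the knockout (KO) locus (`KO` or `B6J`, probability 1/2) from one
F1 parent and one at the QTL locus (`SR` or `B6JJcl`, probability 1/2) from
the other, independently — no linkage is modelled because the two loci enter
from different sides of the cross. The focal fat trait is

    T = mu_t + b_ko·KO + b_qtl·QTL + b_int·KO·QTL + covariates + litter + e

with `KO`, `QTL` indicator-coded. A nonzero `b_int` is the
"same locus" (failure-to-complement) scenario.

**F2 intercross** (default n = 108, 14 litters). Knockout copies are drawn
1:2:1. With `g` the functional-allele dose (2 − KO copies), expression and
the focal trait follow one of four topologies:

* causal:       `E = mu_e + b_ge·g + litter + e`, `T = mu_t + b_et·E + covariates + litter + e`
* independent:  `E` as above, `T = mu_t + b_gt·g + covariates + litter + e`
* reactive:     `T` first (direct genotype effect), then `E = 1 + b_et·(T − E[T]) + litter + e`
* null:         no genetic effect anywhere.

Litter random intercepts (SD `sigma_litter`) are drawn independently for E
and T; other traits receive litter effects scaled to keep the same
litter-to-residual SD ratio. Body weights follow a population growth curve
(ages 1–16 weeks) with an animal-level scale factor and a male shift; organ
and fat traits regress on 16-week body weight with trait-specific slopes.
Gaussian noise acts on the measurement scale and weights are truncated at
zero. Litters are filled sequentially with sizes drawn uniformly from the
design range (the last litter may be truncated; the realized size is the
recorded covariate); parity is uniform per litter; the reciprocal-cross
direction is recorded but has no effect, matching the absence of
genotype-by-sex interactions in the motivating data.

Default effect sizes are calibration choices, not published facts: they are
set so that, in the two-genotype comparison the causal analysis uses, the
expression ratio is ≈ 2.1, the focal fat difference ≈ 0.35 g and the
population R² of trait on expression ≈ 0.29 — the regime the published group
means and R² imply (`b_ge = 1.13`, `b_et = −0.31`, `sigma_e = 0.30`,
`sigma_t = 0.31`, `sigma_litter = 0.10`, `mu_t = 2.726`). Under the
knockout-homozygous genotype the linear expression model goes slightly
negative; raw values are kept in the cohort (the linearity is what the
closed-form checks test) and a detection floor of 0.02 fold is applied only
when a cohort is fed to the Ct-panel simulator, whose log2 transform needs
positive input.

One master seed drives named `SeedSequence` sub-streams (structure,
genotype, body weight, expression, traits, qPCR), so cohorts are
reproducible field-for-field and individual stages can be perturbed
independently.

## Trait adjustment

Analyses never run on raw traits. Each trait is residualized on the
environmental fixed effects retained by backward elimination — parity
(categorical), litter size (continuous), their interaction — plus a litter
random intercept, fit by REML (`statsmodels MixedLM`). Backward elimination
drops the least significant term with Wald P ≥ 0.05, interactions before
main effects; a main effect is protected while a retained interaction
contains it. Term significance uses Wald chi-square tests on coefficient
blocks of the REML fit. The "adjusted" variant of a trait additionally
includes body weight at dissection (16 weeks) as a covariate in the same
final model. Residuals are observation minus fixed-effect prediction minus
the litter BLUP, centred to overall mean zero; they are exactly orthogonal
to the retained design columns (the conditional residual of a random-
intercept model is `sigma_e^2 V^{-1}` times the marginal residual).

Numerical care: the REML surface is optimized with both lbfgs and Powell and
the higher restricted likelihood wins, because lbfgs can stall on the
variance boundary and report convergence. If the litter variance estimate
collapses below 1e-6 of the residual variance (or the fit fails), the model
falls back to fixed-effects-only OLS with a warning — in that regime the two
estimators coincide. A single-litter design raises a degenerate-design
error. Missing trait values propagate as missing; they are never dropped
across traits.

Residualize-then-test is a deliberate two-stage choice (it mirrors the
source workflow and keeps every downstream test a pure function of one
column); it forfeits a little efficiency relative to one joint model per
test, and P values downstream do not account for the adjustment step.

## Group tests

One-way ANOVA is the classical between/within decomposition; with no
covariates the least-squares group means are raw means with pooled-variance
standard errors. Tukey HSD uses the studentized range distribution with the
Tukey–Kramer correction for unequal n; the compact letter display is the
insert-and-absorb algorithm, so two genotypes share a letter iff their
pairwise P ≥ alpha. MANOVA (via `statsmodels`) reports Wilks' lambda,
Pillai's trace, the Hotelling–Lawley trace and Roy's greatest root with
their standard F approximations (Rao's for Wilks; Roy's as an upper-bound
F). With a single response all four statistics collapse to the univariate F
test, implemented as an explicit reduction (the single eigenvalue is
SSH/SSE). Collinear responses are rejected up front with the offending pair
named, rather than silently pseudo-inverted. A summary layer reports both
"any of the four statistics significant" — the permissive reading used when
screening trait groups — and "all four".

Traits are organised into eight groups for the multivariate screens: body
weight, weight gain, body length, organ weight, fat-pad weight, and
body-weight-adjusted variants of the last three. Composite totals (total
fat, total body length) and the male-only trait stay outside the groups and
are tested per trait.

## Quantitative complementation test

The two-way factorial ANOVA fits `trait ~ KO * QTL` (optionally crossed
with sex) on adjusted values with sum-to-zero contrasts and marginal
(Type III) sums of squares, so unbalanced cells are handled; every term's F
equals a nested-model residual-SS comparison, which the tests verify to
1e-9. Cell least-squares means average the prediction evenly over sex
levels, with delta-method standard errors. The call is deterministic:
interaction P < alpha (default 0.05) is *failure to complement* — the
knocked-out locus behaves as the QTL; otherwise *complement*, flagged
marginal when P ≤ 0.10. Sexes are pooled per trait group only when a MANOVA
screen finds no KO-by-QTL-by-sex interaction on any of the four statistics.
An empty genotype cell raises an inestimable-interaction error.

## Relative expression (2^-ddCt)

Replicate Cts are averaged per (sample, gene); dCt = Ct_target −
Ct_control; per-sample fold = `2^-(dCt − dCt_ref)` with the calibrator
group's mean dCt as reference, then rescaled by the calibrator group's
arithmetic mean so that group's mean is exactly 1 while per-sample variation
(hence a nonzero SEM) survives. Whether the published calibrator value of 1
is an arithmetic or geometric mean is not stated anywhere; the arithmetic
convention is a declared design choice, and a classic single-reference-
sample convention is available as an option. Replicate aggregation is the
arithmetic mean of Ct; no outlier rejection and no amplification-efficiency
(Pfaffl) correction. The simulated instrument is the exact inverse
(target Ct = baseline − log2(expression) + noise), so a zero-noise round
trip recovers expression ratios to 1e-9.

## Causal inference test

For genotype G (coded 0/1 across the two informative genotypes), expression
E and trait T — all litter-residualized first; whether litter should instead
enter the component models as a term is ambiguous in the source description,
and residualization was chosen for consistency with the adjustment stage —
the four component tests are plain coefficient t-tests in three OLS fits:

1. G in `T ~ G`
2. G in `E ~ G + T`
3. E in `T ~ E + G`
4. G in `T ~ E + G` (same fitted model as test 3)

`causal` requires tests 1–3 significant and test 4 *non*-significant at
alpha = 0.05; a test-3 P in (0.05, 0.10] downgrades to `causal_marginal`.
Test 4 is accept-the-null logic: at low power it favours a causal call, which
is why the false-causal rate is monitored by simulation. The unconditional
`E ~ G` P value is reported alongside for the expression row of the summary
table. More than two genotype levels are rejected unless the caller
supplies a numeric coding; constant or mutually collinear inputs raise
degenerate-fit errors (condition-number guard at 1e9). R² is the squared
Pearson correlation of E and T, reported with the slope sign.

This plain conditional-regression form is what reproduces the published
decision table. The original CIT literature's intersection-union omnibus P
and equivalence-test form of test 4 are intentionally out of scope here.

## Operating characteristics (computed, not asserted)

The calibration harness estimates, by replicated simulation with spawned
seeds: the type-I rate of the complementation call under a null four-way
cross (n = 352, nominally 0.05); the false-causal rate of the CIT
conjunction under the independent topology at n = 12 + 12 (conservative,
below alpha); and the power of the causal call in the default regime
(expression ratio ≈ 2, population R² ≈ 0.29, n = 12 + 12) — around 0.2–0.3,
i.e. the published design sits in a low-power regime for the full
conjunction, consistent with its borderline test-3 P values. The acceptance
suite runs 1000 replicates for the two error rates; analysis drivers report
300-replicate versions.

## Problem sizes and limitations

Unit tests use 30–60 replicates for selection/recovery checks and smaller
cohorts (n = 120–400) than the full designs; the acceptance suite uses the
full n = 352 and n = 24 designs. Known limitations: Gaussian noise only; no
genotype-by-sex effects; no linkage, dominance or epistasis beyond the
two-locus factorial; litter effects are exchangeable random intercepts (no
maternal covariates); REML variance components at these litter counts carry
~30% relative error; and passing tests on synthetic cohorts show the
machinery is correct under its own assumptions, not that real data meet
them.
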