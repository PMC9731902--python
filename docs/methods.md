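# Methods

This note documents the statistical procedures, the conventions that were
genuinely open choices, the synthetic-data generator, and the limits of what
the test suite demonstrates.

## Left-censored data

A nondetect is an observation known only to lie below its sample-specific
method reporting limit (MRL); in the data model it is stored *at* the MRL
with a censoring flag. Two laboratories with different MRL schedules induce
two censoring "dialects"; all members of a household are analyzed by the
same laboratory, so censoring is household-consistent.

### Kaplan–Meier descriptives (`censored_stats`)

Left-censored concentrations are flipped to right-censored survival times
`z = K − x` with `K = (1 + 1e-9)·max(x)`, the product-limit estimator is
fitted (via lifelines), and summaries are back-transformed. Conventions,
fixed in advance rather than matched to any published table:

- **Restricted mean.** If the smallest observation is censored the survival
  curve never reaches zero; integration is truncated at the largest flipped
  observation. This places the unresolved mass at the smallest censoring
  limit and biases the mean upward by at most (residual mass) × (that
  limit). The estimated mean is invariant to K (tested).
- **SD** from the restricted second moment `∫2zS(z)dz`; with no censoring
  this reduces to the denominator-n SD.
- **Median**: smallest concentration where the back-transformed CDF reaches
  0.5 — a deterministic step-function (type-1) convention, chosen because it
  is exactly checkable against an enumeration oracle. A 1e-10 tolerance on
  the 0.5 comparison absorbs float error accumulated in the survival
  products.
- **Upper percentiles** (95th, 99th) are empirical quantiles with nondetects
  substituted at their MRLs (numpy linear interpolation, type 7), since the
  product-limit curve carries no information above the largest detect. They
  are flagged invalid when the requested level does not exceed the censoring
  fraction.

### Censored Kendall τ_b (`correlation`)

The point estimate is deterministic concordance counting: a comparison
between pairs i and j is determinate in a margin when both values are
detects (ordered by value), or when one is censored at limit L and the other
detected at y ≥ L (censored < detected). Two censored values are always
indeterminate, regardless of their limits — values known only to lie below
their limits are unordered. Indeterminate comparisons count as ties in the
τ_b denominator `sqrt((n0 − t_x)(n0 − t_y))`.

A consequence worth knowing: censoring monotonically shrinks the *net
concordance count* |C − D|, but not necessarily τ_b itself, because the tie
correction shrinks the denominator at the same time. The property test
asserts the former.

The bootstrap resamples pairs jointly. Within each replicate, censored
entries are imputed from the below-limit tail of a lognormal fitted once to
each margin by censored maximum likelihood — the one place a lognormal
assumption can act on a rank statistic, and what breaks the artificial ties
censoring creates. A pure concordance bootstrap is available via
`impute=False`. Intervals are percentile (not BCa); the p-value is the
two-sided sign-crossing proportion `2·min(#{τ*≤0}, #{τ*≥0})/B`, floored at
1/B and capped at 1. Type-I error at nominal 0.05 is verified by simulation
to land inside the binomial band (0.031, 0.069) at n = 50 pairs, B = 999,
500 null replicates.

## Behavior similarity (`similarity`)

For one behavior, pairs fall into both-yes (a) / only-member-1 (b) /
only-member-2 (c) / neither (d). J = a/(a+b+c) is centered by its *exact*
expectation under the fixed-margins permutation null: a* is
Hypergeometric(n, m1, m2) and `E[J] = Σ P(a*)·a*/(m1+m2−a*)` (J := 0 when
m1+m2 = 0). The analytic expectation was chosen over Monte-Carlo because it
is deterministic and checkable against full enumeration (exact to 1e-12 for
n ≤ 7). The bootstrap resamples pairs and re-centers each replicate on its
own margins, because the centered statistic is the estimand. Pairs — not
participants — are the resampling unit; households contributing several
pairs induce mild between-pair dependence that the intervals ignore (the
same caveat applies to the correlation bootstrap).

Behaviors with fewer than 10 users or fewer than 10 non-users (counted over
participants entering the pair analysis) are excluded from the similarity
table by default; both thresholds are inclusive at exactly 10.

## Hierarchical contribution model (`contribution`)

Expected concentrations add on the concentration scale (sources contribute
mass, not log-mass):

    M_j = H_h(j) + Σ_k β_k X_jk + Σ_k γ_k S_jk    shared-home participant
    M_j = b0     + Σ_k β_k X_jk                   singleton

- `X_jk ∈ {0,1}`: participant j reports predictor behavior k (the predictor
  set is chemical-specific, from a priori source hypotheses).
- `S_jk`: number of *other* household members reporting k, capped at 5, and
  counted only over co-resident study participants. A count (rather than an
  any-use indicator) is the default; coefficients are per reporting
  housemate.
- `H_h = exp(μ_H + σ_H z_h)`, `z_h ~ N(0,1)` non-centered: the lognormal
  household background. The single shared-home intercept is the hyper-median
  `exp(μ_H)`; singletons get their own intercept b0. This placement of the
  intercept relative to the household random variable is one reconstruction
  among several possible; it is isolated behind the model configuration.
- Observation model: `log y_j ~ Normal(log M_j − σ_g²/2, σ_g)` so that M_j
  is the arithmetic mean; σ_g is separate for the shared-home and singleton
  groups. Nondetects contribute `Φ((log MRL_j − log M_j + σ_g²/2)/σ_g)` to
  the likelihood (verified against numerical quadrature to 1e-6 relative).
- β_k, γ_k ≥ 0 by construction (log-parameterization): contributions add on
  the concentration scale, so negative contributions are excluded by the
  model's semantics.

Priors (weakly informative, scale-aware, all configurable):
`β_k, γ_k ~ HalfNormal(τ)` with τ the chemical's detect median;
`μ_H, log b0 ~ Normal(log median detect, 2)`; `σ_H, σ_shared, σ_singleton ~
HalfNormal(1)`.

Participants with wholly missing surveys are imputed as non-users (count
reported) by default; `drop_missing_survey=True` excludes them instead.

### Sampling

No-U-Turn sampling (Hoffman & Gelman 2014, Algorithm 6) over the
unconstrained parameterization, with hand-derived analytic gradients
(verified against finite differences), dual-averaging step-size adaptation
targeting 0.8 acceptance, and a diagonal mass matrix estimated from a
Welford window over the middle of warmup. Defaults: 4 chains × 1,000
post-warmup draws. A fit fails loudly when split-R̂ of any contribution
fraction exceeds 1.01, its bulk ESS falls below 400, or divergences exceed
0.5% of draws (arviz diagnostics); `check=False` returns the draws with
diagnostics attached instead of raising, which the replicated simulation
studies use. The sampler itself is validated on correlated and ill-scaled
Gaussian targets and by a prior-pushforward test (a prior-only run must
reproduce directly forward-sampled prior fraction quantiles).

### Estimand

Per posterior draw, over shared-home participants j:
`T_personal = Σ_j Σ_k β_k X_jk`, `T_others = Σ_j Σ_k γ_k S_jk`,
`T_household = Σ_j H_h(j)`; each fraction is its T over the sum of the
three. This ratio-of-totals form is deterministic per draw and sums to one
exactly. The generator records ground-truth fractions with the identical
formula, so recovery comparisons are exact.

## Synthetic cohort generator (`simulate`)

Emulates the structure of a crowdsourced biomonitoring cohort: 82 shared
homes at the observed size mix (82% two-member, 11% three-member, a few
larger, renormalized over sizes 2–6) plus 541 singleton participants; a
quarter of multi-member homes multigenerational; two labs with distinct MRL
schedules (~55/45 split); kit returns within a 0–7 day household span;
optionally a fraction of participants with wholly missing surveys (25% at
the study-scale default).

Behavior concordance within a household uses a shared logit offset: each
household shifts the behavior's logit by ±log(ω)/2, so ω = 1 gives
independent responses and concordance rises monotonically in ω (tested on
1,000 pairs). Concentrations are drawn from exactly the model's generative
structure, then censored at the lab's MRL. The lognormal "arithmetic mean"
parameterization uses log-median = log M − σ²/2. The singleton intercept
defaults to the mean household background `exp(μ_H + σ_H²/2)`.

The ten-chemical default catalog spans the three source regimes — parabens
and triclosan personal-dominant, benzophenone-3 with a noticeable
others'-behavior share, dichlorophenols and bisphenols household-dominant —
with concentration scales in the ng/ml range typical of urinary
biomonitoring.

What the generator does **not** emulate: creatinine/dilution variation,
temporal behavior drift between the two collected voids, measurement-batch
effects beyond the MRL dialects, survey misreporting, and inter-lab
quantitation bias. Passing recovery tests therefore demonstrate the
estimators are correct *under the model's own assumptions*, not that real
cohorts satisfy those assumptions.

## Problem sizes and replication choices

Simulation studies use sizes at which the checks are informative while the
whole suite stays comfortably re-runnable on one CPU: bootstrap calibration
at 500 null replicates × 999 resamples; hierarchical-model recovery at 20
replicates of 80 households + 200 singletons with 2 chains × 500 draws
(500 warmup) — truth fractions near (0.7, 0.1, 0.2) are recovered with
posterior medians within ±0.15 in 20/20 replicates and 90% CrI coverage of
0.90 at these settings. The degenerate all-household check runs at the full
study scale (82 homes + 541 singletons), where the weakly-informative
half-normal priors on β and γ leave under 10% soft-identified mass in the
behavior components.

## Known limitations

- The "others" fraction γ is the most weakly identified component: housemate
  counts S are correlated with household identity, so γ competes with H_h.
  Its posterior retains noticeable prior mass in small cohorts.
- The restricted-mean convention biases the Kaplan–Meier mean upward when
  the smallest observation is censored.
- Bootstrap intervals treat pairs as exchangeable; households contributing
  multiple pairs violate this mildly.
- Pair-type stratification relies on exact return dates; real studies that
  infer collection dates from shipping add dating error the pipeline does
  not model.
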