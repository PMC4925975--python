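# Methods

## The simulation model

`difpower` studies the operating characteristics of the ordinal-logistic-
regression (OLR) likelihood-ratio test for differential item functioning
(DIF) on a 10-item rating scale. Everything is synthetic; one run of the
pipeline is:

1. **Item bank.** Each item *i* gets a discrimination *aᵢ* drawn i.i.d.
   Uniform(0.5, 1.5) and, for a *J*-category item, *J* − 1 thresholds
   obtained by sorting *J* − 1 i.i.d. N(0, 1) draws ascending. A
   *J*-category graded response model (GRM) has *J* − 1 free thresholds
   because the probability of scoring in or above the bottom category is
   identically 1. Sorting is the minimal way to enforce the ordering the
   GRM requires; it is distributionally equivalent to redrawing until
   ordered and keeps the marginal law of the threshold set standard
   normal.

2. **Latent traits.** Reference and focal groups draw θ i.i.d. from one of
   nine condition pairs: N(0, 1), or Beta(α, β) with
   (α, β) ∈ {(1,4), (0.5,4), (4,1), (4,0.5)}, standardized to mean 0 and
   variance 1 via the affine map (x − μ)/σ with μ = α/(α+β) and
   σ² = αβ/((α+β)²(α+β+1)). Standardization preserves the shape (the
   skewness of Beta(0.5, 4) is +1.79, of Beta(4, 0.5) −1.79) while
   placing θ on the same scale as the N(0, 1) thresholds; using raw (0, 1)
   beta draws would confound skewness with a change of location and scale.
   The nine pairs cover identical distributions (normal, moderately
   skewed, highly skewed), normal-versus-skewed, and opposite skews.

3. **Uniform DIF.** One designated item (item 1 by default; item identity
   is exchangeable because parameters are random) has every threshold
   shifted by a signed constant δ ∈ {−0.5, +0.5, +1} in the focal group's
   bank. A uniform shift preserves threshold ordering and moves the
   expected item score down (δ > 0) or up (δ < 0) by the same mechanism at
   every trait level.

4. **Responses.** For each subject and item, a category is drawn from the
   GRM probabilities at the subject's θ using the subject's group bank.
   The draw uses one uniform variate per (subject, item) against the
   decreasing cumulative probabilities, which reproduces the categorical
   distribution exactly.

5. **Testing.** Each item is tested with three nested cumulative-logit
   models — logit P(Y ≤ k) = α_k + β₁θ (+ β₂g) (+ β₃gθ) — where θ is the
   subject's **total score** over all 10 items and g ∈ {0, 1}. Twice the
   log-likelihood differences are referred to χ²₁: Models 1–2 for uniform
   DIF, Models 2–3 for nonuniform DIF. Both statistics are always
   computed; the grid summaries use the uniform test, matching the
   simulated DIF type.

6. **Summaries.** Power is the fraction of replications in which the DIF
   item's uniform test rejects at α = 0.05. Type-I error pools rejections
   of the nine DIF-free items over all replications (9 × n_reps tests);
   pooling uses all available information, and a per-item breakdown can be
   recovered from the streamed per-replication results. Monte-Carlo
   standard errors are √(p(1−p)/n) on the respective denominators.

## Design choices

**Matching score.** The models condition on the observed total score
including the studied item (`matching="total"`, the default), with
`"rest"` available. Total-score matching is the classical operational
choice and is what produces the characteristic score-contamination
signature the grid shows: under a DIF-free design the pooled null-item
rate sits at the nominal level (checked in the test suite at condition 1,
DIF = 0), while a +0.5 shift on one item nudges it to ≈ 0.06 and a +1
shift with skew-mismatched groups inflates it to ≈ 0.15 (both recomputed
by the acceptance script), because the DIF item leaks into every other
item's matching variable.

**Item-parameter lifetime.** By default a fresh item bank is drawn for
every replication (`bank_lifetime="per_replication"`), so a cell's power
estimate is the marginal power over the item-parameter distribution.
Conditional-on-bank power is strongly dispersed — the test suite verifies
that the same design cell moves by more than ten power points across a
handful of random banks, driven mostly by the DIF item's discrimination —
so a fixed-bank estimate is a property of one arbitrary instrument rather
than of the design.
`bank_lifetime="fixed"` (one bank per category count and master seed) is
retained for studying exactly that conditional behaviour.

**Proportional-odds fitter.** Implemented in-package: damped Newton ascent
on the exact multinomial log-likelihood with analytic gradient and
Hessian, step-halving to enforce monotone ascent and ordered cut-points, a
ridge fallback when the Hessian is not negative definite, convergence at
gradient max-norm < 10⁻⁸ or log-likelihood change < 10⁻¹⁰, iteration cap
200. Nested models are warm-started from the smaller fit padded with a
zero, which makes nested log-likelihood monotonicity hold to numerical
precision in practice; a materially negative LRT (> 10⁻⁶) marks the item's
result invalid rather than being clamped silently. Unobserved categories
are collapsed (only observed cuts are parameterized), which handles the
sparse extremes produced by highly skewed traits. The fitter agrees with
statsmodels' `OrderedModel` to ~10⁻⁵ in log-likelihood on simulated data
and reduces exactly to binary logistic regression at J = 2.

**Degenerate replications.** A replication whose tested item has a single
observed category, or whose fits fail to converge, is redrawn once from a
follow-up stream and otherwise dropped from the affected denominators;
drops are counted in `n_convergence_failures` so the policy is auditable.
At the study's sample sizes failures are essentially absent.

**Reproducibility.** Every replication draws from
`SeedSequence((master_seed, J, N, R, dif_code, condition, rep, attempt))`,
so the entire grid is a pure function of (config, master seed), cells and
replications can be recomputed independently in any order, and
parallelization cannot change results.

## What the generator does and does not emulate

The generator emulates a short ordinal scale with moderately
discriminating items, one contaminating item, and group differences
confined to trait-distribution shape. It does **not** emulate: multiple
DIF items, nonuniform DIF generation (discrimination shifts),
multidimensional traits, correlated item residuals, missing data, or
respondent style effects (acquiescence, extreme responding). Passing tests
therefore certify the test procedure's behaviour under a clean GRM world;
real instruments can deviate in all the ways above, most importantly via
multiple simultaneous DIF items, which contaminate the matching score more
than the single-item design studied here.

## Problem sizes

Default replications per cell are 1000 (the reference settings; MC error
≈ 0.015 at p ≈ 0.8 and ≈ 0.007 at p ≈ 0.05), with smaller counts used
where a broad sub-grid is scanned rather than a single cell pinned down:
the severe-DIF floor check runs 27–36 cells at 300 replications each.
Power-only runs can set `items="dif_only"`, which skips the nine null
items per replication (an order-of-magnitude saving) without touching the
power estimate, since items are tested independently and no
multiple-testing rule links them.

## Known limitations

- The type-I definition pools the nine null items; items are exchangeable
  by construction, but with a fixed bank the per-item rates differ and the
  pooled figure averages over them.
- With `matching="total"` the null-item tests are not exactly nominal in
  any scenario containing a DIF item (contamination is the object of
  study, not a bug); use `dif_magnitude=0` scenarios for clean calibration
  checks.
- Cumulative-logit coding means β₁ < 0 for a trait that raises scores;
  all tests are invariant to this sign convention.
- Beta traits standardized to mean 0 remove group *impact* (mean
  differences) by construction; conditions differing in shape only are
  exactly that, and designs with genuine impact need a different trait
  specification.
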