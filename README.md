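# difpower

Monte-Carlo power and type-I error of ordinal logistic regression for
detecting differential item functioning (DIF) in Likert-type rating scales.

## The problem

Health-related quality-of-life and other psychometric instruments are only
comparable across groups if their items behave the same way in each group
after conditioning on the measured trait. An item that violates this —
differential item functioning — is usually hunted with ordinal logistic
regression (OLR): for each item, three nested cumulative-logit
(proportional-odds) models are fit to the item response *Y* with matching
score *θ* (the observed total test score) and group *g* (0 = reference,
1 = focal),

```
Model 1:  logit P(Y ≤ k) = α_k + β₁ θ
Model 2:  logit P(Y ≤ k) = α_k + β₁ θ + β₂ g
Model 3:  logit P(Y ≤ k) = α_k + β₁ θ + β₂ g + β₃ gθ
```

Twice the log-likelihood gain of Model 2 over Model 1 is a 1-df chi-square
test for **uniform DIF** (a constant group shift); Model 3 versus Model 2
tests **nonuniform DIF** (a shift that varies with the trait).

How much power this procedure has — and how its false-positive rate behaves —
depends on the design: the number of response categories *J*, the sample
size and the reference:focal ratio, the size and sign of the DIF, and the
shape of the latent-trait distributions. `difpower` answers such questions
by simulation. It generates item responses from a graded response model
(GRM): with discrimination *aᵢ* and ascending thresholds *b_ij*, the
probability of scoring in or above category *j* is

```
P*ᵢⱼ(θ) = exp(aᵢ(θ − b_ij)) / (1 + exp(aᵢ(θ − b_ij)))
```

and category probabilities are differences of consecutive cumulative terms.
Uniform DIF is injected by adding a constant δ to every threshold of one
item in the focal group. Latent traits come from N(0,1) or from beta
distributions standardized to mean 0 and variance 1, so that skewness can
be varied while staying on the threshold scale; nine built-in
reference/focal pairings (`TRAIT_CONDITIONS`) range from both-normal to
both groups highly skewed in opposite directions.

The proportional-odds fitter is implemented in the package (damped Newton
ascent with analytic gradient and Hessian), so the likelihoods entering the
likelihood-ratio tests are fully specified; it is cross-checked against
statsmodels in the test suite.

## Worked example

Estimate power and pooled type-I error for one design cell — five response
categories, 300 + 300 subjects, both trait distributions normal, a +0.5
uniform shift in item 1 (`examples/power_cell.py`):

```python
from difpower import Scenario, TRAIT_CONDITIONS, run_scenario

scenario = Scenario(n_categories=5, total_n=600, ratio=1,
                    dif_magnitude=0.5, condition=TRAIT_CONDITIONS[1])
summary = run_scenario(scenario, n_reps=200, master_seed=42, items="all")
```

prints

```
replications used: 200
power:   0.735  (MC SE 0.031)
type-I:  0.066  (MC SE 0.006)
convergence failures: 0
```

i.e. a moderate threshold shift of 0.5 is detected in roughly three
quarters of samples of this size, while the nine DIF-free items are
falsely flagged slightly more often than the nominal 5% because the DIF
item contaminates the total matching score.

The other examples show the building blocks: `grm_basics.py` (item banks,
category probabilities, what a uniform shift does to expected scores),
`single_dif_test.py` (per-item LRT table on one dataset),
`mini_grid.py` (a sub-grid run pivoted into a wide power table).

A thin CLI wraps the same machinery:

```
difpower cell -j 5 -n 600 -r 1 --dif 0.5 -c 1 --reps 200 --seed 42
difpower run --config examples/grid_small.yaml --out results/
difpower tables results/results_long.csv -n 600 --metric power
```

The full study grid (3 category counts × 2 sample sizes × 3 ratios ×
2 DIF magnitudes × 9 trait conditions = 324 cells at 1000 replications) is
`GridConfig()`; expect hours of CPU time at full size.

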