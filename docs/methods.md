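# Methods

## Model

Responses are p binary items coded {0,1} (1 = the keyed statement is
endorsed).  The joint distribution is the Ising model

P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} ω_ij xᵢ xⱼ ),

parameterized on the {0,1} state space (not spins ±1): this matches the
conditional-logistic form used by the estimator, P(xᵢ=1 | rest) =
logistic(τᵢ + Σⱼ ω_ij xⱼ), so estimated couplings and simulated couplings
live on the same scale.  No ±1 conversion utilities are provided, on
purpose — mixing the two parameterizations silently rescales couplings by
a factor of 4 and shifts thresholds, and is a classic source of error.

## Estimation (eLasso)

Each node i is regressed on the remaining p−1 items by l1-penalized
logistic regression, minimizing −(1/n)·loglik + λ‖β‖₁ with an unpenalized
intercept.  Per node:

* **Penalty path.** λ_max = maxⱼ |xⱼᵀ(y − ȳ)|/n (the smallest penalty
  with an all-zero solution, from the null-model score equations), then
  100 log-spaced values down to λ_max·r with r = 0.01 when n > p and
  0.05 otherwise.  Predictors are left unstandardized: items are already
  on a common 0/1 scale, and penalizing them equally is the intended
  behaviour; standardizing binary dummies would up-weight rare items.
* **Selection.** EBIC(λ) = −2·loglik + J·log n + 2γ·J·log(p−1), with J
  the number of nonzero slopes and loglik the unpenalized conditional
  log-likelihood of the solution.  Default γ = 0.25.  Ties in the argmin
  resolve toward larger λ, i.e. the sparser model — consistent with the
  method's conservative intent.
* **Combination.** AND rule (default): ω_ij ≠ 0 only if i selects j and
  j selects i; the weight is the arithmetic mean of the two directed
  coefficients.  The mean is a design choice — the neighborhood-selection
  literature fixes only the support, not the symmetrization — chosen so
  AND and OR weights agree wherever both directions are selected.  OR
  rule: mean of the nonzero directions.  τᵢ is the selected intercept of
  node i's regression.

Constant columns make the conditional model undefined; estimation refuses
them by default and can drop them (`drop_constant=True`) with a logged
warning, preserving the remaining labels.

### Solver

The path is solved by iteratively reweighted least squares with
coordinate-wise soft-thresholding (the glmnet algorithm family), compiled
with numba.  Implementation notes:

* warm starts along the decreasing path; exact zeros from the
  soft-threshold operator (J is a count of exact zeros, no thresholding
  heuristic);
* quadratic-approximation weights floored at 1e-5 and the linear
  predictor capped at ±30, the standard guards near fitted probabilities
  of 0/1;
* convergence declared on relative change of the penalized objective,
  tolerance 1e-7, iteration cap 10,000; non-convergence raises, carrying
  the node and λ;
* an active-set strategy (full sweep to admit coordinates, then cycles
  over the nonzero set) and precomputed nonzero-row indices for the
  binary predictors; a 40-node, n≈1000 network fits in a few seconds,
  which is what makes thousands of bootstrap refits feasible;
* the KKT threshold carries a ~1e-12 relative margin so that fitting at
  exactly λ_max yields the null model despite floating-point rounding in
  the score.

The solver is validated in the test suite against closed forms (null
model), statsmodels' unpenalized MLE, a scipy L-BFGS-B oracle on the
variable-split objective, and R's glmnet; agreement is at the 1e-6 level
or better on the shared fixtures.

## Inference

Strength centrality sᵢ = Σⱼ |ω_ij|.  Ranks break ties by label order so
tables are reproducible.  Isolated nodes are exactly those with sᵢ = 0.
The Fruchterman-Reingold layout uses |ω_ij| as the attractive weight —
edge sign is rendered (color), not embodied in forces — and is
deterministic given its seed.  Centrality tables carry both raw and
z-standardized strength columns, since published figures use either.

## Stability

* **Edge/centrality bootstrap.** B resamples of n rows with replacement,
  each refit with the full eLasso pipeline.  Per-replicate seeds are
  spawned from the master seed (`numpy.random.SeedSequence`), so results
  are independent of execution order and identical under any `n_jobs`.
  A resample with a constant column is redrawn (≤ 10 times, logged):
  the estimator is undefined there.  This mildly biases replicates
  toward balanced resamples; with items of moderate prevalence it is
  essentially never triggered.
* **Confidence intervals.** Percentile intervals with
  linear-interpolation quantiles at (1−level)/2 and 1−(1−level)/2;
  default level 0.95.
* **Difference tests.** Percentile CI of the replicate-wise difference
  of two edge weights or two strengths; significant iff 0 lies outside.
  The level (0.95 default) is a package choice; the 0-in-CI rule itself
  is the standard one.
* **Case-dropping bootstrap.** For each drop proportion q in the grid,
  refit on ⌊n(1−q)⌋ distinct rows (without replacement) and correlate
  replicate strength with full-sample strength (Pearson by default,
  Spearman via `method=`; a zero-variance strength vector contributes
  correlation 0, logged).  Default grid {0.1, …, 0.7, 0.75}: the 0.75
  endpoint matches the customary cap of the reported statistic.  The
  CS-coefficient is the largest grid q whose replicates reach
  correlation ≥ 0.7 with probability ≥ 0.95; it is therefore a grid
  value, and a finer grid (e.g. steps of 0.05) is needed to resolve
  intermediate values such as 0.67.

## Synthetic data

`exact_distribution` enumerates all 2^p states (p ≤ 15) and is the
sampler's oracle.  `gibbs_sample` runs single-site Gibbs updates in a
fixed 1..p scan order — chosen over random-site updates for exact
reproducibility — with defaults burn-in 1000 sweeps and thinning 10,
conservative for the coupling magnitudes the generator produces (≤ ~1.5).
On a 4-node test network the total-variation distance between 200,000
Gibbs draws and the exact distribution is ≈ 0.003.

`npi_like_network` emulates the NPI's structure: seven domain blocks of
sizes 8, 7, 5, 6, 5, 6, 3 (the default 40-item layout uses the actual
item-to-domain assignment, so e.g. the Authority block is items 1, 8, 10,
11, 12, 32, 33, 36); every within-block pair positively coupled with
weights U(0.15, 0.65); cross-block pairs coupled at density 0.04 with
weights U(0.1, 0.3), of which 3 edges are made weakly negative
(U(−0.3, −0.1)); thresholds U(−2.1, −1.1).  The threshold range was
calibrated once so that Gibbs samples have a mean total score of ≈ 13 of
40 (observed 13.0 ± 0.6 across generator seeds at n = 2000) and then
frozen.

What the generator does *not* emulate: real NPI data show a stronger
general factor than a block-diagonal coupling matrix produces, so the
synthetic total-score SD (≈ 4) is below the ≈ 6.4 seen in student
samples, and real item content induces redundant near-duplicate pairs
with much stronger edges than the generator's draws.  Passing recovery
tests therefore demonstrate that the estimator recovers networks of this
sparsity and coupling scale at these sample sizes — not that every
feature of empirical questionnaire data is reproduced.

## Validation design

The pipeline is accepted against properties that need no external data:

* sampler vs. enumeration (TV < 0.01 at n = 200,000 on 4 nodes);
* EBIC selection vs. brute-force recomputation with an independent
  likelihood implementation (agreement 1e-8);
* parameter recovery on a fixed sparse 10-node network (7 edges,
  |ω| 0.7–1.5, one negative) at n = 5000: edge-sign sensitivity,
  specificity and weight correlation all ≥ 0.9;
* null calibration (no true edges, n = 2000): specificity ≥ 0.95;
* invariants: symmetry/zero diagonal of every fit, AND ⊆ OR edge sets,
  strength = absolute row sums, CS monotonicity, and bit-reproducibility
  of every stochastic step given its seed.

Empirical reproduction of the published student-sample results
(descriptives 13/6.4, En27 most central, CS = 0.67) additionally requires
the original dataset, which is not redistributed; the corresponding tests
look for `data/npi_responses.csv` and fail with an explanatory message
when it is absent.  At bootstrap scale B = 200 the case-dropping run on
the full 942×40 dataset takes tens of minutes on one CPU; the published
B = 2000 scales linearly.

## Problem sizes and defaults used in shipped runs

The test suite and `scripts/acceptance.py` use: study-scale synthetic
samples at n = 942 (descriptives, strength-recovery), the 10-node sparse
fixture at n = 5000 (recovery) and n = 2000 (stability, with a coarse
grid and B = 10 per proportion), the 4-node enumeration oracle at
n = 200,000, and shortened 30-point penalty paths in tests that refit
hundreds of times (path length changes selection only marginally and is
exposed in `EstimationConfig`).

## Known limitations

* The AND/OR weight symmetrization is a convention; directed coefficient
  pairs are averaged, not jointly estimated.
* EBIC consistency arguments assume sparse truth; dense, weakly coupled
  networks (many |ω| < 0.2 at n ≈ 1000) are recovered only partially —
  visible in the study-scale synthetic runs, where sensitivity is well
  below 1 while specificity stays near 1.
* The case-dropping CS-coefficient is a grid statistic; its resolution
  is the grid step.
* No missing-data handling: any non-{0,1} cell is an error by design.
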