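# isingnet

Network psychometrics for binary questionnaire data: eLasso Ising-network
estimation, strength centrality, and bootstrap stability analysis, with a
synthetic-data generator that makes the whole pipeline verifiable by
parameter recovery.

## The problem

Dichotomous questionnaires — the motivating case is the 40-item
Narcissistic Personality Inventory (NPI), whose item metadata ships with
the package — are traditionally summarized by sum scores or factor models.
The network approach instead treats each item as a node in a pairwise
Markov random field and asks which items are *conditionally* associated
once all other items are controlled for, and which items are most
interconnected.

For binary 0/1 responses the natural model is the Ising model

```
P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} ω_ij xᵢ xⱼ ),   x ∈ {0,1}^p,
```

with node thresholds τ and symmetric couplings Ω (zero diagonal).  A
nonzero ω_ij is an edge: a conditional association between items i and j.

## What the package implements

* **eLasso estimation** (`IsingModel.fit`): each item is regressed on all
  others with l1-penalized logistic regression over a 100-point
  log-spaced penalty path; the Extended Bayesian Information Criterion,
  EBIC(λ) = −2·loglik + J·log n + 2γ·J·log(p−1) with γ = 0.25 by default,
  selects the penalty per node; neighborhoods are combined with the
  conservative AND rule (an edge requires mutual selection; weight = mean
  of the two directed coefficients).  The path solver is a numba-compiled
  IRLS/coordinate-descent routine with an unpenalized intercept and exact
  zeros, cross-checked in the test suite against scipy, statsmodels and
  R's glmnet.
* **Inference** (`IsingFitResults.strength`, `isolated_nodes`,
  `fruchterman_reingold_layout`): strength centrality sᵢ = Σⱼ |ω_ij|
  with ranks and isolated-node flags, plus a weighted force-directed
  layout for plotting.
* **Stability** (`bootstrap_network`, `edge_ci`, `edge_difference_test`,
  `centrality_difference_test`, `case_dropping_bootstrap`,
  `cs_coefficient`): row-resampling bootstrap of the entire estimation
  pipeline with percentile CIs and difference tests (significant iff 0 is
  outside the CI of the bootstrapped difference), and the case-dropping
  bootstrap yielding the correlation-stability (CS) coefficient — the
  largest fraction of respondents that can be dropped while the replicate
  strength vector still correlates ≥ 0.7 with the full-sample one in 95%
  of replicates (≥ 0.25 acceptable, > 0.5 preferred).
* **Synthetic data** (`simulate`): exact enumeration of the state space
  for p ≤ 15, a seeded single-site Gibbs sampler, and `npi_like_network`,
  which builds ground-truth networks with the NPI's seven domain blocks
  (sizes 8, 7, 5, 6, 5, 6, 3), predominantly positive within-block
  couplings, a few weak negative cross-block edges, and thresholds
  calibrated so the mean total score is about 13 of 40.
* **CLI** (`isingnet fit|stability|simulate|all`): one-command runs
  producing descriptives, the network in edge-list/matrix/GraphML form,
  centrality tables, layouts, a JSON stability report, plots, and a
  manifest echoing every seed and setting.

## Worked example

```python
from isingnet import GeneratorSpec, IsingModel, sample_npi_like, summarize_total_scores

data, truth = sample_npi_like(GeneratorSpec(seed=1, n=942))
mean, sd = summarize_total_scores(data)
print(f"total score: mean={mean:.2f}, sd={sd:.2f}")

results = IsingModel(data).fit(gamma=0.25, rule="and")
print(results.summary())
print("five strongest items:", ", ".join(results.strength().top(5)))
```

prints

```
total score: mean=12.81, sd=4.08
Ising network (eLasso) results
==============================================
Items (p):            40
Observations (n):     942
EBIC gamma:           0.25
Rule:                 AND
Edges (nonzero):      59 of 780
Positive / negative:  59 / 0
Mean |weight|:        0.3305
Isolated nodes:       6
Strongest items:      A12, A36, A33, A8, A11
==============================================
five strongest items: A12, A36, A33, A8, A11
```

The synthetic sample behaves like a real NPI administration: the mean
total score sits near 13 of 40, the estimated network is sparse (59 of
780 possible edges) and entirely positive, a handful of items are
conditionally independent of everything else (isolated), and the
strongest items concentrate in the blocks given the densest couplings.
Because the generating network is known, the estimate can be scored:
at this sample size the estimated strength vector correlates ≈ 0.7–0.85
with the true one.

Stability analysis hangs off the same results object:

```python
boot = results.bootstrap(B=2000, seed=1)          # edge/centrality bootstrap
drop = results.case_dropping(B=50, seed=2)        # subsetting bootstrap
from isingnet import cs_coefficient
print(cs_coefficient(drop))
```

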