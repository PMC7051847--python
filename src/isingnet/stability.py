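"""Bootstrap stability analysis for estimated Ising networks.

Three procedures, all pure functions of (inputs, seed):

* nonparametric bootstrap of edge weights and strength centralities
  (resampling n rows with replacement and refitting), giving percentile
  confidence intervals and edge/centrality difference tests;
* case-dropping (subsetting) bootstrap, re-estimating on progressively
  smaller without-replacement subsamples and correlating replicate
  strength with the full-sample strength;
* the correlation-stability (CS) coefficient summarizing the latter: the
  largest drop proportion at which, with 95% probability, that correlation
  stays at or above 0.7.  Values below 0.25 signal unstable centralities;
  above 0.5 is preferred.

Per-replicate seeds are spawned from the master seed with
`numpy.random.SeedSequence`, so results do not depend on execution order and
replicates may run in parallel (joblib).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .data import BinaryDataset
from .model import EstimationConfig, fit_ising
from .network import strength_centrality

__all__ = [
    "EdgeBootstrap",
    "CaseDropResult",
    "DifferenceTestResult",
    "bootstrap_network",
    "edge_ci",
    "edge_difference_test",
    "centrality_difference_test",
    "case_dropping_bootstrap",
    "cs_coefficient",
    "DEFAULT_DROP_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_DROP_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.75)
_MAX_RETRIES = 10


@dataclass(frozen=True)
class EdgeBootstrap:
    """Replicate edge weights and strengths from the row-resampling bootstrap.

    `replicate_edges` is B x E with E = p(p-1)/2 in fixed upper-triangle
    order (`edge_index`); `replicate_strength` is B x p.
    """

    B: int
    edge_index: tuple[tuple[int, int], ...]
    replicate_edges: np.ndarray
    replicate_strength: np.ndarray
    labels: tuple[str, ...]
    seed: int
    estimation_config: EstimationConfig

    def edge_position(self, edge: tuple[int | str, int | str]) -> int:
        """Column of `replicate_edges` for an (i, j) pair of indices or labels."""
        a, b = (self.labels.index(e) if isinstance(e, str) else int(e) for e in edge)
        if a == b:
            raise ValueError("an edge needs two distinct endpoints")
        key = (min(a, b), max(a, b))
        return self.edge_index.index(key)

    def node_position(self, node: int | str) -> int:
        return self.labels.index(node) if isinstance(node, str) else int(node)


@dataclass(frozen=True)
class CaseDropResult:
    """Per-proportion strength correlations from the case-dropping bootstrap.

    `correlations[q]` holds, for each of B replicates at drop proportion
    `proportions[q]`, the correlation between replicate strength and the
    full-sample strength vector.
    """

    proportions: np.ndarray
    correlations: np.ndarray  # Q x B
    seed: int
    method: str = "pearson"


@dataclass(frozen=True)
class DifferenceTestResult:
    """Bootstrap difference test: significant iff 0 lies outside the CI."""

    pair: tuple[str, str]
    ci_low: float
    ci_high: float
    significant: bool
    level: float


def _strength_from_omega(omega: np.ndarray) -> np.ndarray:
    return np.abs(omega).sum(axis=1)


def _one_bootstrap_replicate(values, labels, config, seed_state):
    rng = np.random.default_rng(seed_state)
    n = values.shape[0]
    for attempt in range(_MAX_RETRIES + 1):
        rows = rng.integers(0, n, size=n)
        sub = values[rows]
        means = sub.mean(axis=0)
        if ((means == 0) | (means == 1)).any():
            logger.debug("resample produced a constant column; redrawing (attempt %d)", attempt + 1)
            continue
        net = fit_ising(BinaryDataset(sub, labels), config)
        iu = np.triu_indices(net.p, k=1)
        return net.omega[iu], _strength_from_omega(net.omega)
    raise RuntimeError(
        f"bootstrap replicate kept producing constant columns after {_MAX_RETRIES} retries"
    )


def bootstrap_network(
    X: BinaryDataset,
    B: int,
    seed: int,
    config: EstimationConfig = EstimationConfig(),
    n_jobs: int = 1,
) -> EdgeBootstrap:
    """Row-resampling bootstrap of the whole estimation pipeline.

    Each of the B replicates resamples n rows with replacement and refits
    the network with `fit_ising`.  A resample with a constant column is
    redrawn (at most 10 times) because the nodewise estimator is undefined
    there.  Same (X, B, seed) always gives bit-identical output, regardless
    of `n_jobs`.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    children = np.random.SeedSequence(seed).spawn(B)
    run = delayed(_one_bootstrap_replicate)
    out = Parallel(n_jobs=n_jobs)(
        run(X.values, X.labels, config, child) for child in children
    )
    edges = np.vstack([e for e, _ in out])
    strengths = np.vstack([s for _, s in out])
    if B >= 100:
        logger.info("bootstrap finished: %d replicates, %d edges tracked", B, edges.shape[1])
    p = X.p
    index = tuple((i, j) for i in range(p) for j in range(i + 1, p))
    return EdgeBootstrap(
        B=B,
        edge_index=index,
        replicate_edges=edges,
        replicate_strength=strengths,
        labels=X.labels,
        seed=seed,
        estimation_config=config,
    )


def _percentile_ci(samples: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def edge_ci(boot: EdgeBootstrap, level: float = 0.95) -> np.ndarray:
    """Percentile CIs per edge: E x 2 array of (low, high) at the given level."""
    if boot.B < 20:
        raise ValueError("percentile intervals need at least 20 replicates")
    alpha = (1.0 - level) / 2.0
    qs = np.quantile(boot.replicate_edges, [alpha, 1.0 - alpha], axis=0)
    return qs.T


def edge_difference_test(
    boot: EdgeBootstrap,
    edge_a: tuple[int | str, int | str],
    edge_b: tuple[int | str, int | str],
    level: float = 0.95,
) -> DifferenceTestResult:
    """Is edge A's weight different from edge B's?  CI of the replicate-wise difference."""
    ia, ib = boot.edge_position(edge_a), boot.edge_position(edge_b)
    diff = boot.replicate_edges[:, ia] - boot.replicate_edges[:, ib]
    lo, hi = _percentile_ci(diff, level)
    name = lambda e: "-".join(
        str(x) if isinstance(x, str) else boot.labels[int(x)] for x in e
    )
    return DifferenceTestResult(
        pair=(name(edge_a), name(edge_b)),
        ci_low=lo,
        ci_high=hi,
        significant=not (lo <= 0.0 <= hi),
        level=level,
    )


def centrality_difference_test(
    boot: EdgeBootstrap,
    node_a: int | str,
    node_b: int | str,
    level: float = 0.95,
) -> DifferenceTestResult:
    """Is node A's strength different from node B's?  Same rule as the edge test."""
    ia, ib = boot.node_position(node_a), boot.node_position(node_b)
    diff = boot.replicate_strength[:, ia] - boot.replicate_strength[:, ib]
    lo, hi = _percentile_ci(diff, level)
    name = lambda v: v if isinstance(v, str) else boot.labels[int(v)]
    return DifferenceTestResult(
        pair=(name(node_a), name(node_b)),
        ci_low=lo,
        ci_high=hi,
        significant=not (lo <= 0.0 <= hi),
        level=level,
    )


def _replicate_correlation(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        from scipy.stats import rankdata

        a, b = rankdata(a), rankdata(b)
    if np.std(a) == 0 or np.std(b) == 0:
        logger.debug("zero-variance strength vector in replicate; correlation set to 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _one_casedrop_replicate(values, labels, config, keep, full_strength, method, seed_state):
    rng = np.random.default_rng(seed_state)
    n = values.shape[0]
    for attempt in range(_MAX_RETRIES + 1):
        rows = rng.choice(n, size=keep, replace=False)
        sub = values[rows]
        means = sub.mean(axis=0)
        if ((means == 0) | (means == 1)).any():
            continue
        net = fit_ising(BinaryDataset(sub, labels), config)
        return _replicate_correlation(
            _strength_from_omega(net.omega), full_strength, method
        )
    raise RuntimeError(
        f"case-dropping replicate kept producing constant columns after {_MAX_RETRIES} retries"
    )


def case_dropping_bootstrap(
    X: BinaryDataset,
    proportions=None,
    B: int = 50,
    seed: int = 0,
    config: EstimationConfig = EstimationConfig(),
    n_jobs: int = 1,
    method: str = "pearson",
) -> CaseDropResult:
    """Subsetting bootstrap: refit on floor(n(1-q)) distinct rows per proportion q.

    Records, per replicate, the correlation (Pearson by default, Spearman
    optional) between the replicate's strength vector and the full-sample
    strength vector.  A replicate whose strength vector has zero variance
    contributes correlation 0.
    """
    props = np.sort(np.asarray(proportions if proportions is not None else DEFAULT_DROP_GRID, dtype=float))
    if props.size == 0 or props.min() <= 0 or props.max() >= 1:
        raise ValueError("proportions must be a nonempty grid inside (0, 1)")
    if int(np.floor(X.n * (1.0 - props.max()))) < 50:
        raise ValueError("largest drop proportion leaves fewer than 50 rows")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    full = fit_ising(X, config)
    full_strength = _strength_from_omega(full.omega)
    children = np.random.SeedSequence(seed).spawn(props.size * B)
    jobs = []
    run = delayed(_one_casedrop_replicate)
    for qi, q in enumerate(props):
        keep = int(np.floor(X.n * (1.0 - q)))
        for b in range(B):
            jobs.append(
                run(X.values, X.labels, config, keep, full_strength, method,
                    children[qi * B + b])
            )
    flat = Parallel(n_jobs=n_jobs)(jobs)
    corr = np.asarray(flat, dtype=float).reshape(props.size, B)
    return CaseDropResult(proportions=props, correlations=corr, seed=seed, method=method)


def cs_coefficient(
    result: CaseDropResult,
    cor_threshold: float = 0.7,
    prob: float = 0.95,
) -> float:
    """Correlation-stability coefficient.

    The largest drop proportion q in the grid such that at least `prob` of
    the replicates at q correlate with the full-sample strength at
    `cor_threshold` or better; 0.0 if no grid point qualifies.  Should not
    be below 0.25, preferably above 0.5.
    """
    ok = (result.correlations >= cor_threshold).mean(axis=1) >= prob
    passing = result.proportions[ok]
    return float(passing.max()) if passing.size else 0.0
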