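"""Synthetic binary data from known Ising networks.

Two samplers are provided: exact enumeration of the 2^p state space for
small networks (the oracle), and a single-site Gibbs sampler with a fixed
sequential scan for anything larger.  `npi_like_network` builds ground-truth
networks that emulate the 40-item NPI: seven domain blocks (sizes 8, 7, 5,
6, 5, 6, 3), predominantly positive couplings concentrated within blocks, a
few weak negative cross-block couplings, and negative thresholds calibrated
so that the mean total score is about 13 of 40.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .data import BinaryDataset, npi_metadata
from .model import EstimationConfig, fit_ising
from .network import IsingNetwork

__all__ = [
    "GeneratorSpec",
    "ExactDistribution",
    "RecoveryMetrics",
    "exact_distribution",
    "gibbs_sample",
    "npi_like_network",
    "sample_npi_like",
    "recovery_experiment",
]

_ENUM_MAX_P = 15


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth network and sample-size settings for the NPI-like generator.

    Defaults emulate the study conditions the estimator targets: 40 items in
    seven domain blocks, dense positive within-block couplings, sparse weak
    cross-block links with a handful of small negative edges, and thresholds
    calibrated once so Gibbs samples score ~13/40 on average.
    """

    p: int = 40
    block_sizes: tuple[int, ...] = (8, 7, 5, 6, 5, 6, 3)
    intra_block_coupling: tuple[float, float] = (0.15, 0.65)
    cross_block_density: float = 0.04
    cross_block_coupling: tuple[float, float] = (0.1, 0.3)
    negative_edge_count: int = 3
    negative_coupling: tuple[float, float] = (-0.3, -0.1)
    threshold_range: tuple[float, float] = (-2.1, -1.1)
    n: int = 942
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.p:
            raise ValueError(
                f"block sizes {self.block_sizes} sum to {sum(self.block_sizes)}, not p={self.p}"
            )
        if not 0 <= self.cross_block_density <= 1:
            raise ValueError("cross_block_density must lie in [0, 1]")
        if self.negative_edge_count < 0:
            raise ValueError("negative_edge_count must be >= 0")


@dataclass(frozen=True)
class ExactDistribution:
    """All 2^p states of a small Ising network with their probabilities."""

    states: np.ndarray
    probabilities: np.ndarray

    def marginal(self, i: int) -> float:
        """P(x_i = 1)."""
        return float(self.probabilities[self.states[:, i] == 1].sum())


def _state_table(p: int) -> np.ndarray:
    """All 2^p binary vectors; row index read as a base-2 integer (MSB first)."""
    ints = np.arange(2**p, dtype=np.int64)
    return ((ints[:, None] >> np.arange(p - 1, -1, -1)) & 1).astype(np.int8)


def exact_distribution(net: IsingNetwork) -> ExactDistribution:
    """Enumerate P(x) ∝ exp(tau'x + sum_{i<j} omega_ij x_i x_j) for p <= 15."""
    if net.p > _ENUM_MAX_P:
        raise ValueError(
            f"p={net.p} > {_ENUM_MAX_P}: enumeration infeasible, use gibbs_sample"
        )
    states = _state_table(net.p).astype(float)
    energy = states @ net.tau + 0.5 * np.einsum("si,ij,sj->s", states, net.omega, states)
    energy -= energy.max()
    weights = np.exp(energy)
    return ExactDistribution(states.astype(np.int8), weights / weights.sum())


@njit(cache=True)
def _gibbs_kernel(tau, omega, uniforms, n_keep, burn_in, thin, x0):
    p = tau.shape[0]
    x = x0.copy()
    out = np.empty((n_keep, p), dtype=np.int8)
    sweeps = burn_in + n_keep * thin
    u_idx = 0
    kept = 0
    for sweep in range(sweeps):
        for i in range(p):
            eta = tau[i]
            for j in range(p):
                eta += omega[i, j] * x[j]
            prob = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1 if uniforms[u_idx] < prob else 0
            u_idx += 1
        if sweep >= burn_in and (sweep - burn_in + 1) % thin == 0:
            out[kept] = x
            kept += 1
    return out


def gibbs_sample(
    net: IsingNetwork,
    n: int,
    burn_in: int = 1000,
    thin: int = 10,
    seed: int = 0,
) -> BinaryDataset:
    """Draw n rows by single-site Gibbs sampling with a fixed 1..p scan order.

    The conditional used is P(x_i = 1 | rest) = logistic(tau_i + sum_j
    omega_ij x_j).  Deterministic given the seed; one chain, `burn_in`
    discarded sweeps, one row kept every `thin` sweeps.
    """
    if n < 1 or burn_in < 0 or thin < 1:
        raise ValueError("need n >= 1, burn_in >= 0, thin >= 1")
    rng = np.random.default_rng(seed)
    sweeps = burn_in + n * thin
    uniforms = rng.random(sweeps * net.p)
    x0 = (rng.random(net.p) < 0.5).astype(np.int8)
    values = _gibbs_kernel(
        net.tau, net.omega, uniforms, int(n), int(burn_in), int(thin), x0
    )
    return BinaryDataset(values, net.labels)


def _default_blocks(spec: GeneratorSpec) -> list[list[int]]:
    """Item indices per block; the 40-item default uses the NPI domain layout."""
    if spec.p == 40 and tuple(spec.block_sizes) == (8, 7, 5, 6, 5, 6, 3):
        order = ("Authority", "Exhibitionism", "Superiority", "Entitlement",
                 "Exploitativeness", "Self-sufficiency", "Vanity")
        by_domain: dict[str, list[int]] = {d: [] for d in order}
        for item in npi_metadata():
            by_domain[item.domain].append(item.item_number - 1)
        return [by_domain[d] for d in order]
    blocks, start = [], 0
    for size in spec.block_sizes:
        blocks.append(list(range(start, start + size)))
        start += size
    return blocks


def npi_like_network(spec: GeneratorSpec = GeneratorSpec()) -> IsingNetwork:
    """Ground-truth Ising network with NPI-like block structure.

    Every within-block pair is coupled with a positive weight drawn from
    `intra_block_coupling`; cross-block pairs are coupled with probability
    `cross_block_density`, positive except for `negative_edge_count` of them
    which receive small negative weights from `negative_coupling`.
    Thresholds are drawn from `threshold_range`.  Reproducible given
    `spec.seed`; sampling uses its own substream so the same spec with a
    different `n` yields the identical network.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    p = spec.p
    blocks = _default_blocks(spec)
    omega = np.zeros((p, p))
    lo, hi = spec.intra_block_coupling
    if lo <= 0 or hi < lo:
        raise ValueError("intra_block_coupling must be a positive (low, high) range")
    for block in blocks:
        for a_pos, i in enumerate(block):
            for j in block[a_pos + 1:]:
                w = rng.uniform(lo, hi)
                omega[i, j] = omega[j, i] = w
    block_of = np.empty(p, dtype=int)
    for b, block in enumerate(blocks):
        block_of[np.array(block, dtype=int)] = b
    cross_pairs = [
        (i, j) for i in range(p) for j in range(i + 1, p) if block_of[i] != block_of[j]
    ]
    picked = [pair for pair in cross_pairs if rng.random() < spec.cross_block_density]
    if spec.negative_edge_count > len(picked):
        raise ValueError(
            f"negative_edge_count={spec.negative_edge_count} exceeds the "
            f"{len(picked)} cross-block edges drawn at density {spec.cross_block_density}"
        )
    neg_idx = set(
        rng.choice(len(picked), size=spec.negative_edge_count, replace=False).tolist()
        if spec.negative_edge_count
        else []
    )
    for k, (i, j) in enumerate(picked):
        if k in neg_idx:
            w = rng.uniform(*spec.negative_coupling)
        else:
            w = rng.uniform(*spec.cross_block_coupling)
        omega[i, j] = omega[j, i] = w
    tau = rng.uniform(spec.threshold_range[0], spec.threshold_range[1], size=p)
    if p == 40 and tuple(spec.block_sizes) == (8, 7, 5, 6, 5, 6, 3):
        labels = tuple(item.label for item in npi_metadata())
    else:
        labels = tuple(f"V{i+1}" for i in range(p))
    return IsingNetwork(tau, omega, labels)


def sample_npi_like(
    spec: GeneratorSpec = GeneratorSpec(),
    burn_in: int = 1000,
    thin: int = 10,
) -> tuple[BinaryDataset, IsingNetwork]:
    """Ground-truth network plus a Gibbs sample of `spec.n` rows from it."""
    net = npi_like_network(spec)
    sample_seed = int(np.random.SeedSequence([spec.seed, 23]).generate_state(1)[0] % (2**31))
    data = gibbs_sample(net, spec.n, burn_in=burn_in, thin=thin, seed=sample_seed)
    return data, net


def sparse_recovery_network() -> IsingNetwork:
    """Fixed sparse 10-node network used for parameter-recovery validation.

    Seven edges (one negative) with couplings of magnitude 0.7-1.5 and a
    common threshold of -0.5: strong enough to be recoverable from a few
    thousand Gibbs rows, sparse enough that specificity is informative.
    """
    p = 10
    omega = np.zeros((p, p))
    for i, j, w in [
        (0, 1, 1.2), (1, 2, 0.9), (3, 4, 1.5), (5, 6, -0.8),
        (7, 8, 1.0), (2, 9, 0.7), (4, 7, 0.8),
    ]:
        omega[i, j] = omega[j, i] = w
    return IsingNetwork(np.full(p, -0.5), omega)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Edge-recovery quality of an estimate against a known truth.

    Defined on the off-diagonal upper triangle: sensitivity is the fraction
    of truly nonzero couplings recovered with a nonzero estimate of the same
    sign; specificity the fraction of true zeros estimated as zero; the
    weight correlation is Pearson's r between truth and estimate over the
    truly nonzero couplings.
    """

    sensitivity: float
    specificity: float
    weight_correlation: float
    n_true_edges: int
    n_estimated_edges: int
    estimate: IsingNetwork = field(repr=False, compare=False, default=None)  # type: ignore[assignment]


def _upper(a: np.ndarray) -> np.ndarray:
    return a[np.triu_indices(a.shape[0], k=1)]


def compare_networks(truth: IsingNetwork, estimate: IsingNetwork) -> RecoveryMetrics:
    """Recovery metrics for an estimated network against its ground truth."""
    tw, ew = _upper(truth.omega), _upper(estimate.omega)
    true_nz = tw != 0
    if true_nz.any():
        sens = float(np.mean((ew[true_nz] != 0) & (np.sign(ew[true_nz]) == np.sign(tw[true_nz]))))
        if true_nz.sum() >= 2 and np.std(ew[true_nz]) > 0:
            corr = float(np.corrcoef(tw[true_nz], ew[true_nz])[0, 1])
        else:
            corr = np.nan
    else:
        sens, corr = np.nan, np.nan
    true_z = ~true_nz
    spec = float(np.mean(ew[true_z] == 0)) if true_z.any() else np.nan
    return RecoveryMetrics(
        sensitivity=sens,
        specificity=spec,
        weight_correlation=corr,
        n_true_edges=int(true_nz.sum()),
        n_estimated_edges=int((ew != 0).sum()),
        estimate=estimate,
    )


def recovery_experiment(
    spec: GeneratorSpec,
    config: EstimationConfig = EstimationConfig(),
    burn_in: int = 1000,
    thin: int = 10,
) -> RecoveryMetrics:
    """Generate data from a known network, re-estimate it, and score recovery."""
    data, truth = sample_npi_like(spec, burn_in=burn_in, thin=thin)
    estimate = fit_ising(data, config)
    return compare_networks(truth, estimate)
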