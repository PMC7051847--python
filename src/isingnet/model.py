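"""eLasso estimation of an Ising network from binary data.

Each item is regressed on all other items with l1-penalized logistic
regression over a decreasing penalty path; the Extended Bayesian Information
Criterion (EBIC) selects the penalty per node; neighborhoods are combined
into an undirected network with the AND rule (an edge requires both
endpoints to select each other) or the OR rule.

The user-facing surface follows the Model/Results idiom::

    model = IsingModel(data)            # BinaryDataset, DataFrame or array
    res = model.fit(gamma=0.25)         # IsingFitResults
    res.network                         # IsingNetwork (tau, omega)
    res.strength()                      # CentralityTable
    res.summary()
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._solver import logistic_loglik, solve_path
from .data import BinaryDataset
from .network import CentralityTable, IsingNetwork, fruchterman_reingold_layout, strength_centrality

__all__ = [
    "EstimationConfig",
    "NodewisePath",
    "IsingModel",
    "IsingFitResults",
    "lambda_sequence",
    "l1_logistic",
    "ebic_score",
    "fit_node",
    "fit_ising",
    "ConstantColumnError",
    "ConvergenceError",
]

logger = logging.getLogger(__name__)


class ConstantColumnError(ValueError):
    """A response column is constant; its conditional logistic model is undefined."""


class ConvergenceError(RuntimeError):
    """The penalized solver failed to converge within the iteration cap."""


@dataclass(frozen=True)
class EstimationConfig:
    """eLasso tuning knobs.

    gamma
        EBIC hyperparameter; 0 reduces to ordinary BIC, larger values
        select sparser networks.  Default 0.25.
    rule
        "and" (edge requires mutual selection; conservative, default) or "or".
    n_lambda
        Number of penalties on the log-spaced path.
    lambda_min_ratio
        Smallest penalty as a fraction of lambda_max; when None, 0.01 if
        n > p else 0.05.
    tolerance / max_iter
        Solver convergence tolerance (relative objective change) and
        iteration cap.
    drop_constant
        If True, constant columns are dropped with a warning instead of
        raising; the returned network then has fewer nodes.
    """

    gamma: float = 0.25
    rule: str = "and"
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    tolerance: float = 1e-7
    max_iter: int = 10_000
    drop_constant: bool = False

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.rule not in ("and", "or"):
            raise ValueError("rule must be 'and' or 'or'")
        if self.lambda_min_ratio is not None and not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be positive")

    def resolved_min_ratio(self, n: int, p: int) -> float:
        if self.lambda_min_ratio is not None:
            return self.lambda_min_ratio
        return 0.01 if n > p else 0.05


@dataclass(frozen=True)
class NodewisePath:
    """Model-selection workspace for one node's regression on the others.

    `coefficients` has one row per penalty, one column per predictor item
    (all items except `node_index`, in original order).  `selected` is the
    index of the EBIC-minimizing penalty, with ties resolved toward the
    larger penalty (sparser model).
    """

    node_index: int
    lambdas: np.ndarray
    intercepts: np.ndarray
    coefficients: np.ndarray
    loglik: np.ndarray
    J: np.ndarray
    ebic: np.ndarray
    selected: int

    @property
    def selected_intercept(self) -> float:
        return float(self.intercepts[self.selected])

    @property
    def selected_coefficients(self) -> np.ndarray:
        return self.coefficients[self.selected]


def lambda_sequence(
    X: BinaryDataset | np.ndarray, node: int, config: EstimationConfig = EstimationConfig()
) -> np.ndarray:
    """Decreasing log-spaced penalty path for one node's regression.

    lambda_max is the smallest penalty at which every slope is zero:
    max_j |x_j' (y - ybar)| / n, the maximum absolute score of the
    intercept-only model.
    """
    values = X.values if isinstance(X, BinaryDataset) else np.asarray(X)
    y = values[:, node].astype(float)
    n = values.shape[0]
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ConstantColumnError(
            f"column {node} is constant; exclude it before estimation "
            "(or set drop_constant=True)"
        )
    predictors = np.delete(values, node, axis=1).astype(float)
    lam_max = float(np.max(np.abs(predictors.T @ (y - ybar))) / n)
    lam_max = max(lam_max, 1e-8)  # pure-independence data: keep path valid
    ratio = config.resolved_min_ratio(n, values.shape[1])
    return np.geomspace(lam_max, lam_max * ratio, config.n_lambda)


def l1_logistic(
    predictors: np.ndarray,
    response: np.ndarray,
    lam: float,
    tolerance: float = 1e-7,
    max_iter: int = 10_000,
) -> tuple[float, np.ndarray]:
    """Single-penalty l1 logistic fit with unpenalized intercept.

    Minimizes -(1/n) loglik + lam * ||slopes||_1; deterministic.
    """
    response = np.asarray(response, dtype=float)
    if response.mean() in (0.0, 1.0):
        raise ConstantColumnError("constant response: logistic fit undefined")
    b0s, bs, _, conv = solve_path(
        np.asarray(predictors, dtype=float), response, np.array([float(lam)]),
        tol=tolerance, max_iter=max_iter,
    )
    if not conv[0]:
        raise ConvergenceError(f"l1 logistic did not converge at lambda={lam!r}")
    return float(b0s[0]), bs[0].copy()


def ebic_score(loglik: float, J: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: -2 loglik + J log n + 2 gamma J log(p-1).

    J is the number of nonzero slopes; p-1 is the candidate-predictor count.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    return -2.0 * loglik + J * np.log(n) + 2.0 * gamma * J * np.log(p - 1)


def fit_node(
    X: BinaryDataset | np.ndarray,
    node: int,
    config: EstimationConfig = EstimationConfig(),
) -> NodewisePath:
    """Fit one node's full penalty path and select by EBIC.

    Ties in the EBIC argmin resolve toward the larger penalty, i.e. the
    sparser model.
    """
    values = X.values if isinstance(X, BinaryDataset) else np.asarray(X)
    n, p = values.shape
    lams = lambda_sequence(values, node, config)
    y = values[:, node].astype(float)
    predictors = np.delete(values, node, axis=1).astype(float)
    t0 = time.perf_counter()
    intercepts, coefs, n_iter, conv = solve_path(
        predictors, y, lams, tol=config.tolerance, max_iter=config.max_iter
    )
    if not conv.all():
        bad = int(np.flatnonzero(~conv)[0])
        raise ConvergenceError(
            f"node {node}: no convergence at lambda={lams[bad]:.6g} "
            f"(path index {bad}) within {config.max_iter} iterations"
        )
    loglik = np.array(
        [logistic_loglik(predictors, y, intercepts[l], coefs[l]) for l in range(len(lams))]
    )
    J = np.count_nonzero(coefs, axis=1)
    ebic = np.array(
        [ebic_score(loglik[l], int(J[l]), n, p, config.gamma) for l in range(len(lams))]
    )
    selected = int(np.argmin(ebic))  # first minimum = largest lambda = sparsest
    logger.debug(
        "node %d: path of %d lambdas fit in %.3fs, selected J=%d",
        node, len(lams), time.perf_counter() - t0, int(J[selected]),
    )
    return NodewisePath(
        node_index=node,
        lambdas=lams,
        intercepts=intercepts,
        coefficients=coefs,
        loglik=loglik,
        J=J,
        ebic=ebic,
        selected=selected,
    )


def _directed_slopes(paths: Sequence[NodewisePath], p: int) -> np.ndarray:
    """D[i, j] = slope of item j in node i's selected regression (diag 0)."""
    D = np.zeros((p, p))
    for path in paths:
        i = path.node_index
        others = [j for j in range(p) if j != i]
        D[i, others] = path.selected_coefficients
    return D


def _combine(D: np.ndarray, rule: str) -> np.ndarray:
    """Symmetrize directed slopes under the AND or OR neighborhood rule."""
    both = (D != 0) & (D.T != 0)
    mean = (D + D.T) / 2.0
    if rule == "and":
        omega = np.where(both, mean, 0.0)
    else:
        either = (D != 0) | (D.T != 0)
        single = np.where(D != 0, D, D.T)
        omega = np.where(both, mean, np.where(either, single, 0.0))
    np.fill_diagonal(omega, 0.0)
    return omega


def fit_ising(
    X: BinaryDataset,
    config: EstimationConfig = EstimationConfig(),
) -> IsingNetwork:
    """Estimate the full Ising network: nodewise paths, EBIC, AND/OR rule.

    Under the AND rule an edge's weight is the arithmetic mean of the two
    directed slope estimates when both are nonzero, else 0; under the OR
    rule the mean of the nonzero ones.  Thresholds are the selected
    intercepts.
    """
    if not isinstance(X, BinaryDataset):
        X = BinaryDataset(np.asarray(X), tuple(f"V{j+1}" for j in range(np.asarray(X).shape[1])))
    constant = X.constant_columns()
    if constant:
        names = [X.labels[j] for j in constant]
        if not config.drop_constant:
            raise ConstantColumnError(
                f"constant columns {names}: exclude them or set drop_constant=True"
            )
        logger.warning("dropping constant columns %s before estimation", names)
        keep = [j for j in range(X.p) if j not in set(constant)]
        X = BinaryDataset(X.values[:, keep], tuple(X.labels[j] for j in keep))
    paths = [fit_node(X, i, config) for i in range(X.p)]
    D = _directed_slopes(paths, X.p)
    omega = _combine(D, config.rule)
    tau = np.array([path.selected_intercept for path in paths])
    return IsingNetwork(tau, omega, X.labels)


class IsingModel:
    """Ising network model for an n x p binary item-response matrix.

    Parameters
    ----------
    data
        `BinaryDataset`, pandas DataFrame of {0,1} values (columns are item
        labels), or a plain array.
    labels
        Item labels when `data` is a bare array.

    Examples
    --------
    >>> model = IsingModel(df)
    >>> res = model.fit(gamma=0.25, rule="and")
    >>> res.network.n_edges(), res.strength().top(3)
    """

    def __init__(self, data, labels: Sequence[str] | None = None):
        if isinstance(data, BinaryDataset):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = BinaryDataset.from_dataframe(data)
        else:
            arr = np.asarray(data)
            labels = tuple(labels) if labels else tuple(f"V{j+1}" for j in range(arr.shape[1]))
            self.data = BinaryDataset(arr, labels)

    @classmethod
    def from_csv(cls, path, **read_kwargs) -> "IsingModel":
        from .data import read_binary_items

        return cls(read_binary_items(path, **read_kwargs))

    @property
    def nobs(self) -> int:
        return self.data.n

    @property
    def n_items(self) -> int:
        return self.data.p

    def fit(
        self, config: EstimationConfig | None = None, **kwargs
    ) -> "IsingFitResults":
        """Run the eLasso procedure; kwargs override `EstimationConfig` fields."""
        config = replace(config or EstimationConfig(), **kwargs)
        t0 = time.perf_counter()
        data = self.data
        constant = data.constant_columns()
        if constant and not config.drop_constant:
            names = [data.labels[j] for j in constant]
            raise ConstantColumnError(
                f"constant columns {names}: exclude them or set drop_constant=True"
            )
        if constant:
            logger.warning(
                "dropping constant columns %s before estimation",
                [data.labels[j] for j in constant],
            )
            keep = [j for j in range(data.p) if j not in set(constant)]
            data = BinaryDataset(data.values[:, keep], tuple(data.labels[j] for j in keep))
        paths = [fit_node(data, i, config) for i in range(data.p)]
        D = _directed_slopes(paths, data.p)
        network = IsingNetwork(
            np.array([path.selected_intercept for path in paths]),
            _combine(D, config.rule),
            data.labels,
        )
        logger.info(
            "fit %d-node Ising network (n=%d, gamma=%g, %s rule): %d edges in %.2fs",
            data.p, data.n, config.gamma, config.rule.upper(),
            network.n_edges(), time.perf_counter() - t0,
        )
        return IsingFitResults(self, network, paths, config)


class IsingFitResults:
    """Fitted eLasso Ising network with its per-node selection paths.

    Attributes
    ----------
    network : IsingNetwork
        Thresholds and symmetrized couplings.
    paths : list of NodewisePath
        Per-node penalty paths with EBIC values and selected indices.
    config : EstimationConfig
    """

    def __init__(self, model, network, paths, config):
        self.model = model
        self.network = network
        self.paths = paths
        self.config = config

    @property
    def tau(self) -> np.ndarray:
        return self.network.tau

    @property
    def omega(self) -> np.ndarray:
        return self.network.omega

    def strength(self) -> CentralityTable:
        """Strength centrality (absolute row sums of the coupling matrix)."""
        return strength_centrality(self.network)

    def layout(self, seed: int = 0, iterations: int = 50) -> np.ndarray:
        return fruchterman_reingold_layout(self.network, seed=seed, iterations=iterations)

    def bootstrap(self, B: int, seed: int, n_jobs: int = 1):
        """Nonparametric edge/centrality bootstrap; see `stability.bootstrap_network`."""
        from .stability import bootstrap_network

        return bootstrap_network(self.model.data, B, seed, self.config, n_jobs=n_jobs)

    def case_dropping(
        self, proportions=None, B: int = 50, seed: int = 0, n_jobs: int = 1, method: str = "pearson"
    ):
        """Case-dropping (subsetting) bootstrap; see `stability.case_dropping_bootstrap`."""
        from .stability import case_dropping_bootstrap

        return case_dropping_bootstrap(
            self.model.data, proportions, B, seed, self.config,
            n_jobs=n_jobs, method=method,
        )

    def summary(self) -> str:
        """Plain-text overview: data size, settings, sparsity, strongest items."""
        net = self.network
        cent = self.strength()
        weights = net.edge_weights()
        nz = weights[weights != 0]
        lines = [
            "Ising network (eLasso) results",
            "=" * 46,
            f"Items (p):            {net.p}",
            f"Observations (n):     {self.model.nobs}",
            f"EBIC gamma:           {self.config.gamma}",
            f"Rule:                 {self.config.rule.upper()}",
            f"Edges (nonzero):      {net.n_edges()} of {len(weights)}",
            f"Positive / negative:  {int((nz > 0).sum())} / {int((nz < 0).sum())}",
            f"Mean |weight|:        {np.abs(nz).mean():.4f}" if nz.size else "Mean |weight|:        n/a",
            f"Isolated nodes:       {int(cent.isolated.sum())}",
            f"Strongest items:      {', '.join(cent.top(5))}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<IsingFitResults p={self.network.p} n={self.model.nobs} "
            f"edges={self.network.n_edges()} rule={self.config.rule}>"
        )
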