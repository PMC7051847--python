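"""Ising network container, strength centrality, and layout.

An Ising network over p binary {0,1} items is parameterized by a threshold
vector tau (log-odds scale) and a symmetric zero-diagonal coupling matrix
omega.  P(x) is proportional to exp(sum_i tau_i x_i + sum_{i<j} omega_ij x_i x_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "IsingNetwork",
    "CentralityTable",
    "strength_centrality",
    "isolated_nodes",
    "fruchterman_reingold_layout",
]


@dataclass(frozen=True)
class IsingNetwork:
    """Thresholds tau (length p) and symmetric zero-diagonal couplings omega (p x p)."""

    tau: np.ndarray
    omega: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        omega = np.asarray(self.omega, dtype=float)
        p = tau.shape[0]
        if tau.ndim != 1 or omega.shape != (p, p):
            raise ValueError(f"shape mismatch: tau {tau.shape}, omega {omega.shape}")
        if not (np.isfinite(tau).all() and np.isfinite(omega).all()):
            raise ValueError("non-finite network parameters")
        if not np.allclose(omega, omega.T, atol=1e-12):
            raise ValueError("coupling matrix must be symmetric")
        if np.abs(np.diag(omega)).max(initial=0.0) > 0:
            raise ValueError("coupling matrix must have zero diagonal")
        labels = tuple(self.labels) if self.labels else tuple(
            f"V{i + 1}" for i in range(p)
        )
        if len(labels) != p or len(set(labels)) != p:
            raise ValueError("need p unique labels")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "omega", (omega + omega.T) / 2.0)
        object.__setattr__(self, "labels", labels)

    @property
    def p(self) -> int:
        return self.tau.shape[0]

    def edge_index(self) -> list[tuple[int, int]]:
        """Canonical upper-triangle edge ordering (i < j), all pairs."""
        p = self.p
        return [(i, j) for i in range(p) for j in range(i + 1, p)]

    def edge_weights(self) -> np.ndarray:
        """Upper-triangle weights in `edge_index` order (length p(p-1)/2)."""
        iu = np.triu_indices(self.p, k=1)
        return self.omega[iu]

    def n_edges(self) -> int:
        return int(np.count_nonzero(self.edge_weights()))

    def to_edgelist(self) -> pd.DataFrame:
        """Nonzero edges only, columns node_i, node_j, weight, with i < j."""
        rows = [
            (self.labels[i], self.labels[j], self.omega[i, j])
            for i, j in self.edge_index()
            if self.omega[i, j] != 0.0
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega.copy(), index=list(self.labels), columns=list(self.labels))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, lab in enumerate(self.labels):
            g.add_node(lab, threshold=float(self.tau[i]))
        for i, j in self.edge_index():
            if self.omega[i, j] != 0.0:
                g.add_edge(self.labels[i], self.labels[j], weight=float(self.omega[i, j]))
        return g

    def save_edgelist(self, path: str | Path) -> None:
        self.to_edgelist().to_csv(path, index=False)

    def save_matrix(self, path: str | Path) -> None:
        self.to_matrix_frame().to_csv(path, index_label="item")

    def save_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))

    @classmethod
    def load_matrix(cls, path: str | Path, tau_path: str | Path | None = None) -> "IsingNetwork":
        frame = pd.read_csv(path, index_col=0)
        tau = (
            pd.read_csv(tau_path, index_col=0).iloc[:, 0].to_numpy()
            if tau_path is not None
            else np.zeros(frame.shape[0])
        )
        return cls(tau, frame.to_numpy(), tuple(str(c) for c in frame.columns))

    @classmethod
    def load_graphml(cls, path: str | Path) -> "IsingNetwork":
        g = nx.read_graphml(str(path))
        labels = tuple(g.nodes)
        p = len(labels)
        idx = {lab: k for k, lab in enumerate(labels)}
        tau = np.array([float(g.nodes[lab].get("threshold", 0.0)) for lab in labels])
        omega = np.zeros((p, p))
        for u, v, attrs in g.edges(data=True):
            w = float(attrs.get("weight", 0.0))
            omega[idx[u], idx[v]] = omega[idx[v], idx[u]] = w
        return cls(tau, omega, labels)


@dataclass(frozen=True)
class CentralityTable:
    """Per-node strength centrality with ranks and isolated-node flags."""

    labels: tuple[str, ...]
    strength: np.ndarray
    rank: np.ndarray = field(default=None)  # type: ignore[assignment]
    isolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        strength = np.asarray(self.strength, dtype=float)
        # ranks: 1 = highest strength; ties broken by label (lexicographic) order
        order = sorted(range(len(strength)), key=lambda i: (-strength[i], self.labels[i]))
        rank = np.empty(len(strength), dtype=int)
        rank[order] = np.arange(1, len(strength) + 1)
        object.__setattr__(self, "strength", strength)
        object.__setattr__(self, "rank", rank)
        object.__setattr__(self, "isolated", strength == 0.0)

    def to_dataframe(self, zscore: bool = True) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "label": list(self.labels),
                "strength": self.strength,
                "rank": self.rank,
                "isolated": self.isolated,
            }
        )
        if zscore:
            sd = self.strength.std(ddof=1) if len(self.strength) > 1 else 0.0
            frame["strength_z"] = (
                (self.strength - self.strength.mean()) / sd if sd > 0 else np.nan
            )
        return frame

    def top(self, k: int = 5) -> list[str]:
        """Labels of the k strongest nodes, best first."""
        return [self.labels[i] for i in np.argsort(self.rank)[:k]]


def strength_centrality(net: IsingNetwork) -> CentralityTable:
    """Strength of node i = sum_j |omega_ij|, the absolute sum of its edge weights."""
    return CentralityTable(net.labels, np.abs(net.omega).sum(axis=1))


def isolated_nodes(net: IsingNetwork) -> set[str]:
    """Labels of nodes incident to no nonzero edge (zero strength)."""
    return {net.labels[i] for i in np.flatnonzero(np.abs(net.omega).sum(axis=1) == 0.0)}


def fruchterman_reingold_layout(
    net: IsingNetwork, seed: int = 0, iterations: int = 50
) -> np.ndarray:
    """Weighted Fruchterman-Reingold coordinates, p x 2, deterministic given seed.

    Attraction scales with |edge weight|; edge sign is a display property
    (color), not a force, so positively and negatively coupled neighbours are
    both drawn together in proportion to the connection's magnitude.
    """
    g = nx.Graph()
    g.add_nodes_from(net.labels)
    for i, j in net.edge_index():
        if net.omega[i, j] != 0.0:
            g.add_edge(net.labels[i], net.labels[j], weight=abs(float(net.omega[i, j])))
    pos = nx.spring_layout(g, weight="weight", seed=seed, iterations=iterations)
    return np.array([pos[lab] for lab in net.labels])
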