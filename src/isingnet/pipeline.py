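"""One-call orchestration of the full network analysis.

`run_full_analysis` goes from a binary CSV (or a synthetic draw) to a
bundle of canonical numeric artifacts — descriptives, fitted network in
three serializations, centrality table, layout coordinates, stability
report — plus convenience plots and a machine-readable manifest echoing
every seed and setting.  Numeric CSV/JSON artifacts are the canonical
outputs; plots are conveniences.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import BinaryDataset, read_binary_items, summarize_total_scores, write_binary_items
from .model import EstimationConfig, IsingModel
from .network import fruchterman_reingold_layout
from .stability import (
    DEFAULT_DROP_GRID,
    bootstrap_network,
    case_dropping_bootstrap,
    centrality_difference_test,
    cs_coefficient,
    edge_ci,
    edge_difference_test,
)

__all__ = ["AnalysisConfig", "run_full_analysis", "generate_fixture"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a full run needs; echoed verbatim into the manifest."""

    input_path: str
    output_dir: str
    delimiter: str = ","
    has_header: bool = True
    ignore_columns: tuple[str, ...] = ()
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    bootstraps: int = 2000
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    casedrop_bootstraps: int = 50
    bootstrap_seed: int = 1
    casedrop_seed: int = 2
    layout_seed: int = 1
    ci_level: float = 0.95
    n_jobs: int = 1
    make_plots: bool = True
    run_stability: bool = True
    force: bool = False

    def to_jsonable(self) -> dict:
        out = asdict(self)
        out["estimation"] = asdict(self.estimation)
        return out


def _prepare_outdir(config: AnalysisConfig) -> Path:
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True (--force) to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    return out


def _difference_matrix(boot, positions, labels, level, kind) -> dict:
    """All-pairs boolean significance matrix for edges or nodes."""
    test = edge_difference_test if kind == "edge" else centrality_difference_test
    k = len(positions)
    sig = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            res = test(boot, positions[a], positions[b], level)
            sig[a, b] = sig[b, a] = res.significant
    return {"labels": labels, "significant": sig.tolist()}


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole pipeline; returns a dict of artifact paths and key numbers."""
    out = _prepare_outdir(config)
    stage = "read"
    try:
        data = read_binary_items(
            config.input_path,
            delimiter=config.delimiter,
            has_header=config.has_header,
            ignore_columns=config.ignore_columns,
        )
        logger.info("read %d rows x %d items from %s", data.n, data.p, config.input_path)

        stage = "descriptives"
        mean, sd = summarize_total_scores(data)
        descriptives = {
            "n": data.n,
            "p": data.p,
            "total_score_mean": mean,
            "total_score_sd": sd,
        }
        (out / "descriptives.json").write_text(json.dumps(descriptives, indent=2))

        stage = "estimation"
        results = IsingModel(data).fit(config.estimation)
        net = results.network
        net.save_edgelist(out / "network_edgelist.csv")
        net.save_matrix(out / "network_matrix.csv")
        net.save_graphml(out / "network.graphml")

        stage = "centrality"
        cent = results.strength()
        cent.to_dataframe(zscore=True).to_csv(out / "centrality.csv", index=False)

        stage = "layout"
        coords = fruchterman_reingold_layout(net, seed=config.layout_seed)
        pd.DataFrame(coords, columns=["x", "y"]).assign(label=list(net.labels)).to_csv(
            out / "layout.csv", index=False
        )

        stability_summary: dict = {}
        if config.run_stability:
            stage = "bootstrap"
            boot = bootstrap_network(
                data, config.bootstraps, config.bootstrap_seed,
                config.estimation, n_jobs=config.n_jobs,
            )
            cis = edge_ci(boot, config.ci_level)
            nonzero = [
                k for k, (i, j) in enumerate(boot.edge_index) if net.omega[i, j] != 0.0
            ]
            edge_labels = [
                f"{net.labels[boot.edge_index[k][0]]}-{net.labels[boot.edge_index[k][1]]}"
                for k in nonzero
            ]
            stage = "difference-tests"
            edge_pairs = [boot.edge_index[k] for k in nonzero]
            edge_diff = _difference_matrix(
                boot, edge_pairs, edge_labels, config.ci_level, "edge"
            )
            cent_diff = _difference_matrix(
                boot, list(range(net.p)), list(net.labels), config.ci_level, "node"
            )
            stage = "case-dropping"
            drop = case_dropping_bootstrap(
                data, config.drop_grid, config.casedrop_bootstraps,
                config.casedrop_seed, config.estimation, n_jobs=config.n_jobs,
            )
            cs = cs_coefficient(drop)
            stability_summary = {
                "bootstraps": config.bootstraps,
                "ci_level": config.ci_level,
                "edge_ci": {
                    f"{net.labels[i]}-{net.labels[j]}": [cis[k, 0], cis[k, 1]]
                    for k, (i, j) in enumerate(boot.edge_index)
                    if net.omega[i, j] != 0.0
                },
                "edge_difference_test": edge_diff,
                "centrality_difference_test": cent_diff,
                "case_dropping": {
                    "proportions": drop.proportions.tolist(),
                    "bootstraps_per_proportion": config.casedrop_bootstraps,
                    "mean_correlation": drop.correlations.mean(axis=1).tolist(),
                    "q05_correlation": np.quantile(drop.correlations, 0.05, axis=1).tolist(),
                },
                "cs_coefficient": cs,
                "seeds": {
                    "bootstrap": config.bootstrap_seed,
                    "case_dropping": config.casedrop_seed,
                },
            }
            (out / "stability.json").write_text(json.dumps(stability_summary, indent=2))
            logger.info("stability done: CS-coefficient %.2f", cs)

        if config.make_plots:
            stage = "plots"
            _plot_network(net, coords, out / "network.png")
            _plot_centrality(cent, out / "centrality.png")

        stage = "manifest"
        manifest = {
            "tool": {"name": "isingnet", "version": __version__},
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "platform": platform.platform(),
            "numpy": np.__version__,
            "config": config.to_jsonable(),
            "descriptives": descriptives,
            "n_edges": net.n_edges(),
            "cs_coefficient": stability_summary.get("cs_coefficient"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        logger.exception("pipeline failed during stage %r; partial artifacts kept in %s", stage, out)
        raise
    return {
        "output_dir": str(out),
        "descriptives": descriptives,
        "n_edges": net.n_edges(),
        "strongest": results.strength().top(5),
        "cs_coefficient": stability_summary.get("cs_coefficient"),
    }


def _plot_network(net, coords, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    wmax = np.abs(net.omega).max() or 1.0
    for i, j in net.edge_index():
        w = net.omega[i, j]
        if w == 0.0:
            continue
        ax.plot(
            coords[[i, j], 0], coords[[i, j], 1],
            color="tab:blue" if w > 0 else "tab:red",
            linewidth=3.0 * abs(w) / wmax, alpha=0.7, zorder=1,
        )
    ax.scatter(coords[:, 0], coords[:, 1], s=220, c="white", edgecolors="black", zorder=2)
    for k, lab in enumerate(net.labels):
        ax.annotate(lab, coords[k], ha="center", va="center", fontsize=6, zorder=3)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _plot_centrality(cent, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = cent.to_dataframe().sort_values("strength")
    fig, ax = plt.subplots(figsize=(5, 0.22 * len(frame) + 1))
    ax.plot(frame["strength"], frame["label"], "o-", markersize=3)
    ax.set_xlabel("strength")
    ax.grid(alpha=0.3)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def generate_fixture(spec, output_dir: str | Path, burn_in: int = 1000, thin: int = 10) -> dict:
    """Write a synthetic dataset plus its ground-truth network to a directory."""
    from .simulate import sample_npi_like

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, truth = sample_npi_like(spec, burn_in=burn_in, thin=thin)
    data_path = out / "dataset.csv"
    write_binary_items(data, data_path)
    truth.save_matrix(out / "truth_matrix.csv")
    truth.save_edgelist(out / "truth_edgelist.csv")
    truth.save_graphml(out / "truth.graphml")
    pd.Series(truth.tau, index=list(truth.labels), name="tau").to_csv(
        out / "truth_thresholds.csv", index_label="item"
    )
    logger.info("fixture written to %s (n=%d, p=%d)", out, data.n, data.p)
    return {"dataset": str(data_path), "truth": str(out / "truth_matrix.csv")}
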