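"""Heatmap and network views of a fitted communication table.

Both plots operate on the tidy result table for a single target — one
ligand-receptor pair (``"LIGAND→RECEPTOR"``) or one pathway
(``"pathway:LABEL"``). "Significant" means BH-adjusted p-value at or below
the threshold (default 0.1). Every plotted quantity is also emitted as a
machine-readable table so figures are auditable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["ccc_heatmap", "ccc_network", "select_target", "network_edges"]


def _targets(result: pd.DataFrame) -> list[str]:
    ids = result["ligand"].astype(str) + "→" + result["receptor"].astype(str)
    out: list[str] = []
    for t in ids:
        if t not in out:
            out.append(t)
    return out


def select_target(result: pd.DataFrame, target: str) -> pd.DataFrame:
    """Rows of one LR pair ("LIG→REC") or pathway ("pathway:LABEL")."""
    if target.startswith("pathway:"):
        mask = (result["ligand"] == target) & (result["receptor"] == target)
    else:
        lig, _, rec = target.partition("→")
        mask = (result["ligand"] == lig) & (result["receptor"] == rec)
    sub = result[mask]
    if len(sub) == 0:
        raise KeyError(
            f"target {target!r} not in results; available: {_targets(result)}"
        )
    return sub


def _estimate_matrix(sub: pd.DataFrame, threshold: float):
    senders = sorted(sub["sender_type"].unique())
    receivers = sorted(sub["receiver_type"].unique())
    est = np.full((len(senders), len(receivers)), np.nan)
    sig = np.zeros_like(est, dtype=bool)
    for _, row in sub.iterrows():
        a = senders.index(row["sender_type"])
        b = receivers.index(row["receiver_type"])
        est[a, b] = row["estimate"]
        sig[a, b] = (
            np.isfinite(row["p_adjusted"]) and row["p_adjusted"] <= threshold
        )
    return est, sig, senders, receivers


def ccc_heatmap(
    result: pd.DataFrame,
    target: str,
    path: str | Path,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Sender x receiver heatmap of communication estimates.

    Non-significant cells are masked (grey). Returns the plotted matrix as a
    DataFrame (sender rows, receiver columns; NaN where masked).
    """
    sub = select_target(result, target)
    est, sig, senders, receivers = _estimate_matrix(sub, threshold)
    shown = np.where(sig, est, np.nan)
    if not sig.any():
        logger.warning("no significant cell for %s at threshold %g", target, threshold)

    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * len(receivers), 1.2 + 0.6 * len(senders)))
    vmax = np.nanmax(np.abs(shown)) if np.isfinite(shown).any() else 1.0
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("#dddddd")
    im = ax.imshow(shown, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(receivers)), receivers, rotation=45, ha="right")
    ax.set_yticks(range(len(senders)), senders)
    ax.set_xlabel("receiver cell type")
    ax.set_ylabel("sender cell type")
    ax.set_title(target)
    fig.colorbar(im, ax=ax, label="communication strength")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return pd.DataFrame(shown, index=senders, columns=receivers)


def network_edges(result: pd.DataFrame, target: str, threshold: float = 0.1) -> pd.DataFrame:
    """Significant directed edges for one target (machine-readable form)."""
    sub = select_target(result, target)
    keep = sub["p_adjusted"].notna() & (sub["p_adjusted"] <= threshold)
    edges = sub[keep][
        ["sender_type", "receiver_type", "estimate", "p_adjusted"]
    ].copy()
    edges["sign"] = np.where(edges["estimate"] > 0, "positive", "negative")
    return edges.reset_index(drop=True)


def ccc_network(
    result: pd.DataFrame,
    target: str,
    path: str | Path,
    threshold: float = 0.1,
    edge_list_path: str | Path | None = None,
) -> pd.DataFrame:
    """Directed communication network between cell types.

    Solid edges are positive estimates, dashed edges negative; edge width is
    proportional to |estimate|. Self-loops (autocrine) are allowed. The edge
    list is written as TSV next to the figure (or at ``edge_list_path``).
    """
    sub = select_target(result, target)
    edges = network_edges(result, target, threshold)
    path = Path(path)
    if edge_list_path is None:
        edge_list_path = path.with_suffix(".edges.tsv")
    edges.to_csv(edge_list_path, sep="\t", index=False)

    nodes = sorted(set(sub["sender_type"]) | set(sub["receiver_type"]))
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    for _, e in edges.iterrows():
        graph.add_edge(e["sender_type"], e["receiver_type"], weight=abs(e["estimate"]),
                       positive=e["estimate"] > 0)
    pos = nx.circular_layout(sorted(graph.nodes()))

    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_nodes(graph, pos, ax=ax, node_color="#a6cee3", node_size=900)
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=9)
    if graph.number_of_edges():
        wmax = max(d["weight"] for *_, d in graph.edges(data=True))
        for u, v, d in graph.edges(data=True):
            nx.draw_networkx_edges(
                graph,
                pos,
                edgelist=[(u, v)],
                ax=ax,
                width=0.5 + 3.5 * d["weight"] / wmax,
                style="solid" if d["positive"] else "dashed",
                edge_color="#e31a1c" if d["positive"] else "#1f78b4",
                connectionstyle="arc3,rad=0.12",
                arrows=True,
            )
    ax.set_title(f"{target} (adj. p ≤ {threshold:g})")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return edges
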