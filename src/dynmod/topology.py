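"""Per-timestamp average node-importance summaries.

Average betweenness, closeness and local clustering coefficient characterize
how the network's global shape changes from stage to stage.  Shortest-path
measures are unweighted and normalized so values compare across timestamps
with different network sizes.  Mean retained-edge correlation is reported as
a fourth diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CoexpressionNetwork


@dataclass(frozen=True)
class TopologySummary:
    timestamp: int
    avg_betweenness: float
    avg_closeness: float
    avg_clustering_coefficient: float
    mean_edge_weight: float
    n_nodes: int
    n_edges: int


def summarize_topology(net: CoexpressionNetwork) -> TopologySummary:
    """Exact average betweenness, closeness and clustering of a connected net.

    Betweenness is shortest-path betweenness normalized by (n-1)(n-2)/2;
    closeness is (n-1)/sum of distances; clustering is the local transitivity
    with degree<2 nodes contributing 0.  All unweighted, no sampling.
    """
    if not net.is_connected():
        raise ValueError("network must be connected (upstream contract)")
    g = net.to_igraph()
    n = net.n_nodes
    if n < 3:
        raise ValueError("need at least 3 nodes")
    betw = np.asarray(g.betweenness(directed=False), float) / ((n - 1) * (n - 2) / 2.0)
    clos = np.asarray(g.closeness(normalized=True), float)
    clus = np.asarray(g.transitivity_local_undirected(mode="zero"), float)
    weights = [abs(w) for _, _, w in net.all_edges()]
    return TopologySummary(
        timestamp=net.timestamp,
        avg_betweenness=float(betw.mean()),
        avg_closeness=float(clos.mean()),
        avg_clustering_coefficient=float(clus.mean()),
        mean_edge_weight=float(np.mean(weights)) if weights else 0.0,
        n_nodes=n,
        n_edges=net.n_edges,
    )


def topology_trajectory(nets: list[CoexpressionNetwork]) -> list[TopologySummary]:
    """One summary per timestamp, in input order."""
    if len(nets) < 2:
        raise ValueError("need at least 2 networks for a trajectory")
    return [summarize_topology(net) for net in nets]


# ---------------------------------------------------------------------------
def write_topology_tsv(summaries: list[TopologySummary], path: str | Path) -> None:
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(path, sep="\t", index=False)


def write_topology_json(summaries: list[TopologySummary], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(s) for s in summaries], indent=1))
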