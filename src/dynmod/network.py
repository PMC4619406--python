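"""Per-timestamp weighted co-expression network construction.

A network is built from one timestamp's samples by (1) computing all pairwise
Pearson correlations over the selected genes, (2) keeping exactly the top
fraction ``q`` (default 10%) of gene pairs by correlation magnitude, and
(3) greedily adding the strongest inter-component correlations until the
graph is connected.  A power-law fit to the degree distribution is exposed as
a scale-free diagnostic (never a hard gate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse, stats
from scipy.sparse import csgraph

from .datasets import ExpressionDataset

Edge = tuple[str, str, float]


@dataclass
class CoexpressionNetwork:
    """Weighted undirected co-expression graph at one timestamp.

    ``edges`` are the threshold-retained pairs (weight = |Pearson r|, or the
    signed r in signed mode); ``augmented_edges`` are those added to enforce
    connectivity.  Edges are stored once with gene_a < gene_b lexicographically.
    """

    timestamp: int
    gene_ids: tuple[str, ...]
    edges: list[Edge]
    threshold_value: float
    augmented_edges: list[Edge] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges) + len(self.augmented_edges)

    def all_edges(self) -> list[Edge]:
        return self.edges + self.augmented_edges

    # ------------------------------------------------------------------
    def _index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def adjacency_sparse(self, absolute: bool = True) -> sparse.csr_matrix:
        """Symmetric weighted adjacency (CSR).  ``absolute`` maps weights to |w|."""
        idx = self._index()
        rows, cols, vals = [], [], []
        for a, b, w in self.all_edges():
            i, j = idx[a], idx[b]
            w = abs(w) if absolute else w
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        n = self.n_nodes
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        idx = self._index()
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b, _ in self.all_edges():
            deg[idx[a]] += 1
            deg[idx[b]] += 1
        return deg

    def is_connected(self) -> bool:
        adj = self.adjacency_sparse()
        ncomp, _ = csgraph.connected_components(adj, directed=False)
        return bool(ncomp == 1)

    def to_igraph(self):
        import igraph as ig

        idx = self._index()
        g = ig.Graph(n=self.n_nodes)
        g.vs["name"] = list(self.gene_ids)
        g.add_edges([(idx[a], idx[b]) for a, b, _ in self.all_edges()])
        g.es["weight"] = [abs(w) for _, _, w in self.all_edges()]
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=abs(w), augmented=False)
        for a, b, w in self.augmented_edges:
            g.add_edge(a, b, weight=abs(w), augmented=True)
        return g

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"# timestamp={self.timestamp}",
            f"# threshold_value={self.threshold_value!r}",
            "# genes=" + ",".join(self.gene_ids),
            "gene_a\tgene_b\tweight\taugmented",
        ]
        for a, b, w in self.edges:
            lines.append(f"{a}\t{b}\t{w!r}\t0")
        for a, b, w in self.augmented_edges:
            lines.append(f"{a}\t{b}\t{w!r}\t1")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoexpressionNetwork":
        timestamp, threshold, genes = 0, float("nan"), ()
        edges: list[Edge] = []
        augmented: list[Edge] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("# timestamp="):
                timestamp = int(line.split("=", 1)[1])
            elif line.startswith("# threshold_value="):
                threshold = float(line.split("=", 1)[1])
            elif line.startswith("# genes="):
                genes = tuple(line.split("=", 1)[1].split(","))
            elif line.startswith("#") or line.startswith("gene_a") or not line.strip():
                continue
            else:
                a, b, w, aug = line.split("\t")
                (augmented if aug == "1" else edges).append((a, b, float(w)))
        return cls(timestamp, genes, edges, threshold, augmented)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


# ---------------------------------------------------------------------------
def correlation_matrix(
    dataset: ExpressionDataset, genes: Sequence[str] | None = None
) -> np.ndarray:
    """Pearson correlation across the timestamp's samples (genes x genes).

    Zero-variance genes get correlation 0 with every partner (diagonal stays
    1), with a warning, rather than propagating NaN.
    """
    if genes is None:
        genes = dataset.gene_ids
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples to correlate")
    x = dataset.values.loc[list(genes)].to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance gene(s); their correlations are set to 0",
            stacklevel=2,
        )
        sd = np.where(zero, 1.0, sd)
    z = x / sd[:, None]
    corr = z @ z.T / x.shape[1]
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    corr = (corr + corr.T) / 2.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def threshold_network(
    corr: np.ndarray,
    gene_ids: Sequence[str],
    q: float = 0.10,
    timestamp: int = 0,
    signed: bool = False,
) -> CoexpressionNetwork:
    """Keep exactly ``ceil(q * P)`` of the P = n(n-1)/2 strongest gene pairs.

    Pairs are ranked by |r| descending (or signed r in ``signed`` mode); ties
    at the boundary are broken by lexicographic gene-id pair order so the
    result is deterministic.  ``threshold_value`` records the weakest retained
    correlation magnitude.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("edge fraction q must be in (0, 1]")
    n = corr.shape[0]
    if corr.shape != (n, n) or len(gene_ids) != n:
        raise ValueError("corr must be square and match gene_ids")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("corr must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    score = corr[iu, ju] if signed else np.abs(corr[iu, ju])
    n_pairs = len(score)
    n_keep = math.ceil(q * n_pairs)
    # rank of each node id in lexicographic order, for deterministic ties
    lex = np.empty(n, dtype=int)
    lex[np.argsort(np.asarray(gene_ids, dtype=object))] = np.arange(n)
    order = np.lexsort((lex[ju], lex[iu], -score))
    keep = order[:n_keep]
    edges: list[Edge] = []
    for t in keep:
        a, b = gene_ids[iu[t]], gene_ids[ju[t]]
        if b < a:
            a, b = b, a
        edges.append((a, b, float(corr[iu[t], ju[t]] if signed else abs(corr[iu[t], ju[t]]))))
    threshold_value = float(score[keep[-1]]) if n_keep else float("nan")
    return CoexpressionNetwork(
        timestamp=timestamp,
        gene_ids=tuple(gene_ids),
        edges=edges,
        threshold_value=threshold_value,
    )


def enforce_connectivity(net: CoexpressionNetwork, corr: np.ndarray) -> CoexpressionNetwork:
    """Greedily add the strongest |r| inter-component edge until connected.

    Existing edges are untouched; additions are recorded in
    ``augmented_edges``.  At most n-1 edges are ever added.
    """
    n = net.n_nodes
    if corr.shape != (n, n):
        raise ValueError("corr must match the network's gene set")
    adj = net.adjacency_sparse()
    ncomp, labels = csgraph.connected_components(adj, directed=False)
    augmented: list[Edge] = list(net.augmented_edges)
    absr = np.abs(corr).copy()
    np.fill_diagonal(absr, -1.0)
    existing = {(a, b) for a, b, _ in net.all_edges()}
    while ncomp > 1:
        cand = np.where(labels[:, None] != labels[None, :], absr, -1.0)
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)
        a, b = net.gene_ids[i], net.gene_ids[j]
        if b < a:
            a, b = b, a
        assert (a, b) not in existing
        augmented.append((a, b, float(absr[i, j])))
        existing.add((a, b))
        # merge the two components
        labels[labels == labels[j]] = labels[i]
        ncomp -= 1
    return CoexpressionNetwork(
        timestamp=net.timestamp,
        gene_ids=net.gene_ids,
        edges=list(net.edges),
        threshold_value=net.threshold_value,
        augmented_edges=augmented,
    )


def build_network(
    dataset: ExpressionDataset,
    genes: Sequence[str] | None = None,
    q: float = 0.10,
    timestamp: int = 0,
    signed: bool = False,
) -> CoexpressionNetwork:
    """Correlate, threshold and connect in one call."""
    corr = correlation_matrix(dataset, genes)
    ids = list(genes) if genes is not None else dataset.gene_ids
    net = threshold_network(corr, ids, q=q, timestamp=timestamp, signed=signed)
    return enforce_connectivity(net, corr)


def degree_distribution_fit(net: CoexpressionNetwork) -> tuple[float, float]:
    """Least-squares power-law fit of the degree distribution.

    Fits log(frequency) against log(degree) over observed degrees and returns
    ``(exponent, r_squared)`` where exponent is the positive slope magnitude.
    Degrees observed only once are dropped from the fit when enough distinct
    degrees remain — the singleton tail is pure sampling noise and otherwise
    dominates the residuals.  Purely diagnostic.
    """
    if net.n_nodes < 20:
        raise ValueError("need at least 20 nodes for a degree-distribution fit")
    deg = net.degrees()
    deg = deg[deg > 0]
    values, counts = np.unique(deg, return_counts=True)
    if len(values) < 3:
        raise ValueError("fewer than 3 distinct degrees; power-law fit undefined")
    stable = counts >= 2
    if stable.sum() >= 3:
        values, counts = values[stable], counts[stable]
    fit = stats.linregress(np.log(values), np.log(counts))
    return float(-fit.slope), float(fit.rvalue**2)
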