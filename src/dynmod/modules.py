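"""Overlapping functional-module detection by NMF on the weighted adjacency.

Each timestamp's network is factorized as A ~ W H with a preset inner
dimension k (default 50, the per-stage module count).  Gene g joins module j
whenever its loading H[j, g] is within a ratio c (default 0.8) of its best
loading, so modules may overlap while every gene belongs to at least one
module.  Empty modules are dropped, hence "at most k modules per stage".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CoexpressionNetwork
from .nmf import nmf_best_of


@dataclass(frozen=True)
class GeneModule:
    module_id: str
    timestamp: int
    gene_ids: frozenset
    loadings: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("a module must contain at least one gene")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModuleCatalog:
    """Per-timestamp lists of (possibly overlapping) modules."""

    k: int
    per_timestamp: dict[int, list[GeneModule]] = field(default_factory=dict)

    @property
    def timestamps(self) -> list[int]:
        return sorted(self.per_timestamp)

    def modules_at(self, t: int) -> list[GeneModule]:
        return self.per_timestamp[t]

    def all_modules(self) -> list[GeneModule]:
        return [m for t in self.timestamps for m in self.per_timestamp[t]]

    def __post_init__(self) -> None:
        for t, mods in self.per_timestamp.items():
            if len(mods) > self.k:
                raise ValueError(f"timestamp {t} has more than k={self.k} modules")


# ---------------------------------------------------------------------------
def detect_modules(
    net: CoexpressionNetwork,
    k: int = 50,
    seed: int = 0,
    n_restarts: int = 5,
    membership_ratio: float = 0.8,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> list[GeneModule]:
    """Overlapping modules of one network via best-of-restarts NMF.

    Returns at most ``k`` non-empty modules; identical seeds give identical
    module sets.  A warning is raised (and the best iterate used) if no
    restart reached the convergence tolerance.
    """
    n = net.n_nodes
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the {n} network nodes")
    A = net.adjacency_sparse()
    res = nmf_best_of(A, k, seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol)
    if not res.converged:
        warnings.warn(
            "NMF did not reach tolerance within max_iter; using best iterate",
            stacklevel=2,
        )
    H = res.H
    colmax = H.max(axis=0)
    member = H >= membership_ratio * colmax[None, :]
    # a gene whose loadings are all zero is attached to its argmax component
    dead = colmax <= 0
    if dead.any():
        member[:, dead] = False
        member[np.argmax(H[:, dead], axis=0), np.where(dead)[0]] = True
    modules: list[GeneModule] = []
    genes = np.asarray(net.gene_ids, dtype=object)
    for j in range(k):
        members = genes[member[j]]
        if len(members) == 0:
            continue
        loadings = tuple((str(g), float(H[j, gi])) for gi, g in zip(np.where(member[j])[0], members))
        modules.append(
            GeneModule(
                module_id=f"t{net.timestamp}m{j:02d}",
                timestamp=net.timestamp,
                gene_ids=frozenset(str(g) for g in members),
                loadings=loadings,
            )
        )
    return modules


def catalog_stages(
    nets: list[CoexpressionNetwork],
    k: int = 50,
    seed: int = 0,
    n_restarts: int = 5,
    membership_ratio: float = 0.8,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> ModuleCatalog:
    """Detect modules per timestamp; module ids are timestamp-prefixed."""
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    per_t: dict[int, list[GeneModule]] = {}
    for i, net in enumerate(nets):
        per_t[net.timestamp] = detect_modules(
            net,
            k=k,
            seed=seed + i,
            n_restarts=n_restarts,
            membership_ratio=membership_ratio,
            max_iter=max_iter,
            tol=tol,
        )
    return ModuleCatalog(k=k, per_timestamp=per_t)


# ---------------------------------------------------------------------------
def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def deduplicate_catalog(catalog: ModuleCatalog, jaccard_cutoff: float = 0.9) -> list[GeneModule]:
    """Union-find over near-identical module pairs (Jaccard >= cutoff).

    The earliest-timestamp (then smallest-id) member of each duplicate group
    survives; output is ordered by (timestamp, module_id).
    """
    mods = sorted(catalog.all_modules(), key=lambda m: (m.timestamp, m.module_id))
    parent = list(range(len(mods)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(mods)):
        for j in range(i + 1, len(mods)):
            if _jaccard(mods[i].gene_ids, mods[j].gene_ids) >= jaccard_cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    survivors = [mods[i] for i in range(len(mods)) if find(i) == i]
    return survivors


# ---------------------------------------------------------------------------
def write_gmt(modules: list[GeneModule], path: str | Path) -> None:
    """GMT: module_id <TAB> timestamp=<t> <TAB> gene ids."""
    lines = []
    for m in modules:
        lines.append("\t".join([m.module_id, f"timestamp={m.timestamp}", *sorted(m.gene_ids)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> list[GeneModule]:
    modules = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        mid, desc, genes = parts[0], parts[1], parts[2:]
        t = int(desc.split("=", 1)[1]) if desc.startswith("timestamp=") else 0
        modules.append(GeneModule(module_id=mid, timestamp=t, gene_ids=frozenset(genes)))
    return modules


def write_loadings_tsv(modules: list[GeneModule], path: str | Path) -> None:
    rows = []
    for m in modules:
        if m.loadings is None:
            continue
        for g, w in m.loadings:
            rows.append({"module_id": m.module_id, "gene_id": g, "loading": w})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
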