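"""Discriminative gene selection: rank genes by a patient-vs-control t-test.

The entry filter to the network analysis: from the full measured gene set,
keep the ``k`` genes whose expression best separates patients from healthy
controls (smallest two-sided Welch t-test p-values).  The same selected list
is reused for every timestamp's network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset


@dataclass(frozen=True)
class GeneRanking:
    gene_id: str
    t_statistic: float
    p_value: float
    rank: int


def rank_genes(patients: ExpressionDataset, controls: ExpressionDataset) -> list[GeneRanking]:
    """Per-gene two-sided Welch t-test of patient vs control means.

    Genes are ranked ascending by p-value with a deterministic tie-break by
    gene id.  A gene with zero variance in both groups and identical means is
    assigned t=0, p=1 by convention.
    """
    shared = [g for g in patients.gene_ids if g in set(controls.gene_ids)]
    if not shared:
        raise ValueError("patients and controls share no genes")
    if patients.n_samples < 2 or controls.n_samples < 2:
        raise ValueError("need at least 2 samples per group")

    a = patients.values.loc[shared].to_numpy(float)
    b = controls.values.loc[shared].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    # zero variance in both groups: identical means -> no evidence (t=0, p=1)
    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t[degenerate & equal_means] = 0.0
    p[degenerate & equal_means] = 1.0
    t[degenerate & ~equal_means] = np.inf
    p[degenerate & ~equal_means] = 0.0

    order = sorted(range(len(shared)), key=lambda i: (p[i], shared[i]))
    return [
        GeneRanking(shared[i], float(t[i]), float(p[i]), rank + 1)
        for rank, i in enumerate(order)
    ]


def select_top_genes(ranking: list[GeneRanking], k: int = 2000) -> list[str]:
    """The k genes with smallest p-values, in ranking order."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} ranked genes")
    if k < 0:
        raise ValueError("k must be non-negative")
    return [r.gene_id for r in ranking[:k]]


# ---------------------------------------------------------------------------
def write_ranking_tsv(ranking: list[GeneRanking], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in ranking],
            "t": [r.t_statistic for r in ranking],
            "p": [r.p_value for r in ranking],
            "rank": [r.rank for r in ranking],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
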