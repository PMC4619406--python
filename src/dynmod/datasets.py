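"""Expression matrices with per-sample metadata.

The basic container is a genes x samples matrix of log-scale intensities
together with a per-sample metadata table (group, timestamp, disease state,
response path).  Everything downstream — gene selection, per-stage network
construction, module detection — consumes this type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: metadata columns every dataset carries (missing ones are filled with "NA")
METADATA_COLUMNS = ("group", "timestamp", "disease_state", "response_path")


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix plus sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, log-scale intensities.
    metadata : pandas.DataFrame
        Indexed by sample id; columns include ``group`` (patient/control),
        ``timestamp``, ``disease_state`` and ``response_path``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if set(self.values.columns) != set(self.metadata.index):
            raise ValueError("metadata sample ids must match expression columns")
        # align metadata row order with the matrix column order
        self.metadata = self.metadata.reindex(self.values.columns)
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                self.metadata[col] = "NA"
        if self.values.isna().any().any():
            raise ValueError(
                "expression matrix contains missing values; inputs must be "
                "complete (no imputation is performed)"
            )

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # ------------------------------------------------------------------
    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}...")
        return ExpressionDataset(self.values.loc[list(genes)], self.metadata.copy())

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in dataset: {missing[:5]}...")
        return ExpressionDataset(
            self.values[list(samples)], self.metadata.loc[list(samples)].copy()
        )

    def where(self, **filters: str) -> "ExpressionDataset":
        """Subset samples by metadata equality filters, e.g. group="patient"."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in filters.items():
            if col not in self.metadata.columns:
                raise KeyError(f"unknown metadata column: {col}")
            mask &= self.metadata[col] == val
        return self.subset_samples(list(self.metadata.index[mask]))

    def patients(self) -> "ExpressionDataset":
        return self.where(group="patient")

    def controls(self) -> "ExpressionDataset":
        return self.where(group="control")

    # ------------------------------------------------------------------
    def to_tsv(self, expression_path: str | Path, metadata_path: str | Path | None = None) -> None:
        """Write the matrix (first column gene id, header sample ids) and metadata."""
        self.values.to_csv(expression_path, sep="\t", index_label="gene_id")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, expression_path: str | Path, metadata_path: str | Path) -> "ExpressionDataset":
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
        return cls(values, metadata)

    @staticmethod
    def combine(datasets: Iterable["ExpressionDataset"]) -> "ExpressionDataset":
        """Column-concatenate datasets sharing one gene universe."""
        datasets = list(datasets)
        if not datasets:
            raise ValueError("no datasets to combine")
        genes = datasets[0].gene_ids
        for ds in datasets[1:]:
            if ds.gene_ids != genes:
                raise ValueError("datasets must share an identical gene universe")
        values = pd.concat([ds.values for ds in datasets], axis=1)
        metadata = pd.concat([ds.metadata for ds in datasets], axis=0)
        return ExpressionDataset(values, metadata)
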