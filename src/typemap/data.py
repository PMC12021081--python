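"""Core data carriers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _densify(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


@dataclass
class AnnotatedMatrix:
    """A raw count matrix (cells x genes) with per-cell batch ids and an
    optional per-cell label (present for reference data).

    ``counts`` may be dense or scipy-sparse; entries must be non-negative.
    """

    counts: object
    gene_ids: list[str]
    cell_ids: list[str]
    batch: pd.Series | list[str] = field(default_factory=list)
    label: pd.Series | list[str] | None = None

    def __post_init__(self):
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(f"counts has {n_cells} rows but {len(self.cell_ids)} cell ids")
        if n_genes != len(self.gene_ids):
            raise ValueError(f"counts has {n_genes} columns but {len(self.gene_ids)} gene ids")
        self.batch = pd.Series(list(self.batch), index=self.cell_ids, dtype="object")
        if len(self.batch) != n_cells:
            raise ValueError("every cell needs a batch id")
        if self.label is not None:
            self.label = pd.Series(list(self.label), index=self.cell_ids, dtype="object")
            if len(self.label) != n_cells:
                raise ValueError("label length does not match cell count")
        mn = self.counts.min() if sp.issparse(self.counts) else np.min(self.counts) if n_cells and n_genes else 0
        if n_cells and n_genes and mn < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense_counts(self) -> np.ndarray:
        return _densify(self.counts).astype(np.float64)

    def subset(self, cell_mask=None, gene_mask=None) -> "AnnotatedMatrix":
        cell_mask = np.arange(self.n_cells) if cell_mask is None else np.asarray(cell_mask)
        gene_mask = np.arange(self.n_genes) if gene_mask is None else np.asarray(gene_mask)
        counts = self.counts.tocsr()[cell_mask][:, gene_mask] if sp.issparse(self.counts) \
            else np.asarray(self.counts)[np.ix_(cell_mask, gene_mask)]
        return AnnotatedMatrix(
            counts=counts,
            gene_ids=[self.gene_ids[i] for i in gene_mask],
            cell_ids=[self.cell_ids[i] for i in cell_mask],
            batch=self.batch.iloc[cell_mask].tolist(),
            label=None if self.label is None else self.label.iloc[cell_mask].tolist(),
        )


@dataclass
class FeaturePair:
    """Aligned reference/query feature matrices over g shared HVGs, plus the
    integer encodings the model consumes."""

    ref_features: np.ndarray          # m x g
    query_features: np.ndarray        # n x g
    hvg_ids: list[str]                # length g
    batch_index: np.ndarray           # (m+n,) ints over the combined batch set
    n_batches: int
    label_codes_ref: np.ndarray       # (m,) ints in [0, d)
    type_names: list[str]             # length d, sorted
    ref_cell_ids: list[str] = field(default_factory=list)
    query_cell_ids: list[str] = field(default_factory=list)
    batch_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        g = len(self.hvg_ids)
        if self.ref_features.shape[1] != g or self.query_features.shape[1] != g:
            raise ValueError("feature widths must equal the number of HVGs")
        m, n = self.n_ref, self.n_query
        if len(self.batch_index) != m + n:
            raise ValueError("batch_index must cover all reference + query cells")
        if len(self.label_codes_ref) != m:
            raise ValueError("one label code per reference cell required")
        d = len(self.type_names)
        if m and (self.label_codes_ref.min() < 0 or self.label_codes_ref.max() >= d):
            raise ValueError("reference label code out of range")

    @property
    def n_ref(self) -> int:
        return self.ref_features.shape[0]

    @property
    def n_query(self) -> int:
        return self.query_features.shape[0]

    @property
    def g(self) -> int:
        return len(self.hvg_ids)

    @property
    def d(self) -> int:
        return len(self.type_names)

    def all_features(self) -> np.ndarray:
        return np.vstack([self.ref_features, self.query_features])

    def domain_labels(self) -> np.ndarray:
        """0 for reference cells, 1 for query cells."""
        return np.concatenate([np.zeros(self.n_ref), np.ones(self.n_query)])
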