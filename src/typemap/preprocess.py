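"""Quality control, normalization, HVG selection, and feature assembly.

The pipeline mirrors the common scRNA-seq workflow: cells expressing too
few genes and genes seen in too few cells are dropped in a single round,
counts are scaled to 1e6 per cell and log1p-transformed, and per-batch
highly variable genes are chosen by mean-binned dispersion. The union of
per-batch HVGs restricted to genes present in every domain defines the
shared feature space.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import AnnotatedMatrix, FeaturePair

TARGET_SUM = 1e6


def _nonzero_per_row(counts) -> np.ndarray:
    if sp.issparse(counts):
        return np.asarray((counts > 0).sum(axis=1)).ravel()
    return (np.asarray(counts) > 0).sum(axis=1)


def _nonzero_per_col(counts) -> np.ndarray:
    if sp.issparse(counts):
        return np.asarray((counts > 0).sum(axis=0)).ravel()
    return (np.asarray(counts) > 0).sum(axis=0)


def qc_filter(raw: AnnotatedMatrix, min_genes_per_cell: int = 200,
              min_cells_per_gene: int = 3) -> AnnotatedMatrix:
    """Keep cells expressing >= ``min_genes_per_cell`` genes, then genes
    expressed in >= ``min_cells_per_gene`` of the surviving cells.

    One round only: cell pass first, gene pass on the survivors.
    """
    cell_keep = np.flatnonzero(_nonzero_per_row(raw.counts) >= min_genes_per_cell)
    if cell_keep.size == 0:
        raise ValueError(
            f"cell filter (min_genes_per_cell={min_genes_per_cell}) removed every cell")
    trimmed = raw.subset(cell_mask=cell_keep)
    gene_keep = np.flatnonzero(_nonzero_per_col(trimmed.counts) >= min_cells_per_gene)
    if gene_keep.size == 0:
        raise ValueError(
            f"gene filter (min_cells_per_gene={min_cells_per_gene}) removed every gene")
    return trimmed.subset(gene_mask=gene_keep)


def normalize(mat: AnnotatedMatrix) -> np.ndarray:
    """Scale each cell's counts to ``TARGET_SUM`` total, then log(1 + x)."""
    counts = mat.dense_counts()
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [mat.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"cells with zero total count (run qc_filter first): {bad}")
    return np.log1p(counts * (TARGET_SUM / totals[:, None]))


def binned_dispersion(normed: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Dispersion (variance/mean) of each gene, z-scored within equal-frequency
    mean bins so highly expressed genes do not dominate."""
    mean = normed.mean(axis=0)
    var = normed.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    n_bins = min(n_bins, max(1, np.unique(mean).size))
    quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    quantiles = np.unique(quantiles)
    bins = np.clip(np.searchsorted(quantiles, mean, side="right") - 1,
                   0, len(quantiles) - 2) if len(quantiles) > 1 else np.zeros(len(mean), int)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        members = bins == b
        mu, sd = disp[members].mean(), disp[members].std()
        z[members] = (disp[members] - mu) / sd if sd > 0 else 0.0
    return z


def select_hvgs(mats: list[AnnotatedMatrix], n_top: int = 1200,
                n_bins: int = 20) -> list[str]:
    """Per batch-matrix, rank genes by mean-binned dispersion and take the top
    ``n_top``; return the union across batches intersected with genes present
    in every input matrix (sorted for reproducibility)."""
    if not mats:
        raise ValueError("at least one matrix is required")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    union: set[str] = set()
    for mat in mats:
        k = n_top
        if k > mat.n_genes:
            warnings.warn(f"n_top={n_top} exceeds gene count {mat.n_genes}; clamping")
            k = mat.n_genes
        score = binned_dispersion(normalize(mat), n_bins=n_bins)
        order = np.argsort(-score, kind="stable")[:k]
        union.update(mat.gene_ids[i] for i in order)
    shared = set(mats[0].gene_ids)
    for mat in mats[1:]:
        shared &= set(mat.gene_ids)
    return sorted(union & shared)


def split_batches(mat: AnnotatedMatrix) -> list[AnnotatedMatrix]:
    """One AnnotatedMatrix per batch, preserving within-batch cell order."""
    return [mat.subset(cell_mask=np.flatnonzero((mat.batch == b).to_numpy()))
            for b in pd.unique(mat.batch)]


def assemble_features(ref: AnnotatedMatrix, query: AnnotatedMatrix,
                      hvg_ids: list[str]) -> FeaturePair:
    """Column-align both normalized matrices to ``hvg_ids``, encode batches
    over the combined batch set and labels in sorted-name order.

    Any label column on the query is deliberately ignored (held out as
    ground truth only).
    """
    if ref.label is None:
        raise ValueError("reference matrix must carry labels")

    def _subset_normalized(mat: AnnotatedMatrix) -> np.ndarray:
        pos = {gene: i for i, gene in enumerate(mat.gene_ids)}
        missing = [gene for gene in hvg_ids if gene not in pos]
        if missing:
            raise ValueError(f"genes missing from matrix: {missing[:10]}")
        return normalize(mat)[:, [pos[gene] for gene in hvg_ids]]

    batch_names = sorted(set(ref.batch) | set(query.batch))
    batch_code = {b: i for i, b in enumerate(batch_names)}
    type_names = sorted(set(ref.label))
    label_code = {t: i for i, t in enumerate(type_names)}
    return FeaturePair(
        ref_features=_subset_normalized(ref),
        query_features=_subset_normalized(query),
        hvg_ids=list(hvg_ids),
        batch_index=np.array([batch_code[b] for b in list(ref.batch) + list(query.batch)]),
        n_batches=len(batch_names),
        label_codes_ref=np.array([label_code[t] for t in ref.label]),
        type_names=type_names,
        ref_cell_ids=list(ref.cell_ids),
        query_cell_ids=list(query.cell_ids),
        batch_names=batch_names,
    )


def prepare(ref: AnnotatedMatrix, query: AnnotatedMatrix, n_top: int = 1200,
            n_bins: int = 20, min_genes_per_cell: int = 200,
            min_cells_per_gene: int = 3, hvg_on: str = "all") -> FeaturePair:
    """Full pipeline: QC both domains, select HVGs per batch, assemble features.

    ``hvg_on`` is "all" (HVG selection over every batch of both domains) or
    "reference" (reference batches only).
    """
    ref = qc_filter(ref, min_genes_per_cell, min_cells_per_gene)
    query = qc_filter(query, min_genes_per_cell, min_cells_per_gene)
    batches = split_batches(ref) + (split_batches(query) if hvg_on == "all" else [])
    shared = sorted(set(ref.gene_ids) & set(query.gene_ids))
    if not shared:
        raise ValueError("reference and query share no genes after QC")
    hvgs = select_hvgs(batches, n_top=n_top, n_bins=n_bins)
    hvgs = [gene for gene in hvgs if gene in set(shared)]
    if not hvgs:
        raise ValueError("no shared highly variable genes between domains")
    return assemble_features(ref, query, hvgs)
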