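"""Readers and writers for on-disk single-cell formats.

Supported inputs: MTX triplets (matrix.mtx + genes.tsv + barcodes.tsv),
dense delimited text, and .h5ad containers; cell metadata as TSV/CSV with
columns ``cell_id``, ``batch`` and optionally ``label``.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import AnnotatedMatrix, FeaturePair

META_COLUMNS = ("cell_id", "batch")


def read_metadata(path: str) -> pd.DataFrame:
    sep = "," if path.endswith(".csv") else "\t"
    meta = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks required columns: {missing}")
    return meta.set_index("cell_id")


def _attach_metadata(counts, gene_ids, cell_ids, meta: pd.DataFrame | None) -> AnnotatedMatrix:
    if meta is None:
        raise ValueError("cell metadata (cell_id, batch[, label]) is required")
    meta = meta.reindex(cell_ids)
    if meta["batch"].isna().any():
        missing = [c for c, b in zip(cell_ids, meta["batch"]) if pd.isna(b)][:5]
        raise ValueError(f"metadata missing batch for cells such as {missing}")
    label = meta["label"].tolist() if "label" in meta.columns and meta["label"].notna().all() else None
    return AnnotatedMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                           batch=meta["batch"].tolist(), label=label)


def read_mtx_dir(path: str, metadata: str | None = None) -> AnnotatedMatrix:
    """Read an MTX triplet directory (matrix.mtx, genes.tsv, barcodes.tsv).

    The matrix is stored genes x cells (the 10x convention) or cells x genes;
    orientation is resolved against the annotation file lengths.
    """
    mat = scipy.io.mmread(os.path.join(path, "matrix.mtx")).tocsr()
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape == (len(genes), len(cells)) and len(genes) != len(cells):
        mat = mat.T.tocsr()
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(f"matrix shape {mat.shape} does not match "
                         f"{len(cells)} barcodes x {len(genes)} genes")
    meta_path = metadata or os.path.join(path, "metadata.tsv")
    meta = read_metadata(meta_path) if os.path.exists(meta_path) else None
    return _attach_metadata(mat, genes, cells, meta)


def read_dense(path: str, metadata: str) -> AnnotatedMatrix:
    """Read a dense delimited text matrix with gene columns and cell rows."""
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    meta = read_metadata(metadata)
    return _attach_metadata(df.to_numpy(), df.columns.astype(str).tolist(),
                            df.index.astype(str).tolist(), meta)


def read_h5ad(path: str, batch_key: str = "batch", label_key: str = "label") -> AnnotatedMatrix:
    import anndata

    adata = anndata.read_h5ad(path)
    if batch_key not in adata.obs:
        raise ValueError(f"h5ad file lacks obs[{batch_key!r}]")
    label = adata.obs[label_key].astype(str).tolist() if label_key in adata.obs else None
    X = adata.X
    return AnnotatedMatrix(
        counts=X.tocsr() if sp.issparse(X) else np.asarray(X),
        gene_ids=adata.var_names.astype(str).tolist(),
        cell_ids=adata.obs_names.astype(str).tolist(),
        batch=adata.obs[batch_key].astype(str).tolist(),
        label=label,
    )


def load_annotated(path: str, metadata: str | None = None) -> AnnotatedMatrix:
    """Dispatch on extension: directory -> MTX triplet, .h5ad, else dense text."""
    if os.path.isdir(path):
        return read_mtx_dir(path, metadata=metadata)
    if path.endswith(".h5ad"):
        return read_h5ad(path)
    if metadata is None:
        raise ValueError("dense text input requires a metadata file")
    return read_dense(path, metadata)


def write_mtx_dir(mat: AnnotatedMatrix, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp.csr_matrix(mat.counts))
    pd.Series(mat.gene_ids).to_csv(os.path.join(path, "genes.tsv"), sep="\t",
                                   header=False, index=False)
    pd.Series(mat.cell_ids).to_csv(os.path.join(path, "barcodes.tsv"), sep="\t",
                                   header=False, index=False)
    meta = pd.DataFrame({"cell_id": mat.cell_ids, "batch": mat.batch.tolist()})
    if mat.label is not None:
        meta["label"] = mat.label.tolist()
    meta.to_csv(os.path.join(path, "metadata.tsv"), sep="\t", index=False)


def write_feature_pair(pair: FeaturePair, path: str) -> None:
    """Serialize a FeaturePair to an .h5ad container; the HVG list and label
    map go to ``uns``."""
    import anndata

    X = pair.all_features()
    obs = pd.DataFrame({
        "domain": ["reference"] * pair.n_ref + ["query"] * pair.n_query,
        "batch_index": pair.batch_index,
    }, index=(list(pair.ref_cell_ids) or [f"r{i}" for i in range(pair.n_ref)])
        + (list(pair.query_cell_ids) or [f"q{i}" for i in range(pair.n_query)]))
    adata = anndata.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pair.hvg_ids))
    adata.uns["hvg_ids"] = list(pair.hvg_ids)
    adata.uns["type_names"] = list(pair.type_names)
    adata.uns["n_batches"] = pair.n_batches
    adata.uns["batch_names"] = list(pair.batch_names)
    adata.uns["label_codes_ref"] = json.dumps([int(c) for c in pair.label_codes_ref])
    adata.write_h5ad(path)


def read_feature_pair(path: str) -> FeaturePair:
    import anndata

    adata = anndata.read_h5ad(path)
    is_ref = (adata.obs["domain"] == "reference").to_numpy()
    X = np.asarray(adata.X)
    return FeaturePair(
        ref_features=X[is_ref],
        query_features=X[~is_ref],
        hvg_ids=list(adata.uns["hvg_ids"]),
        batch_index=adata.obs["batch_index"].to_numpy().astype(int),
        n_batches=int(adata.uns["n_batches"]),
        label_codes_ref=np.asarray(json.loads(adata.uns["label_codes_ref"]), dtype=int),
        type_names=list(adata.uns["type_names"]),
        ref_cell_ids=adata.obs_names[is_ref].tolist(),
        query_cell_ids=adata.obs_names[~is_ref].tolist(),
        batch_names=list(adata.uns["batch_names"]),
    )
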