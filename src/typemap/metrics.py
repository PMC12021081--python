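"""Evaluation metrics: the bespoke ones implemented natively, the standard
integration suite delegated to external libraries where available."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


@dataclass
class EvaluationInput:
    embedding: np.ndarray        # cells x z
    batch: np.ndarray
    true_label: np.ndarray
    predicted_label: np.ndarray

    def __post_init__(self):
        n = len(self.embedding)
        for name in ("batch", "true_label", "predicted_label"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match embedding rows")


def accuracy(true_label, predicted_label) -> float:
    """Exact-match fraction over all queried cells."""
    t = np.asarray(true_label)
    p = np.asarray(predicted_label)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.size == 0:
        raise ValueError("cannot score an empty label vector")
    return float((t == p).mean())


def overcorrection_score(embedding: np.ndarray, true_label,
                         k: int = 30) -> tuple[float, float]:
    """Mean fraction of each cell's k nearest (Euclidean) neighbors carrying
    a different true label; lower is better.

    Returns ``(score, 1 - score)`` — the second value is the "higher is
    better" companion used in rank aggregation.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(true_label)
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neighbor_labels = labels[idx[:, 1:]]  # drop self
    score = float((neighbor_labels != labels[:, None]).mean())
    return score, 1.0 - score


def adjusted_shannon_index(true_label, predicted_label, d: int | None = None) -> float:
    """Purity of predicted types against (coarser) true labels, in [0, 1].

    For each predicted type j, H_j is the Shannon entropy (natural log) of
    the true-label proportions within j; the index is
    ``(log d - mean_j H_j) / log d`` with d the number of distinct true
    labels. 1 means every predicted type is pure; 0 means every predicted
    type is uniformly mixed over all d true labels.
    """
    t = np.asarray(true_label)
    p = np.asarray(predicted_label)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if d is None:
        d = len(np.unique(t))
    if d < 2:
        raise ValueError("adjusted Shannon index is undefined for d < 2")
    entropies = []
    for cluster in np.unique(p):
        members = t[p == cluster]
        _, counts = np.unique(members, return_counts=True)
        props = counts / counts.sum()
        entropies.append(float(-(props * np.log(props)).sum()))
    return (np.log(d) - np.mean(entropies)) / np.log(d)


def standard_metric_suite(data: EvaluationInput, n_clusters: int | None = None) -> dict:
    """Thin delegation of the standard integration metrics.

    ARI, NMI and the silhouette-based metrics come from scikit-learn;
    kBET, graph LISI, graph connectivity and isolated-label F1 require the
    optional ``scib`` package and are skipped with a warning when it is
    absent. All values are normalized to [0, 1]; ``overall`` is their mean.
    """
    from sklearn import metrics as skm

    out: dict[str, float] = {}
    out["ari"] = max(0.0, skm.adjusted_rand_score(data.true_label, data.predicted_label))
    out["nmi"] = skm.normalized_mutual_info_score(data.true_label, data.predicted_label)
    if len(np.unique(data.true_label)) > 1:
        out["asw_label"] = (skm.silhouette_score(data.embedding, data.true_label) + 1) / 2
    if len(np.unique(data.batch)) > 1:
        # good batch mixing = silhouette near 0 -> score near 1
        out["asw_batch"] = 1.0 - abs(skm.silhouette_score(data.embedding, data.batch))
    try:
        import scib  # noqa: F401
        import anndata

        adata = anndata.AnnData(X=data.embedding.astype(np.float32))
        adata.obs["batch"] = pd.Categorical(data.batch)
        adata.obs["label"] = pd.Categorical(data.true_label)
        adata.obsm["X_emb"] = data.embedding
        import scanpy as sc

        sc.pp.neighbors(adata, use_rep="X_emb")
        out["graph_connectivity"] = scib.metrics.graph_connectivity(adata, "label")
        out["ilisi"] = scib.metrics.ilisi_graph(adata, "batch", type_="embed",
                                                use_rep="X_emb")
        out["clisi"] = scib.metrics.clisi_graph(adata, "label", type_="embed",
                                                use_rep="X_emb")
        out["kbet"] = scib.metrics.kBET(adata, "batch", "label", type_="embed",
                                        embed="X_emb")
        out["isolated_f1"] = scib.metrics.isolated_labels_f1(adata, "label", "batch",
                                                             "X_emb")
    except ImportError:
        warnings.warn("optional dependency 'scib' not installed; kBET/LISI/"
                      "graph-connectivity/isolated-F1 skipped")
    out["overall"] = float(np.mean([v for k, v in out.items() if k != "overall"]))
    return out
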