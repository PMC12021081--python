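"""Final annotations, embeddings, unknown calls, and reports."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FeaturePair
from .network import Model
from .weighting import reported_confidence

DEFAULT_UNKNOWN_THRESHOLD = 0.25


@dataclass
class AnnotationResult:
    cell_id: str
    predicted_label: str
    confidence: float          # max softmax probability
    reported_weight: float     # R - 1, in (0, 1]
    unknown: bool
    embedding: np.ndarray      # z-vector


def embed_all(model: Model, features: FeaturePair) -> np.ndarray:
    """Latent coordinates for all reference + query cells (shared encoder,
    hence one coordinate system)."""
    return model.encode(features.all_features(), features.batch_index,
                        training=False).data


def annotate(model: Model, features: FeaturePair,
             unknown_threshold: float = DEFAULT_UNKNOWN_THRESHOLD
             ) -> list[AnnotationResult]:
    """Evaluation-mode annotation of the query cells.

    A cell is flagged unknown iff its reported weight (R - 1) falls below
    ``unknown_threshold``; its raw argmax label is preserved either way so
    downstream users can re-threshold. Argmax ties break lexicographically
    (lowest label code).
    """
    if model.cfg.g != features.g:
        raise ValueError(f"model expects {model.cfg.g} genes, features carry "
                         f"{features.g}; HVG sets do not match")
    if model.cfg.d != features.d:
        raise ValueError("model and features disagree on the number of types")
    latent_all = model.encode(features.all_features(), features.batch_index,
                              training=False)
    softmax_q = model.predict(latent_all, training=False).data[features.n_ref:]
    emb_q = latent_all.data[features.n_ref:]
    weights = reported_confidence(softmax_q)
    calls = softmax_q.argmax(axis=1)  # np.argmax returns the first (lowest) index on ties
    cell_ids = features.query_cell_ids or [f"q{i}" for i in range(features.n_query)]
    return [
        AnnotationResult(
            cell_id=cell_ids[i],
            predicted_label=features.type_names[calls[i]],
            confidence=float(softmax_q[i, calls[i]]),
            reported_weight=float(weights[i]),
            unknown=bool(weights[i] < unknown_threshold),
            embedding=emb_q[i],
        )
        for i in range(features.n_query)
    ]


def annotations_to_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [r.cell_id for r in results],
        "predicted_label": [r.predicted_label for r in results],
        "confidence": [r.confidence for r in results],
        "reported_weight": [r.reported_weight for r in results],
        "unknown": [r.unknown for r in results],
    })


def write_annotations(results: list[AnnotationResult], path: str) -> pd.DataFrame:
    frame = annotations_to_frame(results)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def weight_interval_report(results: list[AnnotationResult],
                           true_labels: list[str],
                           bin_width: float = 0.1) -> pd.DataFrame:
    """Accuracy and density per reported-weight interval.

    Bins are left-closed ``[0, w), [w, 2w), ..., [1-w, 1]`` (the last bin
    includes 1). Empty bins report accuracy NaN, not 0.
    """
    if len(true_labels) != len(results):
        raise ValueError("one true label per annotated cell required")
    weights = np.array([r.reported_weight for r in results])
    correct = np.array([r.predicted_label == t for r, t in zip(results, true_labels)])
    n_bins = int(round(1.0 / bin_width))
    idx = np.minimum((weights / bin_width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        members = idx == b
        count = int(members.sum())
        rows.append({
            "bin_low": b * bin_width,
            "bin_high": min((b + 1) * bin_width, 1.0),
            "count": count,
            "fraction": count / len(results) if results else np.nan,
            "accuracy": float(correct[members].mean()) if count else np.nan,
        })
    return pd.DataFrame(rows)
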