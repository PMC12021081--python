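"""Dynamic cell-type and cell weights computed from softmax outputs.

Each training epoch the current predictor output is condensed into:

* ``w_prime``  — per-type mean query softmax mass;
* ``w_ct``     — ``w_prime`` max-normalized, so the dominant type gets 1
  and interfering (reference-only) types drift toward 0;
* ``R``        — per-cell modified entropy ``1 + exp(sum_j p log p)`` in
  (1, 2]: 2 for one-hot confidence, ``1 + 1/d`` for a uniform row;
* ``w_rcell``  — reference cell weight ``w_ct[label] * R``;
* ``w_qcell``  — query cell weight, equal to ``R``;
* ``w_rqcell`` — the concatenation of both, halved, in [0, 1].

The confidence surfaced to users (and thresholded for "unknown" calls) is
``R - 1`` in (0, 1], i.e. ``exp(-entropy)`` of the softmax row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeightState", "cell_type_weight", "modified_entropy", "cell_weights",
           "reported_confidence", "compute_weight_state", "write_cell_report",
           "write_type_report"]


@dataclass
class WeightState:
    w_prime: np.ndarray            # (d,) in [0, 1]
    w_ct: np.ndarray               # (d,) in [0, 1], max exactly 1
    R: np.ndarray                  # (m+n,) in (1, 2]
    w_rcell: np.ndarray            # (m,) in [0, 2]
    w_qcell: np.ndarray            # (n,) in (1, 2]
    w_rqcell: np.ndarray           # (m+n,) in [0, 1]
    reported_query_weight: np.ndarray  # (n,) in (0, 1]


def _check_softmax(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("softmax input must be 2-D (cells x types)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("softmax rows must sum to 1")
    return p


def cell_type_weight(query_softmax: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean query softmax mass per type, and its max-normalized form."""
    p = _check_softmax(query_softmax)
    if p.shape[0] == 0:
        raise ValueError("need at least one query cell")
    w_prime = p.mean(axis=0)
    return w_prime, w_prime / w_prime.max()


def modified_entropy(softmax: np.ndarray) -> np.ndarray:
    """``R = 1 + exp(sum_j p log p)`` per row, with 0*log(0) = 0."""
    p = _check_softmax(softmax)
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return 1.0 + np.exp(plogp.sum(axis=1))


def reported_confidence(query_softmax: np.ndarray) -> np.ndarray:
    """``exp(-entropy) = R - 1`` per query cell, in (0, 1]."""
    return modified_entropy(query_softmax) - 1.0


def cell_weights(R: np.ndarray, w_ct: np.ndarray, ref_labels: np.ndarray,
                 m: int, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combine modified entropy and type weights into per-cell weights.

    ``R`` covers all m+n cells, reference first.
    """
    R = np.asarray(R, dtype=np.float64)
    if R.shape != (m + n,):
        raise ValueError(f"R must have length m+n={m + n}, got {R.shape}")
    ref_labels = np.asarray(ref_labels)
    if ref_labels.shape != (m,):
        raise ValueError("one label per reference cell required")
    if m and (ref_labels.min() < 0 or ref_labels.max() >= len(w_ct)):
        raise ValueError("reference label code out of range")
    w_rcell = np.asarray(w_ct)[ref_labels] * R[:m]
    w_qcell = R[m:]
    w_rqcell = np.concatenate([w_rcell, w_qcell]) / 2.0
    return w_rcell, w_qcell, w_rqcell


def compute_weight_state(softmax_all: np.ndarray, ref_labels: np.ndarray,
                         m: int, n: int) -> WeightState:
    """Full weight refresh from an evaluation-mode forward pass over all
    m reference + n query cells (reference rows first)."""
    softmax_all = _check_softmax(softmax_all)
    if softmax_all.shape[0] != m + n:
        raise ValueError("softmax must cover all reference and query cells")
    query_softmax = softmax_all[m:]
    w_prime, w_ct = cell_type_weight(query_softmax)
    R = modified_entropy(softmax_all)
    w_rcell, w_qcell, w_rqcell = cell_weights(R, w_ct, ref_labels, m, n)
    return WeightState(w_prime=w_prime, w_ct=w_ct, R=R, w_rcell=w_rcell,
                       w_qcell=w_qcell, w_rqcell=w_rqcell,
                       reported_query_weight=R[m:] - 1.0)


def write_cell_report(state: WeightState, cell_ids: list[str], m: int,
                      path: str) -> pd.DataFrame:
    n = len(cell_ids) - m
    report = pd.DataFrame({
        "cell_id": cell_ids,
        "domain": ["reference"] * m + ["query"] * n,
        "w_rqcell": state.w_rqcell,
        "reported_confidence": np.concatenate([state.R[:m] - 1.0,
                                               state.reported_query_weight]),
    })
    report.to_csv(path, sep="\t", index=False)
    return report


def write_type_report(state: WeightState, type_names: list[str],
                      path: str) -> pd.DataFrame:
    order = np.argsort(-state.w_ct, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    report = pd.DataFrame({
        "type_name": type_names,
        "w_prime": state.w_prime,
        "w_ct": state.w_ct,
        "rank": rank,
    })
    report.to_csv(path, sep="\t", index=False)
    return report
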