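"""The four loss terms and the combined adversarial objective.

The reported objective is

    L = L_r + alpha * L_q - beta * L_trans + gamma * L_margin

with the discriminators maximizing L and the encoder/predictor minimizing
it. Training realizes this minimax with a single gradient-descent step on
the surrogate ``L_r + alpha*L_q + beta*L_trans_grl + gamma*L_margin``,
where ``L_trans_grl`` is the transfer loss computed with the gradient
reversal layer between encoder and discriminator bank: descending the
surrogate descends the discriminators' cross-entropy (their argmax of L)
while ascending it through the encoder.

Per-cell importance weights are treated as constants (no gradient flows
through them), and each sum is normalized by the number of contributing
cells so the default alpha/beta/gamma remain comparable across dataset
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor

EPS = 1e-8


@dataclass
class LossConfig:
    alpha: float = 0.5
    beta: float = 0.5
    gamma: float = 1.0
    pseudo_threshold: float = 0.90
    focal_gamma: float = 2.0
    ref_onehot_in_transfer: bool = True

    def __post_init__(self):
        if not 0 < self.pseudo_threshold < 1:
            raise ValueError("pseudo_threshold must be in (0, 1)")


def focal_classification_loss(softmax, labels: np.ndarray, per_cell_weight: np.ndarray,
                              focal_gamma: float = 2.0) -> Tensor:
    """Weighted focal loss, mean over the contributing cells.

    With ``focal_gamma=0`` each term reduces to weighted cross-entropy
    ``-w * log p_true``. With no cells the loss is identically 0.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return Tensor(0.0)
    p = as_tensor(softmax)
    w = np.asarray(per_cell_weight, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("per-cell weights must be non-negative")
    if labels.min() < 0 or labels.max() >= p.shape[1]:
        raise ValueError("label code out of range")
    rows = np.arange(labels.size)
    p_true = p.gather(rows, labels)
    fl = (1.0 - p_true) ** focal_gamma * (-(p_true.clip_min(EPS).log()))
    return (Tensor(w) * fl).sum() / labels.size


def assign_pseudo_labels(query_softmax: np.ndarray,
                         threshold: float = 0.90) -> tuple[np.ndarray, np.ndarray]:
    """Cells whose maximum softmax probability strictly exceeds ``threshold``
    receive their argmax as a pseudo-label.

    Returns (boolean mask over query cells, labels for the masked cells).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(query_softmax, dtype=np.float64)
    mask = p.max(axis=1) > threshold
    return mask, p.argmax(axis=1)[mask]


def binary_cross_entropy(prob: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=np.float64)
    return -(Tensor(t) * prob.clip_min(EPS).log()
             + Tensor(1.0 - t) * (1.0 - prob).clip_min(EPS).log())


def transfer_loss(latent: Tensor, domain_labels: np.ndarray, p_rq: np.ndarray,
                  w_ct: np.ndarray, w_rqcell: np.ndarray, model,
                  use_reversal: bool = True) -> Tensor:
    """Type-weighted domain cross-entropy over the discriminator bank.

    ``p_rq`` holds each cell's per-type coefficient (reference one-hot or
    softmax, query softmax) and is treated as a constant. The latent passes
    through the gradient reversal layer before the bank when
    ``use_reversal`` so a single backward realizes the minimax.
    """
    p_rq = np.asarray(p_rq, dtype=np.float64)
    w_rqcell = np.asarray(w_rqcell, dtype=np.float64)
    n_cells = latent.shape[0]
    if p_rq.shape[0] != n_cells or len(w_rqcell) != n_cells:
        raise ValueError("coefficient shapes must cover every cell")
    lat = model.reverse(latent) if use_reversal else latent
    total = Tensor(0.0)
    for j in range(p_rq.shape[1]):
        if w_ct[j] == 0:
            continue  # interfering type: its discriminator drops out entirely
        bce = binary_cross_entropy(model.discriminate(lat, j), domain_labels)
        coeff = w_ct[j] * w_rqcell * p_rq[:, j]
        total = total + (Tensor(coeff) * bce).sum() / n_cells
    return total


def margin_loss(ref_softmax, ref_labels: np.ndarray, w_rcell: np.ndarray,
                d: int) -> Tensor:
    """Entropy of the renormalized wrong-class mass, weighted and negated.

    Per cell, with ``q_j = p_j / (1 - p_true)`` over the wrong classes, the
    inner sum ``sum_j q_j ln q_j / ln(d-1)`` lies in [-1, 0]: -1 when the
    wrong-class mass is uniform, 0 when concentrated on one class. For
    ``d = 2`` the normalizer ln(d-1) vanishes and is replaced by 1 (the
    inner sum is then identically 0).
    """
    ref_labels = np.asarray(ref_labels)
    m = ref_labels.size
    if m == 0:
        return Tensor(0.0)
    if d < 2:
        raise ValueError("margin loss needs d >= 2")
    p = as_tensor(ref_softmax)
    rows = np.arange(m)
    p_true = p.gather(rows, ref_labels).reshape(-1, 1)
    q = p / (1.0 - p_true).clip_min(EPS)
    wrong = np.ones_like(p.data)
    wrong[rows, ref_labels] = 0.0
    inner = (q * q.clip_min(EPS).log() * Tensor(wrong)).sum(axis=1)
    normalizer = np.log(d - 1) if d > 2 else 1.0
    w = np.asarray(w_rcell, dtype=np.float64)
    return (Tensor(w) * inner).sum() / (normalizer * m)


def total_objective(L_r, L_q, L_trans, L_margin, cfg: LossConfig) -> float:
    """The reported objective ``L_r + a*L_q - b*L_trans + g*L_margin``."""
    values = [float(t.data) if isinstance(t, Tensor) else float(t)
              for t in (L_r, L_q, L_trans, L_margin)]
    if not all(np.isfinite(values)):
        raise FloatingPointError(f"non-finite loss terms: "
                                 f"L_r={values[0]}, L_q={values[1]}, "
                                 f"L_trans={values[2]}, L_margin={values[3]}")
    return values[0] + cfg.alpha * values[1] - cfg.beta * values[2] + cfg.gamma * values[3]


def training_surrogate(L_r: Tensor, L_q: Tensor, L_trans_grl: Tensor,
                       L_margin: Tensor, cfg: LossConfig) -> Tensor:
    """The quantity actually minimized each step; with the reversal layer in
    ``L_trans_grl`` its gradients realize the published minimax exactly."""
    return (as_tensor(L_r) + cfg.alpha * as_tensor(L_q)
            + cfg.beta * as_tensor(L_trans_grl) + cfg.gamma * as_tensor(L_margin))


def transfer_coefficients(ref_labels: np.ndarray, query_softmax: np.ndarray,
                          d: int, ref_onehot: bool = True,
                          ref_softmax: np.ndarray | None = None) -> np.ndarray:
    """Per-cell, per-type coefficients p_rq for the transfer loss: reference
    cells by one-hot true label (or their softmax), query cells by softmax."""
    ref_labels = np.asarray(ref_labels)
    if ref_onehot or ref_softmax is None:
        ref_part = np.zeros((ref_labels.size, d))
        ref_part[np.arange(ref_labels.size), ref_labels] = 1.0
    else:
        ref_part = np.asarray(ref_softmax, dtype=np.float64)
    return np.vstack([ref_part, np.asarray(query_softmax, dtype=np.float64)])
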