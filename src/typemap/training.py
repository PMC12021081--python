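"""Optimization loop: weight refresh, pseudo-labels, schedule, early stop.

Each epoch:

1. a full evaluation-mode forward pass refreshes the weight state and the
   pseudo-label set (both frozen for the rest of the epoch);
2. shuffled minibatches mixing reference and query cells take one
   gradient step each on the adversarial surrogate;
3. the learning rate decays to 60% of its initial value every 5 epochs;
4. the total objective on a stratified 10% reference hold-out is
   monitored; training halts after ``patience`` epochs without an
   improvement of at least ``min_delta`` and the best checkpoint is
   returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import objectives, weighting
from ._autograd import Tensor
from .data import FeaturePair
from .network import Model, ModelConfig
from .objectives import LossConfig
from .weighting import WeightState


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 5e-4
    lr_decay_factor: float = 0.6
    lr_decay_every: int = 5
    max_epochs: int = 50
    patience: int = 10
    batch_size: int = 1024
    seed: int = 0
    min_delta: float = 1e-4
    holdout_frac: float = 0.1


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    """lr for a 0-based epoch index: ``lr * factor ** (epoch // every)``."""
    return cfg.lr * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def refresh_state(model: Model, features: FeaturePair,
                  loss_cfg: LossConfig | None = None
                  ) -> tuple[WeightState, np.ndarray, np.ndarray, np.ndarray]:
    """Evaluation-mode full pass: weight state, pseudo-label mask and labels,
    and the full softmax matrix."""
    loss_cfg = loss_cfg or LossConfig()
    latent = model.encode(features.all_features(), features.batch_index, training=False)
    softmax_all = model.predict(latent, training=False).data
    state = weighting.compute_weight_state(softmax_all, features.label_codes_ref,
                                           features.n_ref, features.n_query)
    mask, labels = objectives.assign_pseudo_labels(softmax_all[features.n_ref:],
                                                   loss_cfg.pseudo_threshold)
    return state, mask, labels, softmax_all


def _stratified_holdout(labels: np.ndarray, frac: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of held-out reference cells, stratified by type."""
    held = np.zeros(labels.size, dtype=bool)
    if frac <= 0:
        return held
    for code in np.unique(labels):
        members = np.flatnonzero(labels == code)
        k = max(1, int(round(frac * members.size))) if members.size > 1 else 0
        held[rng.permutation(members)[:k]] = True
    return held


def _holdout_objective(model: Model, features: FeaturePair, held: np.ndarray,
                       state: WeightState, loss_cfg: LossConfig) -> float:
    """Monitored quantity: reference-side terms of the objective on the
    held-out split (the only labeled signal available)."""
    if not held.any():
        return np.nan
    latent = model.encode(features.ref_features[held],
                          features.batch_index[:features.n_ref][held], training=False)
    p = model.predict(latent, training=False)
    labels = features.label_codes_ref[held]
    w = state.w_rcell[held]
    L_r = objectives.focal_classification_loss(p, labels, w, loss_cfg.focal_gamma)
    L_margin = objectives.margin_loss(p, labels, w, features.d)
    return float(L_r.data) + loss_cfg.gamma * float(L_margin.data)


def train(features: FeaturePair, model_cfg: ModelConfig | None = None,
          loss_cfg: LossConfig | None = None, train_cfg: TrainConfig | None = None,
          log_path: str | None = None) -> tuple[Model, list[dict]]:
    """Run the full optimization and return (best model, per-epoch log)."""
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    if model_cfg is None:
        model_cfg = ModelConfig(g=features.g, d=features.d,
                                n_batches=features.n_batches)
    if model_cfg.d < 2:
        raise ValueError("training requires at least 2 reference cell types")

    rng = np.random.default_rng(train_cfg.seed)
    model = Model(model_cfg, seed=train_cfg.seed)
    optimizer = Adam(model.parameters(), lr=train_cfg.lr,
                     weight_decay=train_cfg.weight_decay)

    m, n = features.n_ref, features.n_query
    X = features.all_features()
    domains = features.domain_labels()
    held = _stratified_holdout(features.label_codes_ref, train_cfg.holdout_frac, rng)
    train_idx = np.concatenate([np.flatnonzero(~held), m + np.arange(n)])

    best_value = np.inf
    best_state = model.state_copy()
    best_epoch = -1
    bad_epochs = 0
    log: list[dict] = []

    for epoch in range(train_cfg.max_epochs):
        state, pseudo_mask, pseudo_labels, softmax_all = refresh_state(
            model, features, loss_cfg)
        pseudo_idx = m + np.flatnonzero(pseudo_mask)
        pseudo_label_of = dict(zip(pseudo_idx.tolist(), pseudo_labels.tolist()))
        p_rq = objectives.transfer_coefficients(
            features.label_codes_ref, softmax_all[m:], features.d,
            ref_onehot=loss_cfg.ref_onehot_in_transfer, ref_softmax=softmax_all[:m])

        optimizer.lr = learning_rate_at(epoch, train_cfg)
        order = rng.permutation(train_idx)
        sums = {"L_r": 0.0, "L_q": 0.0, "L_trans": 0.0, "L_margin": 0.0}
        n_steps = 0
        diverged = False
        for start in range(0, order.size, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            is_ref = idx < m
            ref_idx = idx[is_ref]
            q_idx = idx[~is_ref]
            pseudo_in_batch = np.array([i for i in q_idx if i in pseudo_label_of],
                                       dtype=int)

            latent = model.encode(X[idx], features.batch_index[idx], training=True)
            p = model.predict(latent, training=True)

            pos = {cell: row for row, cell in enumerate(idx)}
            ref_rows = np.array([pos[i] for i in ref_idx], dtype=int)
            L_r = objectives.focal_classification_loss(
                p.take_rows(ref_rows) if ref_rows.size else p,
                features.label_codes_ref[ref_idx],
                state.w_rcell[ref_idx], loss_cfg.focal_gamma)
            if pseudo_in_batch.size:
                q_rows = np.array([pos[i] for i in pseudo_in_batch], dtype=int)
                L_q = objectives.focal_classification_loss(
                    p.take_rows(q_rows),
                    np.array([pseudo_label_of[i] for i in pseudo_in_batch]),
                    state.w_qcell[pseudo_in_batch - m], loss_cfg.focal_gamma)
            else:
                L_q = Tensor(0.0)
            L_trans = objectives.transfer_loss(
                latent, domains[idx], p_rq[idx], state.w_ct,
                state.w_rqcell[idx], model, use_reversal=True)
            L_margin = objectives.margin_loss(
                p.take_rows(ref_rows) if ref_rows.size else p,
                features.label_codes_ref[ref_idx],
                state.w_rcell[ref_idx], features.d) if ref_rows.size else Tensor(0.0)

            try:
                reported = objectives.total_objective(L_r, L_q, L_trans, L_margin,
                                                      loss_cfg)
            except FloatingPointError:
                diverged = True
                break
            surrogate = objectives.training_surrogate(L_r, L_q, L_trans, L_margin,
                                                      loss_cfg)
            model.zero_grad()
            surrogate.backward()
            optimizer.step()

            for key, t in (("L_r", L_r), ("L_q", L_q), ("L_trans", L_trans),
                           ("L_margin", L_margin)):
                sums[key] += float(t.data)
            n_steps += 1
            del reported

        if diverged or n_steps == 0:
            model.load_state(best_state)
            break

        means = {k: v / n_steps for k, v in sums.items()}
        monitor = _holdout_objective(model, features, held, state, loss_cfg)
        entry = {
            "epoch": epoch,
            **means,
            "total": objectives.total_objective(means["L_r"], means["L_q"],
                                                means["L_trans"], means["L_margin"],
                                                loss_cfg),
            "u": int(pseudo_mask.sum()),
            "lr": optimizer.lr,
            "monitor": monitor,
        }
        log.append(entry)

        value = monitor if np.isfinite(monitor) else entry["total"]
        if value < best_value - train_cfg.min_delta:
            best_value = value
            best_state = model.state_copy()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_cfg.patience:
                break

    model.load_state(best_state)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    if best_epoch < 0 and log:
        best_epoch = log[-1]["epoch"]
    return model, log


def train_config_to_dict(cfg: TrainConfig) -> dict:
    return asdict(cfg)
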