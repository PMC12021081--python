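"""The three sub-networks and the trainable batch-embedding table.

* feature extractor E: three fully connected layers with output widths
  [g+c], [512], [128], each of the first two followed by ReLU + dropout;
* label predictor P: two fully connected layers [128] -> [d] with a ReLU +
  dropout between them, followed by softmax;
* a bank of d structurally identical two-layer discriminators mapping the
  128-d latent to P(cell is query), fed through a gradient-reversal layer
  during training.

Batch identity enters as a trainable c-dimensional embedding concatenated
to the gene features; embeddings are randomly initialized and updated by
the optimizer like any other parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autograd import Tensor, as_tensor, concat, reverse_gradient

CHECKPOINT_TAG = "typemap-checkpoint-v1"


@dataclass
class ModelConfig:
    g: int                      # number of input genes (shared HVGs)
    d: int                      # number of reference cell types
    n_batches: int
    c: int = 10                 # batch-embedding dimension
    z: int = 128                # latent dimension
    hidden_e: int = 512
    disc_hidden: int = 64
    dropout_rate: float = 0.2
    grl_scale: float = 1.0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.grl_scale <= 0:
            raise ValueError("grl_scale must be positive")
        for name in ("g", "d", "n_batches", "c", "z", "hidden_e", "disc_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


class Linear:
    """Dense layer with PyTorch-style fan-in uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        bound = 1.0 / np.sqrt(n_in)
        if zero_init:
            self.W = Tensor(np.zeros((n_in, n_out)), requires_grad=True)
            self.b = Tensor(np.zeros(n_out), requires_grad=True)
        else:
            self.W = Tensor(rng.uniform(-bound, bound, (n_in, n_out)), requires_grad=True)
            self.b = Tensor(rng.uniform(-bound, bound, n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def softmax(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)


def _dropout(x: Tensor, rate: float, rng: np.random.Generator,
             training: bool) -> Tensor:
    if not training or rate == 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class Model:
    """Holds all parameters (theta_E, theta_P, theta_D bank, batch embeddings)
    and exposes the forward operations."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        width = cfg.g + cfg.c
        self.enc = [Linear(width, width, rng),
                    Linear(width, cfg.hidden_e, rng),
                    Linear(cfg.hidden_e, cfg.z, rng)]
        self.pred = [Linear(cfg.z, cfg.z, rng),
                     Linear(cfg.z, cfg.d, rng)]
        self.disc = [[Linear(cfg.z, cfg.disc_hidden, rng),
                      Linear(cfg.disc_hidden, 1, rng)] for _ in range(cfg.d)]
        self.batch_embeddings = Tensor(rng.standard_normal((cfg.n_batches, cfg.c)),
                                       requires_grad=True)
        self._drop_rng = np.random.default_rng(seed + 1)

    # -- parameter access ---------------------------------------------

    def encoder_parameters(self) -> list[Tensor]:
        return [p for layer in self.enc for p in layer.parameters] + [self.batch_embeddings]

    def predictor_parameters(self) -> list[Tensor]:
        return [p for layer in self.pred for p in layer.parameters]

    def discriminator_parameters(self, j: int | None = None) -> list[Tensor]:
        banks = self.disc if j is None else [self.disc[j]]
        return [p for bank in banks for layer in bank for p in layer.parameters]

    def parameters(self) -> list[Tensor]:
        return (self.encoder_parameters() + self.predictor_parameters()
                + self.discriminator_parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- forward operations -------------------------------------------

    def encode(self, features, batch_index: np.ndarray,
               training: bool = False) -> Tensor:
        """Concatenate gene features with batch embeddings and map to the
        z-dimensional latent space."""
        x = as_tensor(features)
        if x.shape[1] != self.cfg.g:
            raise ValueError(f"expected {self.cfg.g} gene features, got {x.shape[1]}")
        batch_index = np.asarray(batch_index)
        if batch_index.size and (batch_index.min() < 0
                                 or batch_index.max() >= self.cfg.n_batches):
            raise ValueError("batch index out of range for the embedding table")
        emb = self.batch_embeddings.take_rows(batch_index)
        h = concat([x, emb], axis=1)
        h = _dropout(self.enc[0](h).relu(), self.cfg.dropout_rate, self._drop_rng, training)
        h = _dropout(self.enc[1](h).relu(), self.cfg.dropout_rate, self._drop_rng, training)
        return self.enc[2](h)

    def predict_logits(self, latent: Tensor, training: bool = False) -> Tensor:
        h = _dropout(self.pred[0](latent).relu(), self.cfg.dropout_rate,
                     self._drop_rng, training)
        return self.pred[1](h)

    def predict(self, latent: Tensor, training: bool = False) -> Tensor:
        """Softmax probabilities over the d reference cell types."""
        return softmax(self.predict_logits(latent, training=training))

    def discriminate(self, latent: Tensor, type_index: int) -> Tensor:
        """P(cell is query) from discriminator ``type_index``; 0 denotes the
        reference domain and 1 the query domain."""
        if not 0 <= type_index < self.cfg.d:
            raise ValueError(f"type_index {type_index} outside [0, {self.cfg.d})")
        layers = self.disc[type_index]
        h = layers[0](latent).relu()
        return layers[1](h).sigmoid().reshape(-1)

    def reverse(self, latent: Tensor) -> Tensor:
        return reverse_gradient(latent, self.cfg.grl_scale)

    # -- persistence ---------------------------------------------------

    def _named_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {"batch_embeddings": self.batch_embeddings.data}
        for group, layers in (("enc", self.enc), ("pred", self.pred)):
            for i, layer in enumerate(layers):
                arrays[f"{group}{i}_W"] = layer.W.data
                arrays[f"{group}{i}_b"] = layer.b.data
        for j, bank in enumerate(self.disc):
            for i, layer in enumerate(bank):
                arrays[f"disc{j}_{i}_W"] = layer.W.data
                arrays[f"disc{j}_{i}_b"] = layer.b.data
        return arrays

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named_arrays().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, array in self._named_arrays().items():
            array[...] = state[name]

    def save(self, path: str, extra: dict | None = None) -> None:
        meta = {"format": CHECKPOINT_TAG, "config": asdict(self.cfg),
                "extra": extra or {}}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self._named_arrays())

    @classmethod
    def load(cls, path: str) -> tuple["Model", dict]:
        with np.load(path if str(path).endswith(".npz") else f"{path}.npz",
                     allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            if meta.get("format") != CHECKPOINT_TAG:
                raise ValueError(f"not a recognized checkpoint: {meta.get('format')}")
            model = cls(ModelConfig(**meta["config"]))
            model.load_state({k: archive[k] for k in archive.files if k != "__meta__"})
        return model, meta.get("extra", {})
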