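"""Compact six-layer CNN over bispectrum images; the 64-unit dense layer is the
feature extractor consumed by the forest classifier.

Layer chain (channels-last, SAME conv padding, VALID pooling):

    256x256x1 -> conv 24@5x5 /(4,2) ReLU -> 64x128x24
              -> conv 48@5x5 /(1,1) ReLU -> 64x128x48
              -> maxpool 4x2 /(4,2)      -> 16x64x48
              -> conv 16@3x3 /(1,1) ReLU -> 16x64x16
              -> flatten 16384 -> dense 64 (ReLU) -> softmax head 11

The three conv layers hold 624 + 28,848 + 6,928 = 36,400 trainable parameters; the
dense layers add roughly a million more (reported separately by ``param_counts``).
The softmax head exists only for CNN training and the pure-CNN baseline — the hybrid
classifier discards it and feeds the 64-dim activations to the forest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nnet
from .nnet import Adam, Conv2D, Dense, MaxPool2D, softmax_xent
from .vocab import CLASSES, CLASS_INDEX

#: forward/backward chunk size; mini-batch gradients are accumulated over chunks
_CHUNK = 16


@dataclass(frozen=True)
class CNNSpec:
    """Architecture hyperparameters (defaults are the published network)."""

    input_size: int = 256
    conv1_filters: int = 24
    conv1_kernel: tuple[int, int] = (5, 5)
    conv1_stride: tuple[int, int] = (4, 2)
    conv2_filters: int = 48
    conv2_kernel: tuple[int, int] = (5, 5)
    conv2_stride: tuple[int, int] = (1, 1)
    pool_kernel: tuple[int, int] = (4, 2)
    conv3_filters: int = 16
    conv3_kernel: tuple[int, int] = (3, 3)
    conv3_stride: tuple[int, int] = (1, 1)
    dense_units: int = 64
    n_classes: int = len(CLASSES)

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class TrainingConfig:
    """Optimization protocol: Adam, 100 epochs, mini-batch 128, cross-entropy."""

    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


def conv_param_count(kh: int, kw: int, cin: int, cout: int) -> int:
    """Trainable parameters of a conv layer: (kh*kw*cin + 1) * cout."""
    return (kh * kw * cin + 1) * cout


def param_counts(spec: CNNSpec = CNNSpec()) -> dict[str, int]:
    """Per-layer and total parameter counts (conv-only total reported separately)."""
    c1 = conv_param_count(*spec.conv1_kernel, 1, spec.conv1_filters)
    c2 = conv_param_count(*spec.conv2_kernel, spec.conv1_filters, spec.conv2_filters)
    c3 = conv_param_count(*spec.conv3_kernel, spec.conv2_filters, spec.conv3_filters)
    model = HeartLungCNN(spec, seed=0)
    flat = model.flat_dim
    dense = (flat + 1) * spec.dense_units
    head = (spec.dense_units + 1) * spec.n_classes
    return {"conv1": c1, "conv2": c2, "conv3": c3, "conv_total": c1 + c2 + c3,
            "dense": dense, "head": head, "total": c1 + c2 + c3 + dense + head}


class HeartLungCNN:
    """The six-layer network plus training, feature extraction and persistence."""

    def __init__(self, spec: CNNSpec = CNNSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        self.conv1 = Conv2D(*s.conv1_kernel, 1, s.conv1_filters, s.conv1_stride, rng=rng)
        self.conv2 = Conv2D(*s.conv2_kernel, s.conv1_filters, s.conv2_filters,
                            s.conv2_stride, rng=rng)
        self.pool = MaxPool2D(*s.pool_kernel)
        self.conv3 = Conv2D(*s.conv3_kernel, s.conv2_filters, s.conv3_filters,
                            s.conv3_stride, rng=rng)
        # derive the flattened dimension from the actual shape chain
        h = w = s.input_size
        h1 = -(-h // s.conv1_stride[0]); w1 = -(-w // s.conv1_stride[1])
        h2 = -(-h1 // s.conv2_stride[0]); w2 = -(-w1 // s.conv2_stride[1])
        hp, wp = h2 // s.pool_kernel[0], w2 // s.pool_kernel[1]
        h3 = -(-hp // s.conv3_stride[0]); w3 = -(-wp // s.conv3_stride[1])
        self.flat_dim = h3 * w3 * s.conv3_filters
        self.dense = Dense(self.flat_dim, s.dense_units, activation="relu", rng=rng)
        self.head = Dense(s.dense_units, s.n_classes, activation=None, rng=rng)
        self.loss_history: list[float] = []

    # -- forward ------------------------------------------------------------

    def _stack(self):
        return [self.conv1, self.conv2, self.pool, self.conv3, self.dense, self.head]

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Batch of images (B, 256, 256[, 1]) -> (B, 64) dense activations."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != (self.spec.input_size,) * 2:
            raise ValueError(f"expected {self.spec.input_size}x{self.spec.input_size} images")
        h = self.conv1.forward(x, train)
        h = self.conv2.forward(h, train)
        h = self.pool.forward(h, train)
        h = self.conv3.forward(h, train)
        h = h.reshape(h.shape[0], -1)
        return self.dense.forward(h, train)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.forward_features(x, train), train)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dense.backward(d)
        b = d.shape[0]
        s = self.spec
        h3 = self.conv3._cache[2][3]  # ho of conv3
        d = d.reshape(b, h3, self.flat_dim // (h3 * s.conv3_filters), s.conv3_filters)
        d = self.conv3.backward(d)
        d = self.pool.backward(d)
        d = self.conv2.backward(d)
        self.conv1.backward(d)

    # -- training -----------------------------------------------------------

    def train_classifier(self, images: np.ndarray, labels,
                         cfg: TrainingConfig | None = None) -> list[float]:
        """Train the softmax-headed network; returns the per-epoch mean loss history."""
        cfg = cfg or TrainingConfig()
        x = np.asarray(images, dtype=np.float32)
        y = np.asarray([CLASS_INDEX[l] if isinstance(l, str) else int(l) for l in labels])
        present = np.unique(y)
        if present.size < self.spec.n_classes:
            warnings.warn(f"only {present.size}/{self.spec.n_classes} classes present "
                          "in the training data", stacklevel=2)
        rng = np.random.default_rng(cfg.seed)
        opt = Adam([p for layer in self._stack() if hasattr(layer, "params")
                    for p in layer.params()], lr=cfg.learning_rate)
        n = x.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                bidx = order[start:start + cfg.batch_size]
                nnet.zero_grads(self._stack())
                bloss = 0.0
                for cstart in range(0, bidx.size, _CHUNK):
                    cidx = bidx[cstart:cstart + _CHUNK]
                    logits = self.forward_logits(x[cidx], train=True)
                    loss, dlog = softmax_xent(logits, y[cidx], denom=bidx.size)
                    if not np.isfinite(loss):
                        raise FloatingPointError("non-finite training loss")
                    bloss += loss
                    self._backward(dlog)
                opt.step()
                epoch_loss += bloss * bidx.size
            self.loss_history.append(epoch_loss / n)
        return self.loss_history

    # -- inference ----------------------------------------------------------

    def features(self, images: np.ndarray) -> np.ndarray:
        """64-dim feature vector(s) from the dense layer (softmax head unused).

        Accepts one (256, 256) image or a batch; deterministic and independent of
        batch composition (evaluation always runs in inference mode).
        """
        arr = np.asarray(images, dtype=np.float32)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        out = np.concatenate([self.forward_features(arr[i:i + _CHUNK])
                              for i in range(0, arr.shape[0], _CHUNK)])
        return out[0] if single else out

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class indices from the softmax head (the pure-CNN baseline)."""
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        logits = np.concatenate([self.forward_logits(arr[i:i + _CHUNK])
                                 for i in range(0, arr.shape[0], _CHUNK)])
        return logits.argmax(axis=1)

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file .npz with the weights and an embedded spec hash."""
        arrays = {}
        for i, layer in enumerate([self.conv1, self.conv2, self.conv3, self.dense, self.head]):
            arrays[f"w{i}"] = layer.w
            arrays[f"b{i}"] = layer.b
        np.savez(Path(path), spec=json.dumps(asdict(self.spec)),
                 spec_hash=self.spec.hash(), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "HeartLungCNN":
        data = np.load(Path(path), allow_pickle=False)
        spec_dict = json.loads(str(data["spec"]))
        for k in ("conv1_kernel", "conv1_stride", "conv2_kernel", "conv2_stride",
                  "pool_kernel", "conv3_kernel", "conv3_stride"):
            spec_dict[k] = tuple(spec_dict[k])
        spec = CNNSpec(**spec_dict)
        if str(data["spec_hash"]) != spec.hash():
            raise ValueError("spec hash mismatch in saved model")
        model = cls(spec)
        for i, layer in enumerate([model.conv1, model.conv2, model.conv3,
                                   model.dense, model.head]):
            layer.w = data[f"w{i}"].astype(np.float32)
            layer.b = data[f"b{i}"].astype(np.float32)
            layer.dw = np.zeros_like(layer.w)
            layer.db = np.zeros_like(layer.b)
        return model
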