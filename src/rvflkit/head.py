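"""The deep-feature head: adjusted top layers, SGDM trainer, feature taps.

The head replaces a backbone's classification layers with the stack

    embedding → FC1000 → Dropout → FC64 → Dropout → FC24 → FC2 → softmax

(dropout p = 0.3, active only during training).  After training on
softmax cross-entropy with SGD-with-momentum and a stepwise-decayed learning
rate, *deep features* are read off at the 24- and 64-unit layers: the
pre-activation values at the named tap, tagged ``fea24`` / ``fea64``.

The backbone itself is pluggable: anything exposing ``input_shape`` and a
deterministic ``forward(images) -> embeddings`` satisfies the contract
(see :func:`rvflkit.synthetic.tiny_backbone` for a desk-scale one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import TrainingError, ValidationError
from .features import CLASS_ORDER, FORMAT_VERSION, FeatureMatrix, concat_features  # noqa: F401
from .linalg import one_hot
from .rng import substream

__all__ = [
    "HeadSpec",
    "HeadTrainConfig",
    "BackboneContract",
    "Head",
    "build_head",
    "train_head",
    "lr_schedule",
    "extract_features",
    "concat_features",
    "save_head",
    "load_head",
]

TAP_WIDTHS = {"fc24": 24, "fc64": 64}


@runtime_checkable
class BackboneContract(Protocol):
    """Any deterministic image-batch → fixed-width-embedding mapping."""

    input_shape: tuple[int, int, int]

    def forward(self, images: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class HeadSpec:
    """Architecture of the adjusted top layers.

    ``layer_sizes`` excludes the embedding width (supplied at build time);
    ``dropout_positions`` indexes the hidden layers after which dropout
    applies (0 = after the 1000-unit layer, 1 = after the 64-unit layer).
    """

    layer_sizes: tuple[int, ...] = (1000, 64, 24, 2)
    dropout_positions: tuple[int, ...] = (0, 1)
    dropout_p: float = 0.3
    tap_names: tuple[str, ...] = ("fc24", "fc64")

    def __post_init__(self):
        if not (0 <= self.dropout_p < 1):
            raise ValidationError("dropout_p must be in [0, 1)")
        if self.layer_sizes[-1] != len(CLASS_ORDER):
            raise ValidationError("final layer width must equal the class count")


@dataclass(frozen=True)
class HeadTrainConfig:
    """SGDM schedule: 12 epochs, lr 5e-4 dropped ×0.1 every 3 epochs,
    mini-batches of 60, reshuffled each epoch, momentum 0.9."""

    max_epochs: int = 12
    initial_lr: float = 5e-4
    batch_size: int = 60
    lr_drop_period: int = 3
    lr_drop_factor: float = 0.1
    momentum: float = 0.9
    shuffle_each_epoch: bool = True

    def __post_init__(self):
        if min(self.max_epochs, self.batch_size, self.lr_drop_period) < 1:
            raise ValidationError("epochs, batch size and drop period must be >= 1")
        if self.initial_lr <= 0:
            raise ValidationError("initial_lr must be positive")
        if not (0 < self.lr_drop_factor <= 1):
            raise ValidationError("lr_drop_factor must be in (0, 1]")
        if self.momentum < 0:
            raise ValidationError("momentum must be non-negative")


@dataclass
class Head:
    """Dense head parameters: one (W, b) pair per FC layer."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    spec: HeadSpec = field(default_factory=HeadSpec)

    @property
    def embedding_width(self) -> int:
        return self.weights[0].shape[0]

    @property
    def parameter_count(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
        tap: str | None = None,
    ):
        """Forward pass.

        Inference mode (default) disables dropout, so repeated calls on the
        same batch are identical.  With ``tap`` set, returns the
        pre-activation values at the named layer instead of the softmax
        output.  In training mode returns (probs, cache) for backprop.
        """
        tap_layer = None
        if tap is not None:
            if tap not in TAP_WIDTHS:
                raise ValidationError(f"unknown tap {tap!r}; expected fc24 or fc64")
            tap_layer = [i for i, s in enumerate(self.spec.layer_sizes)
                         if s == TAP_WIDTHS[tap]][0]
        a = np.asarray(X, dtype=float)
        cache = {"a": [a], "mask": []}
        n_layers = len(self.weights)
        for i in range(n_layers):
            z = a @ self.weights[i] + self.biases[i]
            if tap_layer is not None and i == tap_layer:
                return z
            if i < n_layers - 1:
                a = np.maximum(z, 0.0)  # ReLU between hidden FC layers
                mask = None
                if training and i in self.spec.dropout_positions and self.spec.dropout_p > 0:
                    keep = 1.0 - self.spec.dropout_p
                    mask = (dropout_rng.random(a.shape) < keep) / keep
                    a = a * mask
                cache["a"].append(a)
                cache["mask"].append(mask)
            else:
                zmax = z.max(axis=1, keepdims=True)
                ez = np.exp(z - zmax)
                probs = ez / ez.sum(axis=1, keepdims=True)
        if training:
            return probs, cache
        return probs


def build_head(embedding_width: int, spec: HeadSpec = HeadSpec(), seed: int = 0) -> Head:
    """Initialize head parameters with seeded He-scaled Gaussians.

    Layer sizes run embedding → 1000 → 64 → 24 → 2; biases start at zero.
    """
    if embedding_width < 1:
        raise ValidationError("embedding_width must be >= 1")
    rng = substream(seed, "head_init")
    sizes = (embedding_width,) + tuple(spec.layer_sizes)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return Head(weights=weights, biases=biases, spec=spec)


def lr_schedule(cfg: HeadTrainConfig) -> list[float]:
    """Realized per-epoch learning rates under the step decay."""
    return [
        cfg.initial_lr * cfg.lr_drop_factor ** (e // cfg.lr_drop_period)
        for e in range(cfg.max_epochs)
    ]


def train_head(
    head: Head,
    features: FeatureMatrix,
    cfg: HeadTrainConfig = HeadTrainConfig(),
    seed: int = 0,
) -> tuple[Head, dict]:
    """Train the head in place with SGDM on softmax cross-entropy.

    Returns the head and a trace dict with per-epoch mean loss and the
    realized learning rate per epoch.
    """
    if len(features.classes_present()) < 2:
        raise ValidationError("head training needs both classes present")
    n = features.n_samples
    if cfg.batch_size > n:
        raise ValidationError(f"batch_size {cfg.batch_size} exceeds N={n}")
    X = features.values
    Y = one_hot(features.labels, CLASS_ORDER).values
    shuffle_rng = substream(seed, "head_shuffle")
    dropout_rng = substream(seed, "head_dropout")
    vel_w = [np.zeros_like(W) for W in head.weights]
    vel_b = [np.zeros_like(b) for b in head.biases]
    rates = lr_schedule(cfg)
    epoch_loss = []
    for epoch, lr in enumerate(rates):
        order = shuffle_rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            probs, cache = head.forward(xb, training=True, dropout_rng=dropout_rng)
            loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged (non-finite) at epoch {epoch}")
            losses.append(loss)
            # backprop
            grad_z = (probs - yb) / len(idx)
            for i in range(len(head.weights) - 1, -1, -1):
                a_prev = cache["a"][i]
                gW = a_prev.T @ grad_z
                gb = grad_z.sum(axis=0)
                if i > 0:
                    grad_a = grad_z @ head.weights[i].T
                    mask = cache["mask"][i - 1]
                    if mask is not None:
                        grad_a = grad_a * mask
                    # ReLU gate: a_prev stores post-dropout activations, whose
                    # nonzero pattern matches the ReLU output's support
                    grad_z = grad_a * (cache["a"][i] > 0)
                vel_w[i] = cfg.momentum * vel_w[i] - lr * gW
                vel_b[i] = cfg.momentum * vel_b[i] - lr * gb
                head.weights[i] += vel_w[i]
                head.biases[i] += vel_b[i]
        epoch_loss.append(float(np.mean(losses)))
    return head, {"epoch_loss": epoch_loss, "epoch_lr": rates}


def extract_features(
    head: Head,
    data,
    tap: str,
    backbone: BackboneContract | None = None,
    sample_ids=None,
    labels=None,
) -> FeatureMatrix:
    """Tap deep features from the trained head at ``fc24`` or ``fc64``.

    ``data`` is either a FeatureMatrix of backbone embeddings, or (with
    ``backbone`` given) a raw image batch plus ids and labels.  The result is
    the pre-activation value at the tap, tagged fea24/fea64; extraction is
    inference-mode and therefore idempotent.
    """
    if tap not in TAP_WIDTHS:
        raise ValidationError(f"unknown tap {tap!r}; expected one of {tuple(TAP_WIDTHS)}")
    if isinstance(data, FeatureMatrix):
        emb, ids, labs = data.values, data.sample_ids, data.labels
    else:
        if backbone is None:
            raise ValidationError("raw images require a backbone")
        emb = backbone.forward(np.asarray(data))
        ids, labs = list(sample_ids), list(labels)
    Z = head.forward(emb, tap=tap)
    tag = "fea24" if tap == "fc24" else "fea64"
    return FeatureMatrix(values=Z, sample_ids=ids, labels=labs, level_tag=tag)


def save_head(head: Head, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "kind": "head",
        "layer_sizes": list(head.spec.layer_sizes),
        "dropout_positions": list(head.spec.dropout_positions),
        "dropout_p": head.spec.dropout_p,
        "weights": [W.tolist() for W in head.weights],
        "biases": [b.tolist() for b in head.biases],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_head(path) -> Head:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    spec = HeadSpec(
        layer_sizes=tuple(doc["layer_sizes"]),
        dropout_positions=tuple(doc["dropout_positions"]),
        dropout_p=doc["dropout_p"],
    )
    return Head(
        weights=[np.asarray(W, dtype=float) for W in doc["weights"]],
        biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
        spec=spec,
    )
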