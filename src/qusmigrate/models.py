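"""Reduced patch classifiers for the victim and perpetrator machines.

The migration method is architecture-agnostic; what matters is that the
victim and perpetrator default to DIFFERENT families, mirroring the fact that
an attacker cannot know the opaque model's architecture. Three families are
provided: ``dense_style`` (concatenative feature reuse, the victim default),
``residual_style`` (identity skip connections, the perpetrator default), and
``linear_baseline`` (logistic regression on raw samples). Training minimizes
patch-wise binary cross-entropy -[y log yhat + (1-y) log(1-yhat)] with Adam
and horizontal-flip augmentation; patches are z-scored before entering the
network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .preprocess import PatchSet, augment_flip

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "build_classifier",
    "train",
    "predict_scores",
    "PatchCNNClassifier",
    "victim_spec",
    "perpetrator_spec",
]

FAMILIES = ("dense_style", "residual_style", "linear_baseline")


@dataclass(frozen=True)
class ClassifierSpec:
    """Reduced-architecture description: family, depth, width, input shape."""

    family: str = "dense_style"
    n_blocks: int = 2
    base_channels: int = 8
    input_shape: tuple[int, int] = (200, 26)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.n_blocks < 0 or self.base_channels < 1:
            raise ValueError("invalid architecture size")


def victim_spec(**overrides) -> ClassifierSpec:
    kw = dict(family="dense_style", n_blocks=2, base_channels=8)
    kw.update(overrides)
    return ClassifierSpec(**kw)


def perpetrator_spec(**overrides) -> ClassifierSpec:
    kw = dict(family="residual_style", n_blocks=2, base_channels=12)
    kw.update(overrides)
    return ClassifierSpec(**kw)


@dataclass(frozen=True)
class TrainConfig:
    """Adam training protocol. Full-scale protocol values are lr 1e-5, 10 epochs,
    batch 2048 patches; the desk-scale defaults below are sized so the
    from-scratch reduced networks converge reliably on a few hundred patches
    (enough optimizer steps per training)."""

    learning_rate: float = 3e-3
    epochs: int = 20
    batch_size: int = 64
    augment_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if not 0 <= self.augment_probability <= 1:
            raise ValueError("augment_probability must lie in [0, 1]")


def build_classifier(spec: ClassifierSpec, seed: int) -> nn.Sequential:
    """Deterministically initialized reduced network emitting one logit.

    Uniform(+-1/sqrt(fan_in)) initialization throughout. The sigmoid is folded
    into the loss / score computation for numerical stability.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.input_shape
    c = spec.base_channels
    layers: list[nn.Layer]
    if spec.family == "linear_baseline":
        layers = [nn.Dense(rng, h * w, 1)]
        return nn.Sequential(layers)
    # the stem must span several RF periods axially (21 samples ~ 5 periods of
    # a 9 MHz pulse at 40 MHz) so its filters resolve spectral content — the
    # cue that survives cross-machine calibration; shorter stems let training
    # latch onto non-transferable texture idiosyncrasies
    if h < 25 or w < 5:
        raise ValueError("input shape smaller than the network's receptive field")
    layers = [
        nn.Conv2d(rng, 1, c, kernel=(21, 3), stride=(4, 2)),
        nn.ReLU(),
        nn.AvgPool2d(),
    ]
    ch = c
    for _ in range(spec.n_blocks):
        if spec.family == "dense_style":
            layers.append(nn.DenseBlock(rng, ch, growth=c))
            ch += c
        else:
            layers.append(nn.ResidualBlock(rng, ch))
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(rng, ch, 1))
    return nn.Sequential(layers)


def _as_array(patches) -> np.ndarray:
    x = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    return np.asarray(x, dtype=np.float32)


def predict_scores(model: nn.Sequential, patches, batch_size: int = 1024) -> np.ndarray:
    """Sigmoid scores in (0, 1), one per patch; deterministic and invariant to
    batch order (no batch-coupled layers)."""
    x = _as_array(patches)
    if x.ndim != 3:
        raise ValueError("patches must be (n, height, width)")
    out = np.empty(len(x), dtype=np.float64)
    for s in range(0, len(x), batch_size):
        chunk = x[s : s + batch_size][:, None]
        out[s : s + batch_size] = nn.sigmoid(model.forward(chunk)[:, 0])
    return out


def per_sample_losses(model: nn.Sequential, patches, labels, batch_size: int = 1024) -> np.ndarray:
    """Cross-entropy of each patch under the current model (no update pass)."""
    x = _as_array(patches)
    y = np.asarray(labels, dtype=np.float64)
    out = np.empty(len(x))
    for s in range(0, len(x), batch_size):
        logits = model.forward(x[s : s + batch_size][:, None])[:, 0]
        out[s : s + batch_size] = nn.bce_with_logits(logits, y[s : s + batch_size])[0]
    return out


def train_epoch(
    model: nn.Sequential,
    opt: nn.Adam,
    x: np.ndarray,
    y: np.ndarray,
    batch_size: int,
    augment_probability: float,
    rng: np.random.Generator,
) -> float:
    """One shuffled pass of Adam minibatch updates; returns the mean loss."""
    order = rng.permutation(len(x))
    total = 0.0
    for s in range(0, len(order), batch_size):
        idx = order[s : s + batch_size]
        xb = augment_flip(x[idx], augment_probability, rng).astype(np.float32)
        logits = model.forward(xb[:, None])[:, 0]
        losses, dz = nn.bce_with_logits(logits, y[idx])
        total += float(losses.sum())
        dout = (dz / len(idx)).astype(np.float32)[:, None]
        model.backward(dout)
        opt.step(model.grads)
    return total / len(order)


def train(
    model: nn.Sequential, patches, labels, cfg: TrainConfig = TrainConfig()
) -> tuple[nn.Sequential, list[float]]:
    """Train a classifier on (standardized) patches with binary labels.

    Returns the model and the per-epoch mean-loss history. A single-class
    label vector triggers a warning but training proceeds.
    """
    import warnings

    x = _as_array(patches)
    y = np.asarray(labels, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary")
    if len(np.unique(y)) < 2:
        warnings.warn("training labels contain a single class", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history = [
        train_epoch(model, opt, x, y, cfg.batch_size, cfg.augment_probability, rng)
        for _ in range(cfg.epochs)
    ]
    return model, history


class PatchCNNClassifier:
    """sklearn-style estimator facade over the reduced numpy networks.

    fit expects z-scored patches (n, h, w) and binary labels; predict_proba /
    decision-style scores come from :func:`predict_scores`. Fitted attributes:
    ``model_``, ``loss_history_``, ``classes_``.
    """

    def __init__(
        self,
        spec: ClassifierSpec = ClassifierSpec(),
        train_config: TrainConfig = TrainConfig(),
        seed: int = 0,
    ):
        self.spec = spec
        self.train_config = train_config
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec, "train_config": self.train_config, "seed": self.seed}

    def set_params(self, **params) -> "PatchCNNClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "PatchCNNClassifier":
        x = _as_array(X)
        spec = replace(self.spec, input_shape=x.shape[1:])
        self.model_ = build_classifier(spec, self.seed)
        cfg = replace(self.train_config, seed=self.seed)
        _, self.loss_history_ = train(self.model_, x, y, cfg)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        return predict_scores(self.model_, X)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_function(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
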