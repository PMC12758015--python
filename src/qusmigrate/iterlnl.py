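"""Iterative learning with noisy labels: the migration engine.

Starting labels come from the victim's opaque score interface applied to
transfer-function-calibrated perpetrator patches, thresholded at a percentile
given by the label-distribution prior (median for a balanced task). Each
denoising cycle re-initializes the perpetrator model and trains it with
small-loss anchor selection at an assumed noise rate epsilon: every epoch,
the (1 - epsilon) fraction of training points with the lowest current
cross-entropy is treated as reliably labeled and only those are trained on.
After the cycles, labels are re-acquired from the refined model and a final
model is trained on the RAW (uncalibrated) perpetrator patches, yielding a
classifier native to the perpetrator machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import models as _models
from .blackbox import VictimInterface
from .models import ClassifierSpec, TrainConfig
from .preprocess import PatchSet, zscore
from .transfer_function import TransferFunction, apply_gamma_patches

__all__ = [
    "IterLNLConfig",
    "IterLNLState",
    "pseudo_label",
    "select_anchors",
    "run_iterlnl",
    "evaluate",
    "accuracy_score_pct",
    "auc_score",
    "IterLNLMigrator",
]


@dataclass(frozen=True)
class IterLNLConfig:
    """Migration hyperparameters.

    noise_rate: assumed fraction of wrong pseudo-labels; anchors are the
    (1 - noise_rate) lowest-loss points, selected within each pseudo-class by
    default so the anchor set stays balanced (``per_class_anchors=False``
    selects globally, which with a from-scratch reduced network can feed back
    into a one-class collapse). label_percentile: score percentile separating
    class 0 from class 1 when acquiring noisy labels (median for a balanced
    task; 40/60 model a vague prior). n_cycles: denoising cycles.
    """

    noise_rate: float = 0.20
    label_percentile: float = 50.0
    n_cycles: int = 10
    validation_fraction: float = 0.10
    seed: int = 0
    warm_start: bool = False
    fine_tune_final: bool = False
    per_class_anchors: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must lie in [0, 1)")
        if not 0 < self.label_percentile < 100:
            raise ValueError("label_percentile must lie in (0, 100)")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be nonnegative")


@dataclass
class IterLNLState:
    """Trace of one migration run."""

    labels: np.ndarray
    initial_labels: np.ndarray
    initial_scores: np.ndarray
    cycle_metrics: list[dict] = field(default_factory=list)
    anchor_counts: list[int] = field(default_factory=list)
    query_count: int = 0


def pseudo_label(scores: np.ndarray, percentile: float = 50.0) -> np.ndarray:
    """Rank-threshold scores into binary labels using the label-distribution
    prior: the lowest floor(n * p / 100) scores become class 0, the rest
    class 1. Ties break by stable score order then index."""
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n0 = int(np.floor(s.size * percentile / 100.0))
    order = np.argsort(s, kind="stable")
    labels = np.ones(s.size, dtype=np.int64)
    labels[order[:n0]] = 0
    return labels


def select_anchors(per_sample_losses: np.ndarray, noise_rate: float) -> np.ndarray:
    """Indices of the round((1 - noise_rate) * n) smallest losses, ties broken
    by index (stable sort); these are the presumed-correctly-labeled points."""
    losses = np.asarray(per_sample_losses, dtype=np.float64)
    if losses.size == 0:
        raise ValueError("losses must be non-empty")
    if not np.all(np.isfinite(losses)):
        raise ValueError("losses must be finite")
    if not 0 <= noise_rate < 1:
        raise ValueError("noise_rate must lie in [0, 1)")
    k = int(np.floor((1.0 - noise_rate) * losses.size + 0.5))
    order = np.argsort(losses, kind="stable")
    return np.sort(order[:k])


def _anchor_train(
    model,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    noise_rate: float,
    rng: np.random.Generator,
    per_class: bool = False,
) -> tuple[list[float], list[int]]:
    """Anchor-gated training: each epoch, per-sample losses are measured in a
    no-update pass, anchors selected, and one epoch trained on anchors only."""
    opt = _models.nn.Adam(model.params, lr=cfg.learning_rate)
    history, counts = [], []
    for _ in range(cfg.epochs):
        losses = _models.per_sample_losses(model, x, y)
        if per_class:
            anchors = np.sort(
                np.concatenate(
                    [
                        np.flatnonzero(y == c)[select_anchors(losses[y == c], noise_rate)]
                        for c in (0, 1)
                        if np.any(y == c)
                    ]
                )
            )
        else:
            anchors = select_anchors(losses, noise_rate)
        counts.append(len(anchors))
        loss = _models.train_epoch(
            model, opt, x[anchors], y[anchors], cfg.batch_size, cfg.augment_probability, rng
        )
        history.append(loss)
    return history, counts


def run_iterlnl(
    victim: VictimInterface,
    tf: TransferFunction | None,
    X_perp: PatchSet,
    spec: ClassifierSpec,
    cfg: IterLNLConfig = IterLNLConfig(),
    train_config: TrainConfig = TrainConfig(),
) -> tuple[object, IterLNLState]:
    """Migrate the victim's functionality onto unlabeled perpetrator patches.

    ``X_perp`` holds raw perpetrator patches already at the victim sampling
    rate. With ``tf=None`` the calibration step is skipped (the ablation arm).
    Returns the final perpetrator-native model and the run trace.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(X_perp)
    if n == 0:
        raise ValueError("X_perp must be non-empty")

    x_cal_set = apply_gamma_patches(X_perp, tf) if tf is not None else X_perp
    x_cal = zscore(x_cal_set.patches).astype(np.float32)
    x_raw = zscore(X_perp.patches).astype(np.float32)

    q0 = victim.query_count
    scores0 = victim.query(x_cal)
    y = pseudo_label(scores0, cfg.label_percentile)
    state = IterLNLState(
        labels=y.copy(), initial_labels=y.copy(), initial_scores=scores0
    )

    model = None
    for cycle in range(cfg.n_cycles):
        val_n = max(1, int(round(cfg.validation_fraction * n))) if n > 1 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:val_n], perm[val_n:]
        if model is None or not cfg.warm_start:
            model = _models.build_classifier(
                replace(spec, input_shape=x_cal.shape[1:]),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        history, counts = _anchor_train(
            model, x_cal[train_idx], y[train_idx], train_config,
            cfg.noise_rate, rng, cfg.per_class_anchors,
        )
        state.anchor_counts.extend(counts)
        scores = _models.predict_scores(model, x_cal)
        y = pseudo_label(scores, cfg.label_percentile)
        val_scores = scores[val_idx] if val_n else np.array([])
        state.cycle_metrics.append(
            {
                "cycle": cycle,
                "train_loss": history[-1],
                "val_loss": float(
                    np.mean(
                        _models.nn.bce_with_logits(
                            np.log(np.clip(val_scores, 1e-12, 1 - 1e-12))
                            - np.log1p(-np.clip(val_scores, 1e-12, 1 - 1e-12)),
                            y[val_idx],
                        )[0]
                    )
                )
                if val_n
                else np.nan,
                "label_flip_fraction": float(np.mean(y != state.labels)),
            }
        )
        state.labels = y.copy()

    # final model: perpetrator-native, trained on RAW patches with the refined
    # labels (same anchor-gated protocol: the labels are still noisy)
    if cfg.fine_tune_final and model is not None:
        final = model
    else:
        final = _models.build_classifier(
            replace(spec, input_shape=x_raw.shape[1:]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    _anchor_train(final, x_raw, y, train_config, cfg.noise_rate, rng, cfg.per_class_anchors)
    state.labels = y
    state.query_count = victim.query_count - q0
    return final, state


def accuracy_score_pct(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    """Patch-wise accuracy (%) at a fixed score threshold (< 0.5 -> class 0)."""
    pred = (np.asarray(scores) >= threshold).astype(int)
    return float(np.mean(pred == np.asarray(labels)) * 100.0)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the pairwise-comparison definition with ties counted 0.5,
    computed via midranks (exactly equal to the O(n^2) pairwise count)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n1 = int(np.sum(y == 1))
    n0 = s.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined for a single-class label set")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(s.size)
    sorted_s = s[order]
    i = 0
    while i < s.size:
        j = i
        while j + 1 < s.size and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # midrank
        i = j + 1
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def evaluate(model, patchset: PatchSet, labels: np.ndarray | None = None) -> dict:
    """Patch-wise accuracy (%) and AUC of a model on a labeled test PatchSet.

    Patches are z-scored with the training rule before scoring.
    """
    y = labels if labels is not None else patchset.labels
    if y is None:
        raise ValueError("test labels are required")
    x = zscore(np.asarray(patchset.patches, dtype=np.float64)).astype(np.float32)
    scores = _models.predict_scores(model, x)
    return {
        "accuracy_pct": accuracy_score_pct(scores, y),
        "auc": auc_score(scores, y),
        "n": len(y),
    }


def aggregate_seed_metrics(metrics: list[dict]) -> dict:
    """Mean +- std over per-seed metric dicts (accuracy_pct, auc)."""
    out = {}
    for key in ("accuracy_pct", "auc"):
        vals = np.array([m[key] for m in metrics], dtype=float)
        out[f"{key}_mean"] = float(vals.mean())
        out[f"{key}_std"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    out["n_seeds"] = len(metrics)
    return out


class IterLNLMigrator:
    """sklearn-style estimator facade over :func:`run_iterlnl`.

    fit(X) consumes an unlabeled perpetrator PatchSet; fitted attributes are
    ``model_`` (perpetrator-native), ``state_`` (trace), ``labels_``.
    """

    def __init__(
        self,
        victim: VictimInterface,
        tf: TransferFunction | None,
        spec: ClassifierSpec,
        config: IterLNLConfig = IterLNLConfig(),
        train_config: TrainConfig = TrainConfig(),
    ):
        self.victim = victim
        self.tf = tf
        self.spec = spec
        self.config = config
        self.train_config = train_config

    def get_params(self, deep: bool = True) -> dict:
        return {
            "victim": self.victim,
            "tf": self.tf,
            "spec": self.spec,
            "config": self.config,
            "train_config": self.train_config,
        }

    def set_params(self, **params) -> "IterLNLMigrator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: PatchSet, y=None) -> "IterLNLMigrator":
        self.model_, self.state_ = run_iterlnl(
            self.victim, self.tf, X, self.spec, self.config, self.train_config
        )
        self.labels_ = self.state_.labels
        return self

    def predict(self, X) -> np.ndarray:
        x = zscore(np.asarray(X.patches if isinstance(X, PatchSet) else X, dtype=np.float64))
        return (_models.predict_scores(self.model_, x.astype(np.float32)) >= 0.5).astype(int)

    def score(self, X: PatchSet, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
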