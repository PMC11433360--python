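"""The ParkinsonNet classifier: architecture, subject-level splits, training.

The network is a five-block CNN for the color correlation matrices: per
block a convolution (32 -> 64 -> 128 -> 256 -> 512 filters), ReLU, max
pooling, and dropout; blocks 1-4 use 3x3 kernels with 2x2 pooling, block
5 uses a 1x1 convolution with unit ("1x1") pooling; then flatten and two
dense layers, the last a single sigmoid unit giving the probability that
the image belongs to the disease-associated class.  The fully literal
all-1x1-pooling variant is selectable through ``pool_sizes`` for fidelity
experiments, at the cost of a very wide flatten.

Splits are subject-level throughout: a subject's images never straddle
train/test/validation, and a designated holdout cohort (or an automatic
pick of at least one subject per class) goes entirely to validation.
Evaluation uses precision, recall, and the F1 score (harmonic mean).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ValidationError
from .nn import (
    bce_with_logits,
    Adam,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    Sigmoid,
    bce_loss,
)

__all__ = [
    "ModelConfig",
    "TrainHyper",
    "DatasetManifest",
    "TrainReport",
    "build_parkinsonnet",
    "split_by_subject",
    "train",
    "evaluate_f1",
    "classify",
]


@dataclass
class ModelConfig:
    """Architecture and initialization parameters."""

    conv_filters: tuple = (32, 64, 128, 256, 512)
    kernel_sizes: tuple = (3, 3, 3, 3, 1)
    pool_sizes: tuple = (2, 2, 2, 2, 1)
    dropout: float = 0.25
    dense_width: int = 64
    input_hw: int = 128
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 5:
            raise ValidationError("ParkinsonNet has exactly 5 convolutional layers")
        if len(self.kernel_sizes) != 5 or len(self.pool_sizes) != 5:
            raise ValidationError("need one kernel and pool size per conv layer")
        hw = self.input_hw
        for p in self.pool_sizes:
            if hw % p:
                raise ValidationError(
                    f"input size {self.input_hw} not divisible by the pooling schedule"
                )
            hw //= p
        self._final_hw = hw

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrainHyper:
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5  # early stopping on test loss
    class_weighting: bool = False
    seed: int = 0


@dataclass
class DatasetManifest:
    """Subject-level image records: path, subject, manifestation, label, split."""

    frame: pd.DataFrame

    REQUIRED = ("path", "subject", "manifestation", "label", "split")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"manifest missing columns {missing}")

    def check_subject_disjoint(self) -> None:
        per_subject = self.frame.groupby("subject")["split"].nunique()
        bad = per_subject[per_subject > 1]
        if len(bad):
            raise ValidationError(f"subjects straddle splits: {list(bad.index)}")

    def subset(self, split: str, manifestation: str | None = None) -> pd.DataFrame:
        df = self.frame[self.frame["split"] == split]
        if manifestation is not None:
            df = df[df["manifestation"] == manifestation]
        return df

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path))


@dataclass
class TrainReport:
    epochs: list = field(default_factory=list)  # dicts: epoch, train/test loss+acc
    precision: float = np.nan
    recall: float = np.nan
    f1: float = np.nan
    flags: dict = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0


def build_parkinsonnet(cfg: ModelConfig) -> Sequential:
    """Instantiate the network with seeded He initialization."""
    rng = np.random.default_rng(cfg.seed)
    layers = []
    in_ch = cfg.in_channels
    for filters, k, p in zip(cfg.conv_filters, cfg.kernel_sizes, cfg.pool_sizes):
        layers.append(Conv2D(in_ch, filters, k, rng))
        layers.append(ReLU())
        layers.append(MaxPool2D(p))
        layers.append(Dropout(cfg.dropout, rng))
        in_ch = filters
    layers.append(Flatten())
    flat = cfg.conv_filters[-1] * cfg._final_hw * cfg._final_hw
    layers.append(Dense(flat, cfg.dense_width, rng))
    layers.append(ReLU())
    layers.append(Dense(cfg.dense_width, 1, rng))
    layers.append(Sigmoid())
    return Sequential(layers)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_by_subject(
    manifest: DatasetManifest,
    fractions=(0.6, 0.2, 0.2),
    holdout_subjects=None,
    seed: int = 0,
) -> DatasetManifest:
    """Assign every subject wholly to train, test, or validation.

    ``holdout_subjects`` (if given) go entirely to validation; otherwise at
    least one subject per class — round(validation_fraction x class size),
    minimum 1 — is picked at random.  The remaining subjects are assigned
    greedily (largest image count first) to whichever of train/test is
    furthest below its target image share, approximating the requested
    60/20/20 image-count fractions without ever splitting a subject.
    """
    df = manifest.frame.copy()
    subjects = df.groupby("subject").agg(
        n_images=("path", "count"), label=("label", "max")
    )
    if holdout_subjects:
        missing = [s for s in holdout_subjects if s not in subjects.index]
        if missing:
            raise ValidationError(f"holdout subjects not in manifest: {missing}")
        holdout = list(holdout_subjects)
    else:
        rng = np.random.default_rng(seed)
        holdout = []
        for cls, members in subjects.groupby("label"):
            if len(members) < 3:
                raise ValidationError(
                    f"need >= 3 subjects per class for an automatic holdout (class {cls})"
                )
            k = max(1, int(round(fractions[2] * len(members))))
            picks = rng.choice(np.sort(members.index.to_numpy()), size=k, replace=False)
            holdout.extend(picks.tolist())

    rest = subjects.drop(index=holdout).sort_index()
    share = fractions[0] / (fractions[0] + fractions[1])
    assignment = {s: "validation" for s in holdout}
    # stratify: apportion each class's subjects separately so train and
    # test see the same class balance (a skewed test split would mislead
    # the early-stopping criterion)
    for _cls, members in rest.groupby("label"):
        members = members.sort_values("n_images", ascending=False, kind="stable")
        n_cls = members["n_images"].sum()
        targets = {"train": share * n_cls, "test": (1 - share) * n_cls}
        counts = {"train": 0, "test": 0}
        for subj, row in members.iterrows():
            deficits = {k: targets[k] - counts[k] for k in counts}
            pick = max(sorted(deficits), key=lambda k: deficits[k])
            assignment[subj] = pick
            counts[pick] += row["n_images"]
    df["split"] = df["subject"].map(assignment)
    out = DatasetManifest(df)
    out.check_subject_disjoint()
    return out


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def evaluate_f1(probabilities, labels, threshold: float = 0.5):
    """Precision, recall, and F1 of thresholded probabilities.

    ``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``, ``F1 = 2PR/(P+R)``; any zero
    denominator yields 0 for that quantity, with a flag in the returned
    dict noting the degeneracy.
    """
    prob = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    pred = (prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    flags = {}
    if tp + fp == 0:
        precision, flags["no_positive_predictions"] = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, flags["no_positive_labels"] = 0.0, True
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1, flags


def classify(model: Sequential, images: np.ndarray) -> np.ndarray:
    """Disease-class probabilities for one image (C,H,W) or a batch (N,C,H,W)."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    return model.forward(x, training=False).ravel()


def _accuracy(prob, y):
    return float(np.mean((prob >= 0.5).astype(int) == y))


def train(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    hyper: TrainHyper | None = None,
    model_cfg: ModelConfig | None = None,
) -> TrainReport:
    """Train with binary cross-entropy, early-stopping on test loss.

    Per-epoch train/test loss and accuracy are recorded; the weights from
    the best test-loss epoch are restored at the end.  With ``max_epochs
    = 0`` the report carries empty curves and the untrained model may
    still be evaluated.  Fully deterministic under ``hyper.seed``.
    """
    hyper = hyper or TrainHyper()
    report = TrainReport(seed=hyper.seed)
    if model_cfg is not None:
        report.config_hash = model_cfg.config_hash()
    if hyper.max_epochs == 0:
        return report
    y_train = np.asarray(y_train, dtype=np.float32).reshape(-1, 1)
    y_test = np.asarray(y_test, dtype=np.float32).reshape(-1, 1)
    if x_train.shape[0] == 0 or x_test.shape[0] == 0:
        raise ValidationError("train and test splits must be non-empty")
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training split contains a single class")

    weights = np.ones_like(y_train)
    if hyper.class_weighting:
        pos = float(y_train.mean())
        weights = np.where(y_train == 1, 0.5 / max(pos, 1e-6), 0.5 / max(1 - pos, 1e-6))

    rng = np.random.default_rng(hyper.seed)
    opt = Adam(model.params(), lr=hyper.lr)
    best_loss, best_state, best_epoch = np.inf, model.state(), -1
    x_train = x_train.astype(np.float32)
    x_test = x_test.astype(np.float32)
    # train through the fused sigmoid+BCE for stability: forward/backward
    # stop at the logit layer, the trailing Sigmoid is inference-only
    body = Sequential(model.layers[:-1])
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(x_train.shape[0])
        ep_loss, seen = 0.0, 0
        for start in range(0, order.size, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            z = body.forward(x_train[idx], training=True)
            loss, _prob, grad = bce_with_logits(z, y_train[idx])
            grad = grad * weights[idx]
            body.backward(grad)
            opt.step(model.grads())
            ep_loss += loss * idx.size
            seen += idx.size
        train_prob = classify(model, x_train)
        test_prob = classify(model, x_test)
        test_loss, _ = bce_loss(test_prob.reshape(-1, 1), y_test)
        report.epochs.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / seen,
                "train_acc": _accuracy(train_prob, y_train.ravel()),
                "test_loss": test_loss,
                "test_acc": _accuracy(test_prob, y_test.ravel()),
            }
        )
        if test_loss < best_loss - 1e-6:
            best_loss, best_state, best_epoch = test_loss, model.state(), epoch
        elif epoch - best_epoch >= hyper.patience:
            break
    model.load_state(best_state)
    return report
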