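"""Closed-set CNN classification of particle crops.

The classifier is a "micro-CNN": one CONV + max-pool block, four
CONV + max-pool + dropout blocks, then two dense layers with a softmax
output — small enough to train on a CPU in minutes.  Crops are padded
to square (preserving aspect ratio, filling with the crop's border
median) and resized to the model's input size.  Training uses Adam,
categorical cross-entropy with optional inverse-frequency class
weights, and 8-fold dihedral augmentation (the 90-degree rotations and
mirrors of each training image) applied to the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from fimflow import nn


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training hyperparameters of the micro-CNN."""

    input_size: int = 32
    channels: tuple[int, ...] = (8, 16, 32, 32, 64)
    kernel_size: int = 3
    dense_units: int = 64
    dropout_rate: float = 0.25
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    class_weighting: bool = True

    def validate(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if len(self.channels) != 5:
            raise ValueError("architecture uses five convolution blocks")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32 (five 2x2 pools)")


@dataclass
class Prediction:
    """Per-crop class probabilities plus the rejection decision."""

    roi_id: str
    probs: np.ndarray
    argmax_label: str
    method: str = "softmax"
    rejected: bool = False
    score: float = 0.0


@dataclass
class DataSplit:
    images: list[np.ndarray]
    labels: list[str]


# ---------------------------------------------------------------------------
# augmentation and splitting


def augment_dihedral(crop: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral transforms of a square crop (lossless, pixel-exact).

    Rotations by 0/90/180/270 degrees of the crop and of its mirror
    image; the identity is included.
    """
    if crop.shape[0] != crop.shape[1]:
        raise ValueError("crop must be square; pad it first")
    out = []
    for base in (crop, crop[:, ::-1]):
        for k in range(4):
            out.append(np.ascontiguousarray(np.rot90(base, k)))
    return out


def pad_to_square(crop: np.ndarray, fill: float | None = None) -> np.ndarray:
    """Pad a crop to square, centering it; fill defaults to border median."""
    h, w = crop.shape[:2]
    if h == w:
        return crop
    if fill is None:
        border = np.concatenate([crop[0], crop[-1], crop[:, 0], crop[:, -1]])
        fill = float(np.median(border))
    side = max(h, w)
    out = np.full((side, side) + crop.shape[2:], fill, dtype=crop.dtype)
    y0 = (side - h) // 2
    x0 = (side - w) // 2
    out[y0:y0 + h, x0:x0 + w] = crop
    return out


def split_dataset(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    augment_train: bool = True,
) -> tuple[DataSplit, DataSplit, DataSplit]:
    """Stratified train/validation/test split (default 70:15:15).

    Dihedral augmentation is applied to the training split only, so the
    validation and test sets contain no transformed duplicates of
    training images.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    labels = list(labels)
    rng = np.random.default_rng(seed)
    splits = (DataSplit([], []), DataSplit([], []), DataSplit([], []))
    for cls in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == cls]
        if len(idx) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 images")
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(ratios[0] * n))
        n_va = int(round(ratios[1] * n))
        n_tr = max(1, min(n_tr, n - 2))
        n_va = max(1, min(n_va, n - n_tr - 1))
        parts = (idx[:n_tr], idx[n_tr:n_tr + n_va], idx[n_tr + n_va:])
        for split, part in zip(splits, parts):
            for i in part:
                split.images.append(images[i])
                split.labels.append(cls)
    train, val, test = splits
    if augment_train:
        aug_imgs: list[np.ndarray] = []
        aug_labels: list[str] = []
        for img, lab in zip(train.images, train.labels):
            for t in augment_dihedral(pad_to_square(img)):
                aug_imgs.append(t)
                aug_labels.append(lab)
        train = DataSplit(aug_imgs, aug_labels)
    return train, val, test


# ---------------------------------------------------------------------------
# model


def preprocess(crops: Sequence[np.ndarray], input_size: int) -> np.ndarray:
    """Pad-to-square, resize and scale crops to a (N, 1, S, S) batch."""
    batch = np.empty((len(crops), 1, input_size, input_size))
    for i, crop in enumerate(crops):
        sq = pad_to_square(np.asarray(crop, dtype=np.float64))
        img = resize(sq, (input_size, input_size), anti_aliasing=True, mode="reflect")
        batch[i, 0] = img / 255.0 - 0.5
    return batch


def build_trunk(config: CnnConfig, rng: np.random.Generator) -> list[nn.Layer]:
    """Convolutional feature extractor: CONV-MP, then 4 x CONV-MP-DO."""
    layers: list[nn.Layer] = []
    c_prev = 1
    for i, c in enumerate(config.channels):
        layers += [nn.Conv2d(c_prev, c, config.kernel_size, rng), nn.ReLU(), nn.MaxPool2()]
        if i > 0:
            layers.append(nn.Dropout(config.dropout_rate))
        c_prev = c
    layers.append(nn.Flatten())
    return layers


class CnnModel:
    """A trained micro-CNN: network, class names and training history."""

    def __init__(self, net: nn.Sequential, classes: list[str], config: CnnConfig,
                 history: list[dict] | None = None):
        self.net = net
        self.classes = classes
        self.config = config
        self.history = history or []

    def forward_probs(self, batch: np.ndarray, train: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        return nn.softmax(self.net.forward(batch, train=train, rng=rng))

    def predict_probs(self, crops: Sequence[np.ndarray]) -> np.ndarray:
        """Deterministic inference (dropout off) in batches."""
        out = []
        for i in range(0, len(crops), 256):
            batch = preprocess(crops[i:i + 256], self.config.input_size)
            out.append(self.forward_probs(batch))
        return np.vstack(out)


def _class_weights(labels: np.ndarray, k: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=k)
    w = len(labels) / (k * np.maximum(counts, 1))
    return w


def _train_network(
    net: nn.Sequential,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_va: np.ndarray,
    y_va: np.ndarray,
    config: CnnConfig,
    loss_fn,
    eval_fn,
) -> list[dict]:
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(net, lr=config.learning_rate)
    history = []
    n = len(y_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            out = net.forward(X_tr[sel], train=True, rng=rng)
            loss, grad = loss_fn(out, y_tr[sel])
            net.backward(grad)
            opt.step()
            total += loss * len(sel)
        if np.isnan(total):
            raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
        record = {"epoch": epoch, "train_loss": total / n}
        if len(y_va):
            record["val_accuracy"] = eval_fn(X_va, y_va)
        history.append(record)
    return history


def train_closed_set(train: DataSplit, val: DataSplit, config: CnnConfig) -> CnnModel:
    """Train the closed-set classifier; deterministic given the seed."""
    config.validate()
    classes = sorted(set(train.labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_tr = np.array([class_to_idx[l] for l in train.labels])
    y_va = np.array([class_to_idx[l] for l in val.labels], dtype=int)
    X_tr = preprocess(train.images, config.input_size)
    X_va = preprocess(val.images, config.input_size) if len(val.images) else np.empty((0,))

    rng = np.random.default_rng(config.seed)
    feat_dim = config.channels[-1] * (config.input_size // 32) ** 2
    layers = build_trunk(config, rng) + [
        nn.Dense(feat_dim, config.dense_units, rng),
        nn.ReLU(),
        nn.Dense(config.dense_units, len(classes), rng),
    ]
    net = nn.Sequential(layers)
    weights = _class_weights(y_tr, len(classes)) if config.class_weighting else None

    def loss_fn(logits, y):
        return nn.cross_entropy(logits, y, weights)

    def eval_fn(X, y):
        preds = []
        for i in range(0, len(y), 256):
            preds.append(net.forward(X[i:i + 256], train=False).argmax(axis=1))
        return float((np.concatenate(preds) == y).mean())

    history = _train_network(net, X_tr, y_tr, X_va, y_va, config, loss_fn, eval_fn)
    return CnnModel(net, classes, config, history)


def predict(
    model: CnnModel, crops: Sequence[np.ndarray], roi_ids: Sequence[str] | None = None
) -> list[Prediction]:
    """Deterministic softmax predictions (no rejection applied)."""
    probs = model.predict_probs(crops)
    ids = roi_ids if roi_ids is not None else [str(i) for i in range(len(crops))]
    return [
        Prediction(
            roi_id=ids[i],
            probs=probs[i],
            argmax_label=model.classes[int(probs[i].argmax())],
            method="softmax",
            rejected=False,
            score=float(probs[i].max()),
        )
        for i in range(len(crops))
    ]


def confusion_and_accuracy(
    predictions: Sequence[Prediction], truth: Sequence[str]
) -> tuple[pd.DataFrame, float, dict[str, float]]:
    """Confusion matrix (rows = truth, columns = predicted) and accuracies.

    Rejected predictions are tallied in a dedicated "(rejected)" column.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions")
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth lengths differ")
    pred_labels = [
        "(rejected)" if p.rejected else p.argmax_label for p in predictions
    ]
    rows = sorted(set(truth))
    cols = sorted(set(pred_labels) | set(rows))
    mat = pd.DataFrame(0, index=rows, columns=cols)
    for t, p in zip(truth, pred_labels):
        mat.loc[t, p] += 1
    correct = sum(1 for t, p in zip(truth, pred_labels) if t == p)
    overall = correct / len(truth)
    per_class = {
        r: float(mat.loc[r, r] / mat.loc[r].sum()) if mat.loc[r].sum() else 0.0
        for r in rows
        if r in mat.columns
    }
    return mat, overall, per_class
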