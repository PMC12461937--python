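"""Classification with rejection for out-of-distribution particles.

Environmental samples contain many particle types absent from any
training set (debris, rare taxa), and a closed-set classifier silently
assigns them to a known class.  Three rejection mechanisms are
implemented behind one contract (label, scalar score, rejected flag):

* **SoftMax thresholding** — reject when the maximum class probability
  falls below a threshold.
* **Monte-Carlo dropout (MCD)** — run multiple stochastic forward
  passes with dropout active, average the per-pass probabilities, and
  threshold the mean maximum probability.
* **Class-anchor clustering (CAC)** — train the network to embed each
  class near a fixed anchor (scaled one-hot point) with a distance
  loss; classify to the nearest anchor and reject when that distance
  exceeds a threshold.

A fourth strategy is data-side rather than score-side: training with a
*known out-of-distribution class* (KOC), a catch-all debris class whose
predictions map to a null label at reporting time.

The report layer sweeps a shared threshold grid and produces
precision/recall over known-class items plus per-group rejection rates
for the unknown sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from fimflow import nn
from fimflow.classify import (
    CnnConfig,
    CnnModel,
    DataSplit,
    Prediction,
    _class_weights,
    _train_network,
    build_trunk,
    preprocess,
)

#: reserved label for the known out-of-distribution (catch-all debris) class
KOC_LABEL = "KOC"
#: null label reported for rejected / KOC-assigned particles
NULL_LABEL = "(null)"


@dataclass(frozen=True)
class RejectionConfig:
    """Method selection and thresholds for classification with rejection."""

    method: str = "softmax"
    threshold: float = 0.5
    mcd_passes: int = 50
    cac_anchor_magnitude: float = 10.0
    cac_loss_weight: float = 0.1

    def validate(self) -> None:
        if self.method not in ("softmax", "mcd", "cac"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.mcd_passes < 1:
            raise ValueError("mcd_passes must be >= 1")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def confidence(pred: Prediction) -> float:
    """Method-agnostic confidence: higher always means more trustworthy.

    For softmax/MCD the score *is* the confidence (max probability); for
    CAC the score is a distance, so confidence is its negation.
    """
    return -pred.score if pred.method == "cac" else pred.score


# ---------------------------------------------------------------------------
# softmax thresholding


def softmax_reject(pred: Prediction, threshold: float) -> Prediction:
    """Reject when the maximum class probability falls below ``threshold``."""
    score = float(pred.probs.max())
    return replace(pred, score=score, rejected=bool(score < threshold))


# ---------------------------------------------------------------------------
# Monte-Carlo dropout


def mcd_predict(
    model: CnnModel,
    crops: Sequence[np.ndarray],
    passes: int = 50,
    seed: int = 0,
    threshold: float | None = None,
    roi_ids: Sequence[str] | None = None,
) -> list[Prediction]:
    """Mean softmax output over stochastic forward passes (dropout on).

    With ``dropout_rate == 0`` every pass is the deterministic forward
    pass, so the result equals plain prediction exactly.  The rejection
    score is the maximum of the mean probabilities, thresholded the same
    way as softmax thresholding when ``threshold`` is given.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    rng = np.random.default_rng(seed)
    if model.config.dropout_rate == 0.0:
        passes = 1  # every pass is the deterministic forward pass
    mean_probs = []
    for i in range(0, len(crops), 256):
        batch = preprocess(crops[i:i + 256], model.config.input_size)
        acc = np.zeros((batch.shape[0], len(model.classes)))
        for _ in range(passes):
            acc += model.forward_probs(batch, train=True, rng=rng)
        mean_probs.append(acc / passes)
    probs = np.vstack(mean_probs)
    ids = roi_ids if roi_ids is not None else [str(i) for i in range(len(crops))]
    preds = []
    for i in range(len(crops)):
        score = float(probs[i].max())
        preds.append(
            Prediction(
                roi_id=ids[i],
                probs=probs[i],
                argmax_label=model.classes[int(probs[i].argmax())],
                method="mcd",
                rejected=bool(threshold is not None and score < threshold),
                score=score,
            )
        )
    return preds


# ---------------------------------------------------------------------------
# class-anchor clustering


class CacModel(CnnModel):
    """Micro-CNN with a K-dimensional embedding head and fixed class anchors."""

    def __init__(self, net, classes, config, anchors: np.ndarray, history=None):
        super().__init__(net, classes, config, history)
        self.anchors = anchors

    def embed(self, crops: Sequence[np.ndarray]) -> np.ndarray:
        out = []
        for i in range(0, len(crops), 256):
            batch = preprocess(crops[i:i + 256], self.config.input_size)
            out.append(self.net.forward(batch, train=False))
        return np.vstack(out)

    def distances(self, crops: Sequence[np.ndarray]) -> np.ndarray:
        return nn.anchor_distances(self.embed(crops), self.anchors)


def train_cac(
    train: DataSplit,
    val: DataSplit,
    config: CnnConfig,
    rejection: RejectionConfig | None = None,
) -> CacModel:
    """Train the class-anchor-clustering open-set model.

    Same trunk as the closed-set model; the head outputs a K-dimensional
    embedding whose class anchors sit at ``anchor_magnitude`` times the
    one-hot points.  The loss attracts samples to their own anchor and
    repels the others (tuplet term), shrinking intra-class and growing
    inter-class distances.
    """
    config.validate()
    rejection = rejection or RejectionConfig(method="cac")
    classes = sorted(set(train.labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    k = len(classes)
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
        nn.Dense(config.dense_units, k, rng),
    ]
    net = nn.Sequential(layers)
    anchors = rejection.cac_anchor_magnitude * np.eye(k)

    def loss_fn(embed, y):
        return nn.cac_loss(embed, y, anchors, rejection.cac_loss_weight)

    def eval_fn(X, y):
        preds = []
        for i in range(0, len(y), 256):
            d = nn.anchor_distances(net.forward(X[i:i + 256], train=False), anchors)
            preds.append(d.argmin(axis=1))
        return float((np.concatenate(preds) == y).mean())

    history = _train_network(net, X_tr, y_tr, X_va, y_va, config, loss_fn, eval_fn)
    return CacModel(net, classes, config, anchors, history)


def cac_predict(
    model: CacModel,
    crops: Sequence[np.ndarray],
    threshold: float | None = None,
    roi_ids: Sequence[str] | None = None,
) -> list[Prediction]:
    """Nearest-anchor classification; score is the distance (lower = better).

    Rejection triggers when the distance to the nearest anchor exceeds
    ``threshold``.  The reported probabilities are the softmax of the
    negated distances.
    """
    d = model.distances(crops)
    probs = nn.softmax(-d)
    ids = roi_ids if roi_ids is not None else [str(i) for i in range(len(crops))]
    preds = []
    for i in range(len(crops)):
        j = int(d[i].argmin())
        score = float(d[i, j])
        preds.append(
            Prediction(
                roi_id=ids[i],
                probs=probs[i],
                argmax_label=model.classes[j],
                method="cac",
                rejected=bool(threshold is not None and score > threshold),
                score=score,
            )
        )
    return preds


# ---------------------------------------------------------------------------
# known out-of-distribution class (KOC)


def train_with_koc(
    train: DataSplit, val: DataSplit, config: CnnConfig
) -> CnnModel:
    """Train an ordinary (K+1)-class model that includes a KOC class.

    The training split must contain items labeled :data:`KOC_LABEL`
    (a catch-all debris class).  At reporting time KOC predictions map
    to the null label via :func:`map_koc_to_null`.
    """
    if KOC_LABEL not in set(train.labels):
        raise ValueError(f"training split contains no {KOC_LABEL!r} items")
    from fimflow.classify import train_closed_set

    return train_closed_set(train, val, config)


def map_koc_to_null(pred: Prediction) -> Prediction:
    """Report a KOC-class prediction as the null (out-of-distribution) label."""
    if pred.argmax_label == KOC_LABEL:
        return replace(pred, argmax_label=NULL_LABEL, rejected=True)
    return pred


# ---------------------------------------------------------------------------
# precision / recall / rejection report


@dataclass
class OpenSetReport:
    """Threshold sweep of one rejection method over a mixed test set."""

    method: str
    curve: pd.DataFrame  # threshold, precision, recall, rejection_rate_<group>...
    unknown_assignment: dict[str, dict[str, float]]

    def rejection_at_recall(self, group: str, recall: float) -> float:
        """Rejection rate of an unknown group at the threshold whose
        known-class recall is closest to ``recall``."""
        i = (self.curve["recall"] - recall).abs().idxmin()
        return float(self.curve.loc[i, f"rejection_rate_{group}"])


def precision_recall_rejection(
    predictions: Sequence[Prediction],
    truth_labels: Sequence[str],
    unknown_groups: Sequence[str | None],
    n_thresholds: int = 101,
) -> OpenSetReport:
    """Sweep rejection thresholds and measure the resulting trade-offs.

    ``truth_labels[i]`` is the known-class label, or arbitrary for
    unknowns; ``unknown_groups[i]`` is None for known-class items, else
    the unknown group name (e.g. "debris", "novel").  The grid is the
    set of evenly spaced quantiles of the observed confidence
    distribution, so curves are resolution-independent.

    At each threshold items with confidence below it are rejected.
    Precision and recall are computed over known-class items only:
    recall = accepted-and-correct / all known; precision =
    accepted-and-correct / accepted known.  Each unknown group's
    rejection rate is its rejected fraction.
    """
    if not predictions:
        raise ValueError("no predictions")
    if not (len(predictions) == len(truth_labels) == len(unknown_groups)):
        raise ValueError("input lengths differ")
    methods = {p.method for p in predictions}
    if len(methods) != 1:
        raise ValueError("mixed prediction methods in one report")
    method = methods.pop()

    conf = np.array([confidence(p) for p in predictions])
    correct = np.array(
        [p.argmax_label == t for p, t in zip(predictions, truth_labels)]
    )
    known = np.array([g is None for g in unknown_groups])
    groups = sorted({g for g in unknown_groups if g is not None})
    quantiles = np.linspace(0, 1, n_thresholds)
    grid = np.quantile(conf, quantiles)

    rows = []
    for thr in grid:
        accepted = conf >= thr
        n_known = int(known.sum())
        acc_known = accepted & known
        tp = int((acc_known & correct).sum())
        precision = tp / acc_known.sum() if acc_known.sum() else 1.0
        recall = tp / n_known if n_known else 0.0
        row = {"threshold": float(thr), "precision": precision, "recall": recall}
        for g in groups:
            in_g = np.array([x == g for x in unknown_groups])
            row[f"rejection_rate_{g}"] = float((~accepted[in_g]).mean())
        rows.append(row)

    assignment: dict[str, dict[str, float]] = {}
    for g in groups:
        idx = [i for i, x in enumerate(unknown_groups) if x == g]
        labels = [predictions[i].argmax_label for i in idx]
        assignment[g] = {
            lab: labels.count(lab) / len(labels) for lab in sorted(set(labels))
        }
    return OpenSetReport(
        method=method, curve=pd.DataFrame(rows), unknown_assignment=assignment
    )
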