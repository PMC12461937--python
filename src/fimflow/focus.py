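"""Out-of-focus particle filtering with a random-forest classifier.

Degree of focus is a continuous quality, but downstream classification
only wants sharp particles, so a binary in-focus / out-of-focus model is
trained on the morphometric feature catalog.  The training recipe:
stratified 70:30 train/test split, Pearson pruning of redundant
features, impurity-importance ranking, and a final retrain on the
top-12 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from fimflow import features as ft

IN_FOCUS = "in_focus"
OUT_OF_FOCUS = "out_of_focus"


@dataclass
class FocusModel:
    """Trained focus classifier plus its provenance and held-out metrics."""

    estimator: RandomForestClassifier
    feature_names_used: list[str]
    train_seed: int
    metrics: dict
    threshold: float = 0.5

    def predict_proba_out(self, table: pd.DataFrame) -> np.ndarray:
        """Probability that each row is out of focus."""
        missing = [n for n in self.feature_names_used if n not in table.columns]
        if missing:
            raise KeyError(f"feature table missing columns: {missing}")
        X = table[self.feature_names_used].to_numpy(dtype=np.float64)
        idx = list(self.estimator.classes_).index(OUT_OF_FOCUS)
        return self.estimator.predict_proba(X)[:, idx]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "FocusModel":
        return joblib.load(path)


def _fit(
    table: pd.DataFrame,
    labels: np.ndarray,
    names: Sequence[str],
    split_ratio: float,
    seed: int,
    n_estimators: int,
) -> FocusModel:
    X = table[list(names)].to_numpy(dtype=np.float64)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both focus classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples for a stratified split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        labels,
        train_size=split_ratio,
        random_state=seed,
        stratify=labels,
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    per_class = {
        c: float((pred[y_te == c] == c).mean()) for c in classes
    }
    metrics = {
        "overall_accuracy": float((pred == y_te).mean()),
        "per_class_accuracy": per_class,
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
        "n_estimators": n_estimators,
    }
    return FocusModel(
        estimator=forest,
        feature_names_used=list(names),
        train_seed=seed,
        metrics=metrics,
    )


def train_focus_classifier(
    table: pd.DataFrame,
    labels: Sequence[str],
    split_ratio: float = 0.7,
    seed: int = 0,
    n_estimators: int = 200,
) -> FocusModel:
    """Train on all columns of ``table`` with a stratified 70:30 split."""
    return _fit(
        table, np.asarray(labels), list(table.columns), split_ratio, seed, n_estimators
    )


def retrain_top_k(
    model: FocusModel,
    table: pd.DataFrame,
    labels: Sequence[str],
    k: int = 12,
    split_ratio: float = 0.7,
) -> FocusModel:
    """Retrain using only the ``k`` most important features.

    Importance ranking is recomputed on ``table`` restricted to the
    features the input model used.
    """
    if k > len(model.feature_names_used):
        raise ValueError(
            f"k={k} exceeds the {len(model.feature_names_used)} available features"
        )
    ranked = ft.rank_importance(
        table[model.feature_names_used], labels, seed=model.train_seed
    )
    top = ranked[:k]
    new = _fit(
        table,
        np.asarray(labels),
        top,
        split_ratio,
        model.train_seed,
        model.metrics.get("n_estimators", 200),
    )
    return new


def filter_in_focus(
    items: Sequence,
    table: pd.DataFrame,
    model: FocusModel,
) -> tuple[list, list]:
    """Partition ``items`` (parallel to table rows) by predicted focus.

    Returns ``(in_focus, out_of_focus)`` preserving input order.
    """
    if len(items) != len(table):
        raise ValueError("items and feature table lengths differ")
    if len(items) == 0:
        return [], []
    p_out = model.predict_proba_out(table)
    keep, drop = [], []
    for item, p in zip(items, p_out):
        (drop if p >= model.threshold else keep).append(item)
    return keep, drop
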