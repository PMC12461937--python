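"""Morphometric and intensity feature catalog for particle ROIs.

A fixed, ordered catalog of 47 per-particle features spanning shape
(region-property morphometrics), intensity statistics over the particle
support, and edge-noise statistics (gradient- and Laplacian-based
responses in a band around the particle boundary) that track degree of
focus.  The catalog version string travels with every feature vector so
downstream models can detect a schema change.

Also provides the two feature-selection steps used by the focus
classifier: Pearson-correlation pruning of redundant features and
impurity-based importance ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters, measure, morphology
from sklearn.ensemble import RandomForestClassifier

CATALOG_VERSION = "reconstructed-v1"

_SHAPE_NAMES = [
    "area",
    "perimeter",
    "perimeter_crofton",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "solidity",
    "extent",
    "circularity",
    "convexity",
    "aspect_ratio",
    "convex_area",
    "filled_area",
    "euler_number",
    "orientation",
    "bbox_width",
    "bbox_height",
    "bbox_area",
    "feret_diameter_max",
    "hu_moment_1",
    "hu_moment_2",
    "hu_moment_3",
    "hu_moment_4",
]
_INTENSITY_NAMES = [
    "mean_intensity",
    "max_intensity",
    "min_intensity",
    "sd_intensity",
    "median_intensity",
    "intensity_range",
    "intensity_skewness",
    "intensity_kurtosis",
    "p10_intensity",
    "p25_intensity",
    "p75_intensity",
    "p90_intensity",
    "iqr_intensity",
    "integrated_intensity",
    "contrast",
]
_EDGE_NAMES = [
    "edge_noise_gradient",
    "edge_noise_laplacian",
    "mean_gradient",
    "max_gradient",
    "sd_gradient",
    "tenengrad",
    "mean_laplacian_abs",
    "max_laplacian_abs",
]

#: ordered names of the 47-feature catalog
FEATURE_NAMES: tuple[str, ...] = tuple(_SHAPE_NAMES + _INTENSITY_NAMES + _EDGE_NAMES)
assert len(FEATURE_NAMES) == 47

_EPS = 1e-12


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values of one ROI, in catalog order."""

    roi_id: str
    values: Mapping[str, float]
    catalog_version: str = CATALOG_VERSION

    def as_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = FEATURE_NAMES if names is None else names
        return np.array([self.values[n] for n in names], dtype=np.float64)


def _shape_features(mask: np.ndarray, wanted: set[str]) -> dict[str, float]:
    prop = measure.regionprops(mask.astype(np.uint8))[0]
    out: dict[str, float] = {}
    perim = None

    def need(name: str) -> bool:
        return name in wanted

    if need("area") or need("circularity"):
        out["area"] = float(prop.area)
    if {"perimeter", "circularity", "convexity"} & wanted:
        perim = float(prop.perimeter)
        out["perimeter"] = perim
    if need("perimeter_crofton"):
        out["perimeter_crofton"] = float(prop.perimeter_crofton)
    if need("equivalent_diameter"):
        out["equivalent_diameter"] = float(prop.equivalent_diameter_area)
    if {"major_axis_length", "aspect_ratio"} & wanted:
        out["major_axis_length"] = float(prop.axis_major_length)
    if {"minor_axis_length", "aspect_ratio"} & wanted:
        out["minor_axis_length"] = float(prop.axis_minor_length)
    if need("eccentricity"):
        out["eccentricity"] = float(prop.eccentricity)
    if need("solidity"):
        out["solidity"] = float(prop.solidity)
    if need("extent"):
        out["extent"] = float(prop.extent)
    if need("circularity"):
        out["circularity"] = float(
            4 * np.pi * prop.area / max(perim, _EPS) ** 2 if perim else 1.0
        )
    if need("convexity"):
        hull = measure.regionprops(prop.image_convex.astype(np.uint8))[0]
        out["convexity"] = float(hull.perimeter / max(perim, _EPS)) if perim else 1.0
    if need("aspect_ratio"):
        out["aspect_ratio"] = float(
            prop.axis_major_length / max(prop.axis_minor_length, 1.0)
        )
    if need("convex_area"):
        out["convex_area"] = float(prop.area_convex)
    if need("filled_area"):
        out["filled_area"] = float(prop.area_filled)
    if need("euler_number"):
        out["euler_number"] = float(prop.euler_number)
    if need("orientation"):
        out["orientation"] = float(prop.orientation)
    if {"bbox_width", "bbox_height", "bbox_area"} & wanted:
        y0, x0, y1, x1 = prop.bbox
        out["bbox_width"] = float(x1 - x0)
        out["bbox_height"] = float(y1 - y0)
        out["bbox_area"] = float((x1 - x0) * (y1 - y0))
    if need("feret_diameter_max"):
        out["feret_diameter_max"] = float(prop.feret_diameter_max)
    if {"hu_moment_1", "hu_moment_2", "hu_moment_3", "hu_moment_4"} & wanted:
        hu = prop.moments_hu
        for i in range(4):
            out[f"hu_moment_{i + 1}"] = float(hu[i])
    return {k: v for k, v in out.items() if k in wanted}


def _intensity_features(pix: np.ndarray, wanted: set[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    mean = float(pix.mean())
    sd = float(pix.std())
    out["mean_intensity"] = mean
    out["max_intensity"] = float(pix.max())
    out["min_intensity"] = float(pix.min())
    out["sd_intensity"] = sd
    out["median_intensity"] = float(np.median(pix))
    out["intensity_range"] = out["max_intensity"] - out["min_intensity"]
    if {"intensity_skewness", "intensity_kurtosis"} & wanted:
        if sd < _EPS:
            out["intensity_skewness"] = 0.0
            out["intensity_kurtosis"] = 0.0
        else:
            out["intensity_skewness"] = float(stats.skew(pix))
            out["intensity_kurtosis"] = float(stats.kurtosis(pix))
    if {"p10_intensity", "p25_intensity", "p75_intensity", "p90_intensity", "iqr_intensity"} & wanted:
        p10, p25, p75, p90 = np.percentile(pix, [10, 25, 75, 90])
        out.update(
            p10_intensity=float(p10),
            p25_intensity=float(p25),
            p75_intensity=float(p75),
            p90_intensity=float(p90),
            iqr_intensity=float(p75 - p25),
        )
    out["integrated_intensity"] = float(pix.sum())
    out["contrast"] = sd / max(abs(mean), _EPS)
    return {k: v for k, v in out.items() if k in wanted}


def _edge_features(crop: np.ndarray, mask: np.ndarray, wanted: set[str]) -> dict[str, float]:
    grad = filters.sobel(crop)
    lap = np.abs(ndimage.laplace(crop))
    foot = morphology.disk(2)
    band = morphology.dilation(mask, foot) & ~morphology.erosion(mask, foot)
    if not band.any():
        band = mask
    g_in = grad[mask]
    l_in = lap[mask]
    out = {
        "edge_noise_gradient": float(grad[band].mean()),
        "edge_noise_laplacian": float(lap[band].mean()),
        "mean_gradient": float(g_in.mean()),
        "max_gradient": float(g_in.max()),
        "sd_gradient": float(g_in.std()),
        "tenengrad": float((g_in**2).mean()),
        "mean_laplacian_abs": float(l_in.mean()),
        "max_laplacian_abs": float(l_in.max()),
    }
    return {k: v for k, v in out.items() if k in wanted}


def compute_features(
    crop: np.ndarray,
    mask: np.ndarray,
    roi_id: str = "",
    names: Sequence[str] | None = None,
) -> FeatureVector:
    """Compute catalog features for one ROI crop and its support mask.

    ``names`` restricts computation to a subset (kept in catalog order);
    by default the full 47-feature catalog is computed.  All values are
    finite and deterministic.
    """
    if mask.shape != crop.shape:
        raise ValueError("mask and crop shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    wanted = set(FEATURE_NAMES if names is None else names)
    unknown = wanted - set(FEATURE_NAMES)
    if unknown:
        raise KeyError(f"unknown feature names: {sorted(unknown)}")
    crop = np.asarray(crop, dtype=np.float64)
    values: dict[str, float] = {}
    if wanted & set(_SHAPE_NAMES):
        values.update(_shape_features(mask, wanted))
    if wanted & set(_INTENSITY_NAMES):
        values.update(_intensity_features(crop[mask], wanted))
    if wanted & set(_EDGE_NAMES):
        values.update(_edge_features(crop, mask, wanted))
    ordered = {n: values[n] for n in FEATURE_NAMES if n in wanted}
    assert all(np.isfinite(v) for v in ordered.values())
    return FeatureVector(roi_id=roi_id, values=ordered)


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame indexed by roi_id."""
    if not vectors:
        return pd.DataFrame(columns=list(FEATURE_NAMES))
    names = list(vectors[0].values.keys())
    data = [[v.values[n] for n in names] for v in vectors]
    return pd.DataFrame(data, columns=names, index=[v.roi_id for v in vectors])


def prune_correlated(table: pd.DataFrame, r_threshold: float = 0.95) -> list[str]:
    """Drop features that are highly Pearson-correlated with an earlier one.

    Greedy pass in catalog order: a feature is retained only if its
    absolute correlation with every already-retained feature is below
    ``r_threshold``.  Zero-variance features carry no information and are
    dropped with a warning.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 samples for correlation pruning")
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must lie in (0, 1]")
    variances = table.var(axis=0)
    degenerate = [c for c in table.columns if variances[c] < _EPS]
    if degenerate:
        warnings.warn(f"dropping zero-variance features: {degenerate}", stacklevel=2)
    live = [c for c in table.columns if c not in degenerate]
    corr = table[live].corr().abs()
    retained: list[str] = []
    for name in live:
        if all(corr.loc[name, kept] < r_threshold - 1e-12 for kept in retained):
            retained.append(name)
    return retained


def rank_importance(
    table: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    n_estimators: int = 200,
) -> list[str]:
    """Rank features by mean impurity decrease of a random-forest classifier.

    Samples are put into a canonical order before fitting, so the ranking
    depends only on the data multiset and the seed, not on row order.
    Ties are broken by catalog order.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to rank importance")
    X = table.to_numpy(dtype=np.float64)
    order = np.lexsort(np.vstack([X.T, labels.astype("U")]))
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(X[order], labels[order])
    imp = forest.feature_importances_
    ranked = sorted(range(len(imp)), key=lambda i: (-imp[i], i))
    return [table.columns[i] for i in ranked]
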