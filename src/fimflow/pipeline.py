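"""End-to-end orchestration of the processing stages.

Stages communicate through on-disk artifacts (PNG frames, CSV tables,
JSON reports) so each one is independently runnable and testable,
mirroring the batch workflow of the instrument: simulate (or ingest)
frames -> object detection -> feature extraction -> out-of-focus
filtering -> background-particle removal -> optional classification.
The run report records per-stage counts, the global seed and a config
hash, making a run reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from fimflow import bpd as bpd_mod
from fimflow import features as ft
from fimflow import focus as focus_mod
from fimflow import segmenter as seg_mod
from fimflow import synthgen as sg

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "segment", "features", "focus", "bpd")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _scene_config(config: dict, seed: int) -> sg.SceneConfig:
    block = dict(config.get("simulate", {}))
    block.setdefault("seed", seed)
    return sg.SceneConfig(**block)


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute the enabled stages in order and write a run report.

    ``config`` holds one parameter block per stage plus ``seed`` and
    ``stages`` (ordered subset of the default stage list).  Artifacts
    land in ``out_dir``; the report is returned and written as
    ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    unknown = set(stages) - set(DEFAULT_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    report: dict[str, Any] = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": [],
        "counts": {},
    }

    frames: list[np.ndarray] | None = None
    truth = None
    rois_per_frame: list[list[seg_mod.ParticleROI]] | None = None
    table: pd.DataFrame | None = None
    rois_flat: list[seg_mod.ParticleROI] = []

    current = "(setup)"
    try:
        if "simulate" in stages:
            current = "simulate"
            scene = _scene_config(config, seed)
            frames, truth = sg.render_sequence(scene)
            sg.write_frames(frames, out / "frames")
            sg.write_truth(truth, out / "truth.jsonl")
            report["stages"].append("simulate")
            report["counts"]["frames"] = len(frames)
            report["counts"]["truth_particles"] = len(truth)

        if "segment" in stages:
            current = "segment"
            if frames is None:
                in_dir = config.get("segment", {}).get("frames_dir")
                if not in_dir:
                    raise ValueError("segment stage needs frames (simulate or frames_dir)")
                frames = sg.read_frames(in_dir)
            params = seg_mod.SegmenterParams(
                **{k: v for k, v in config.get("segment", {}).items() if k != "frames_dir"}
            )
            rois_per_frame = seg_mod.segment_sequence(frames, params)
            rois_flat = [r for fr in rois_per_frame for r in fr]
            seg_mod.roi_table(rois_flat).to_csv(out / "rois.csv", index=False)
            report["stages"].append("segment")
            report["counts"]["particles_segmented"] = len(rois_flat)

        if "features" in stages:
            current = "features"
            if rois_per_frame is None:
                raise ValueError("features stage needs the segment stage")
            vectors = [
                ft.compute_features(r.crop, r.mask, r.roi_id) for r in rois_flat
            ]
            table = ft.feature_table(vectors)
            table.to_csv(out / "features.csv", index_label="roi_id")
            report["stages"].append("features")

        if "focus" in stages:
            current = "focus"
            if table is None:
                raise ValueError("focus stage needs the features stage")
            block = dict(config.get("focus", {}))
            model_path = block.get("model")
            if model_path:
                model = focus_mod.FocusModel.load(model_path)
            else:
                n_pairs = int(block.get("n_training_pairs", 300))
                rng = np.random.default_rng(seed + 1)
                crops, masks, labels = sg.make_focus_pairs(n_pairs, rng)
                fx = ft.feature_table(
                    [
                        ft.compute_features(c, m, str(i))
                        for i, (c, m) in enumerate(zip(crops, masks))
                    ]
                )
                model = focus_mod.train_focus_classifier(fx, labels, seed=seed + 1)
                model.save(out / "focus_model.joblib")
            keep, drop = focus_mod.filter_in_focus(rois_flat, table, model)
            kept_ids = {r.roi_id for r in keep}
            rois_per_frame = [
                [r for r in fr if r.roi_id in kept_ids] for fr in rois_per_frame
            ]
            rois_flat = keep
            table = table.loc[[r.roi_id for r in rois_flat]]
            report["stages"].append("focus")
            report["counts"]["particles_after_focus"] = len(rois_flat)
            report["counts"]["focus_model_accuracy"] = model.metrics["overall_accuracy"]

        if "bpd" in stages:
            current = "bpd"
            if rois_per_frame is None:
                raise ValueError("bpd stage needs the segment stage")
            params = bpd_mod.BpdParams(
                **{
                    k: tuple(v) if k == "feature_subset" else v
                    for k, v in config.get("bpd", {}).items()
                }
            )
            obs = bpd_mod.particles_from_rois(rois_per_frame, params.feature_subset)
            labels_map = bpd_mod.run_bpd(obs, params)
            tab = seg_mod.roi_table(rois_flat)
            tab["background"] = [labels_map[r.roi_id] for r in rois_flat]
            tab.to_csv(out / "rois_bpd.csv", index=False)
            n_bg = int(tab["background"].sum())
            report["stages"].append("bpd")
            report["counts"]["particles_flagged_background"] = n_bg
            report["counts"]["particles_after_bpd"] = len(rois_flat) - n_bg
            if frames is not None:
                mean_per_frame = (len(rois_flat) - n_bg) / len(frames)
                scene = _scene_config(config, seed)
                fov_um2 = (
                    scene.frame_width_px * scene.um_per_px
                    * scene.frame_height_px * scene.um_per_px
                )
                report["counts"]["estimated_concentration_per_ml"] = (
                    seg_mod.estimate_concentration(mean_per_frame, fov_um2, 200.0)
                )
    except Exception as exc:
        report["error"] = {"stage": current, "cause": str(exc)}
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
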