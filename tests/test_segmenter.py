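"""Object detection and five-category evaluation."""

import numpy as np
import pytest

from fimflow import segmenter as seg
from fimflow import synthgen as sg


def _stamp_scene(centers, specs, cfg):
    """Render one frame with sprites at chosen centers; return frame+truth."""
    frame = np.full((cfg.frame_height_px, cfg.frame_width_px), cfg.background_level)
    truth = []
    for i, (center, spec) in enumerate(zip(centers, specs)):
        patch, mask = sg.make_sprite(spec)
        h, w = patch.shape
        x0, y0 = center[0] - w // 2, center[1] - h // 2
        frame[y0:y0 + h, x0:x0 + w] += patch * cfg.background_level
        truth.append(
            sg.GroundTruthRecord(
                frame_index=0,
                particle_id=f"p{i}",
                center_xy=center,
                is_background=False,
                sprite=spec,
                bbox=(x0, y0, x0 + w, y0 + h),
            )
        )
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8), truth


class TestSegment:
    def test_blank_frame_yields_nothing(self, rng):
        frame = np.clip(128 + rng.normal(0, 2, (100, 100)), 0, 255).astype(np.uint8)
        assert seg.segment(frame, seg.SegmenterParams(threshold_offset=15)) == []

    def test_constant_frame_warns_and_returns_empty(self, caplog):
        frame = np.full((50, 50), 128, dtype=np.uint8)
        with caplog.at_level("WARNING"):
            assert seg.segment(frame, seg.SegmenterParams()) == []
        assert "constant frame" in caplog.text

    def test_well_separated_disks_recovered_one_to_one(self):
        cfg = sg.SceneConfig()
        centers = [(60 + 90 * i, 60 + 90 * j) for i in range(5) for j in range(3)]
        specs = [sg.SpriteSpec("disk", 12.0, -0.5, shape_seed=k) for k in range(15)]
        frame, truth = _stamp_scene(centers, specs, cfg)
        rois = seg.segment(frame, seg.SegmenterParams())
        assert len(rois) == 15
        for rec in truth:
            inside = [
                r for r in rois
                if r.bbox[0] <= rec.center_xy[0] < r.bbox[2]
                and r.bbox[1] <= rec.center_xy[1] < r.bbox[3]
            ]
            assert len(inside) == 1

    def test_adjacent_disks_merge_into_one_roi(self):
        cfg = sg.SceneConfig()
        centers = [(100, 100), (100 + 9, 100)]
        specs = [sg.SpriteSpec("disk", 10.0, -0.5)] * 2
        frame, truth = _stamp_scene(centers, specs, cfg)
        rois = seg.segment(frame, seg.SegmenterParams(closing_radius_px=3))
        assert len(rois) == 1
        x0, y0, x1, y1 = rois[0].bbox
        assert all(x0 <= c[0] < x1 and y0 <= c[1] < y1 for c in centers)

    def test_min_area_monotonicity(self):
        cfg = sg.SceneConfig(n_frames=1, n_targets_per_frame=12, seed=8)
        frames, _ = sg.render_sequence(cfg)
        counts = [
            len(seg.segment(frames[0], seg.SegmenterParams(min_area_px=a)))
            for a in (1, 5, 15, 40, 100)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_roi_invariants(self):
        cfg = sg.SceneConfig(n_frames=1, n_targets_per_frame=8, seed=9)
        frames, _ = sg.render_sequence(cfg)
        for roi in seg.segment(frames[0], seg.SegmenterParams()):
            x0, y0, x1, y1 = roi.bbox
            assert x0 <= roi.centroid_xy[0] < x1
            assert y0 <= roi.centroid_xy[1] < y1
            assert roi.crop.shape == roi.mask.shape


class TestEvaluateOda:
    def _cfg(self):
        return sg.SceneConfig()

    def test_clean_scene_all_true_positive(self):
        cfg = self._cfg()
        centers = [(80, 80), (200, 200), (350, 250)]
        specs = [sg.SpriteSpec("disk", 12.0, -0.5, shape_seed=k) for k in range(3)]
        frame, truth = _stamp_scene(centers, specs, cfg)
        rois = seg.segment(frame, seg.SegmenterParams())
        res = seg.evaluate_oda(rois, truth, cfg)
        assert (res.true_positive, res.false_positive, res.false_negative) == (3, 0, 0)
        assert res.merge == res.split == 0
        assert res.accuracy == 1.0

    def test_spurious_roi_counts_false_positive(self):
        cfg = self._cfg()
        frame, truth = _stamp_scene(
            [(100, 100)], [sg.SpriteSpec("disk", 12.0, -0.5)], cfg
        )
        rois = seg.segment(frame, seg.SegmenterParams())
        fake = seg.ParticleROI(
            frame_index=0,
            roi_id="fake",
            bbox=(300, 300, 310, 310),
            mask=np.ones((10, 10), dtype=bool),
            centroid_xy=(305.0, 305.0),
            area_px=100,
            crop=np.zeros((10, 10)),
        )
        res = seg.evaluate_oda(rois + [fake], truth, cfg)
        assert res.false_positive == 1
        assert res.true_positive == 1

    def test_merged_particles_count_one_merge(self):
        cfg = self._cfg()
        centers = [(100, 100), (109, 100)]
        specs = [sg.SpriteSpec("disk", 10.0, -0.5)] * 2
        frame, truth = _stamp_scene(centers, specs, cfg)
        rois = seg.segment(frame, seg.SegmenterParams(closing_radius_px=3))
        res = seg.evaluate_oda(rois, truth, cfg)
        assert res.merge == 1
        assert res.true_positive == 0

    def test_split_particle_counts_once(self):
        cfg = self._cfg()
        frame, truth = _stamp_scene(
            [(100, 100)], [sg.SpriteSpec("disk", 16.0, -0.5)], cfg
        )
        full = seg.segment(frame, seg.SegmenterParams())[0]
        x0, y0, x1, y1 = full.bbox
        xm = (x0 + x1) // 2
        left = seg.ParticleROI(
            0, "L", (x0, y0, xm, y1), full.mask[:, :xm - x0], (x0 + 1.0, y0 + 1.0),
            int(full.mask[:, :xm - x0].sum()), full.crop[:, :xm - x0],
        )
        right = seg.ParticleROI(
            0, "R", (xm, y0, x1, y1), full.mask[:, xm - x0:], (xm + 1.0, y0 + 1.0),
            int(full.mask[:, xm - x0:].sum()), full.crop[:, xm - x0:],
        )
        res = seg.evaluate_oda([left, right], truth, cfg)
        assert res.split == 1
        assert res.true_positive == 0

    def test_category_totals_bounded_by_roi_count(self):
        cfg = sg.SceneConfig(n_frames=1, n_targets_per_frame=20, seed=10)
        frames, truth = sg.render_sequence(cfg)
        rois = seg.segment(frames[0], seg.SegmenterParams())
        res = seg.evaluate_oda(rois, truth, cfg)
        assert res.true_positive + res.false_positive + res.merge <= len(rois)

    def test_frame_mismatch_is_an_error(self):
        cfg = self._cfg()
        frame, truth = _stamp_scene(
            [(100, 100)], [sg.SpriteSpec("disk", 12.0, -0.5)], cfg
        )
        rois = [
            seg.ParticleROI(
                5, "x", (0, 0, 4, 4), np.ones((4, 4), bool), (1.0, 1.0), 16,
                np.zeros((4, 4)),
            )
        ]
        with pytest.raises(ValueError):
            seg.evaluate_oda(rois, truth, cfg)


class TestConcentration:
    def test_reference_geometry(self):
        # 1 particle/frame over a 725x545 um FOV with a 200 um deep channel
        c = seg.estimate_concentration(1.0, 725 * 545, 200)
        assert c == pytest.approx(1.27e4, rel=0.01)

    def test_zero_particles(self):
        assert seg.estimate_concentration(0.0, 725 * 545, 200) == 0.0

    def test_depth_proportionality(self):
        a = seg.estimate_concentration(3.0, 725 * 545, 200)
        b = seg.estimate_concentration(3.0, 725 * 545, 400)
        assert a == pytest.approx(2 * b)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            seg.estimate_concentration(1.0, -5.0, 200)
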