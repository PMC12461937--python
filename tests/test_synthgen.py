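"""Scene generator: sprite rasterization, sequence rendering, ground truth."""

import numpy as np
import pytest

from fimflow import synthgen as sg


class TestMakeSprite:
    def test_disk_mask_diameter_matches_physical_size(self):
        # 5 um disk at 1.55 um/px spans ~3.2 px; the centroid row of the
        # rasterized mask holds 3 pixels
        patch, mask = sg.make_sprite(sg.SpriteSpec("disk", 5.0, -0.5))
        row = mask[mask.shape[0] // 2]
        assert row.sum() == 3

    def test_zero_blur_is_identity(self):
        spec = sg.SpriteSpec("disk", 10.0, -0.5, blur_sigma_px=0.0)
        patch, mask = sg.make_sprite(spec)
        assert np.array_equal(patch != 0, mask)
        assert set(np.unique(patch)) <= {0.0, -0.5}

    def test_zero_contrast_is_invisible_but_mask_defined(self):
        patch, mask = sg.make_sprite(sg.SpriteSpec("disk", 10.0, 0.0))
        assert np.all(patch == 0)
        assert mask.sum() > 0

    def test_blur_spreads_but_conserves_support_mask(self):
        sharp, m0 = sg.make_sprite(sg.SpriteSpec("disk", 10.0, -0.5, 0.0))
        blurred, m1 = sg.make_sprite(sg.SpriteSpec("disk", 10.0, -0.5, 2.0))
        assert m1.sum() == m0.sum()
        assert blurred.min() > sharp.min()  # peak contrast reduced

    @pytest.mark.parametrize("kind", sg.SPRITE_KINDS)
    def test_sprite_fits_its_patch_and_is_deterministic(self, kind):
        spec = sg.SpriteSpec(kind, 12.0, -0.5, shape_seed=42)
        patch, mask = sg.make_sprite(spec)
        # support does not touch the patch border
        assert not mask[0].any() and not mask[-1].any()
        assert not mask[:, 0].any() and not mask[:, -1].any()
        patch2, mask2 = sg.make_sprite(spec)
        assert np.array_equal(patch, patch2) and np.array_equal(mask, mask2)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sg.make_sprite(sg.SpriteSpec("disk", -1.0, 0.5))
        with pytest.raises(ValueError):
            sg.make_sprite(sg.SpriteSpec("hexagon", 5.0, 0.5))
        with pytest.raises(ValueError):
            sg.make_sprite(sg.SpriteSpec("disk", 5.0, 0.5, blur_sigma_px=-1))


class TestRenderSequence:
    def test_per_frame_truth_count(self):
        cfg = sg.SceneConfig(n_frames=4, n_targets_per_frame=10, n_background=3, seed=0)
        _, truth = sg.render_sequence(cfg)
        for t in range(4):
            assert sum(r.frame_index == t for r in truth) == 13

    def test_same_seed_bitwise_identical(self):
        cfg = sg.SceneConfig(n_frames=3, seed=9)
        f1, t1 = sg.render_sequence(cfg)
        f2, t2 = sg.render_sequence(cfg)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
        assert t1 == t2

    def test_zero_jitter_keeps_background_fixed(self):
        cfg = sg.SceneConfig(
            n_frames=6, n_targets_per_frame=0, n_background=4, max_jitter_px=0, seed=1
        )
        _, truth = sg.render_sequence(cfg)
        centers = {}
        for rec in truth:
            centers.setdefault(rec.particle_id, set()).add(rec.center_xy)
        assert all(len(c) == 1 for c in centers.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_background_jitter_bounded(self, seed):
        cfg = sg.SceneConfig(
            n_frames=12, n_targets_per_frame=0, n_background=6, max_jitter_px=12, seed=seed
        )
        _, truth = sg.render_sequence(cfg)
        base = {r.particle_id: np.array(r.center_xy) for r in truth if r.frame_index == 0}
        for rec in truth:
            d = np.hypot(*(np.array(rec.center_xy) - base[rec.particle_id]))
            assert d <= cfg.max_jitter_px

    def test_particle_id_conventions(self):
        cfg = sg.SceneConfig(n_frames=3, n_targets_per_frame=2, n_background=2, seed=2)
        _, truth = sg.render_sequence(cfg)
        bg = [r for r in truth if r.is_background]
        tg = [r for r in truth if not r.is_background]
        # a background id appears in every frame; a target id in exactly one
        for pid in {r.particle_id for r in bg}:
            assert {r.frame_index for r in bg if r.particle_id == pid} == {0, 1, 2}
        target_ids = [r.particle_id for r in tg]
        assert len(target_ids) == len(set(target_ids))

    def test_truth_records_match_rendered_pixels(self):
        cfg = sg.SceneConfig(
            n_frames=1, n_targets_per_frame=3, n_background=0, seed=3, noise_sigma=0.0
        )
        frames, truth = sg.render_sequence(cfg)
        for rec in truth:
            mask, (x0, y0, x1, y1) = sg.truth_mask(rec, cfg)
            crop = frames[0][y0:y1, x0:x1]
            # particle pixels darker than background where mask is set
            assert crop[mask].mean() < cfg.background_level

    def test_default_frame_geometry(self):
        cfg = sg.SceneConfig()
        assert (cfg.frame_width_px, cfg.frame_height_px) == (468, 352)


class TestFovCoverage:
    def test_high_density_matches_stated_incidence(self):
        # 25 targets + 8 background per frame -> ~0.8% of the field covered
        covs = []
        for seed in range(5):
            cfg = sg.SceneConfig(
                n_frames=3, n_targets_per_frame=25, n_background=8, seed=seed
            )
            _, truth = sg.render_sequence(cfg)
            covs.append(sg.fov_coverage(truth, cfg))
        assert abs(np.mean(covs) - 0.8) <= 0.2

    def test_single_disk_known_area(self):
        # one disk of ~1185 um^2 in a 725x545 um frame covers ~0.3%
        d_um = 2 * np.sqrt(1185 / np.pi)
        cfg = sg.SceneConfig(n_frames=1)
        _, mask = sg.make_sprite(sg.SpriteSpec("disk", d_um, -0.5))
        rec = sg.GroundTruthRecord(
            frame_index=0,
            particle_id="p",
            center_xy=(100, 100),
            is_background=False,
            sprite=sg.SpriteSpec("disk", d_um, -0.5),
            bbox=(100 - mask.shape[1] // 2, 100 - mask.shape[0] // 2,
                  100 + (mask.shape[1] + 1) // 2, 100 + (mask.shape[0] + 1) // 2),
        )
        assert sg.fov_coverage([rec], cfg) == pytest.approx(0.3, abs=0.05)

    def test_empty_truth_is_an_error(self):
        with pytest.raises(ValueError):
            sg.fov_coverage([], sg.SceneConfig())

    def test_adding_a_particle_never_decreases_coverage(self):
        cfg = sg.SceneConfig(n_frames=1, n_targets_per_frame=6, n_background=0, seed=4)
        _, truth = sg.render_sequence(cfg)
        cov_prev = 0.0
        for k in range(1, len(truth) + 1):
            cov = sg.fov_coverage(truth[:k], cfg)
            assert cov >= cov_prev - 1e-12
            cov_prev = cov


class TestFocusPairs:
    def test_counts_and_balance(self, rng):
        crops, masks, labels = sg.make_focus_pairs(100, rng)
        assert len(crops) == len(masks) == len(labels) == 200
        assert labels.count("in_focus") == labels.count("out_of_focus") == 100

    def test_blur_lowers_max_gradient(self, rng):
        crops, _, labels = sg.make_focus_pairs(30, rng)
        for i in range(0, 60, 2):
            sharp = np.abs(np.diff(crops[i].astype(float), axis=1)).max()
            soft = np.abs(np.diff(crops[i + 1].astype(float), axis=1)).max()
            assert labels[i] == "in_focus" and labels[i + 1] == "out_of_focus"
            assert soft < sharp

    def test_seeded_reproducibility(self):
        a = sg.make_focus_pairs(10, np.random.default_rng(5))
        b = sg.make_focus_pairs(10, np.random.default_rng(5))
        assert all(np.array_equal(x, y) for x, y in zip(a[0], b[0]))
        assert a[2] == b[2]

    def test_rejects_nonpositive_n(self, rng):
        with pytest.raises(ValueError):
            sg.make_focus_pairs(0, rng)


class TestRoundTrip:
    def test_frames_and_truth_roundtrip(self, tmp_path):
        cfg = sg.SceneConfig(n_frames=2, n_targets_per_frame=2, n_background=1, seed=6)
        frames, truth = sg.render_sequence(cfg)
        sg.write_frames(frames, tmp_path / "f")
        sg.write_truth(truth, tmp_path / "t.jsonl")
        frames2 = sg.read_frames(tmp_path / "f")
        truth2 = sg.read_truth(tmp_path / "t.jsonl")
        assert all(np.array_equal(a, b) for a, b in zip(frames, frames2))
        assert truth2 == truth
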