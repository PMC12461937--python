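"""Two-stage background-particle detection."""

import numpy as np
import pytest

from fimflow import bpd
from fimflow import synthgen as sg


def _obs(uid, frame, x, y, **feats):
    base = {"area": 40.0, "perimeter": 24.0, "eccentricity": 0.2,
            "hu_moment_1": 0.16, "median_intensity": 70.0, "p75_intensity": 75.0}
    base.update(feats)
    return bpd.ParticleObs(uid=uid, frame_index=frame, centroid_xy=(x, y), features=base)


PARAMS = bpd.BpdParams()


class TestClusterByPosition:
    def test_three_colocated_copies_form_one_cluster(self):
        particles = [_obs(i, i, 100 + i, 100) for i in range(3)]
        clusters = bpd.cluster_by_position(particles, PARAMS)
        assert len(set(clusters.values())) == 1
        assert all(v >= 0 for v in clusters.values())

    def test_isolated_particle_is_noise(self):
        particles = [_obs("a", 0, 50, 50), _obs("b", 1, 300, 300)]
        clusters = bpd.cluster_by_position(particles, PARAMS)
        assert set(clusters.values()) == {-1}

    def test_two_distant_stationary_particles_two_clusters(self):
        eps = PARAMS.distance_threshold_px
        particles = [_obs(f"a{t}", t, 50, 50) for t in range(3)]
        particles += [_obs(f"b{t}", t, 50 + 5 * eps, 50) for t in range(3)]
        clusters = bpd.cluster_by_position(particles, PARAMS)
        a = {clusters[f"a{t}"] for t in range(3)}
        b = {clusters[f"b{t}"] for t in range(3)}
        assert len(a) == len(b) == 1 and a != b
        # brute force: no cross pair within eps
        for p in particles[:3]:
            for q in particles[3:]:
                d = np.hypot(
                    p.centroid_xy[0] - q.centroid_xy[0],
                    p.centroid_xy[1] - q.centroid_xy[1],
                )
                assert d > eps

    def test_empty_window(self):
        assert bpd.cluster_by_position([], PARAMS) == {}


class TestSubcluster:
    def test_identical_copies_one_subcluster(self):
        members = [_obs(i, i, 100, 100) for i in range(3)]
        sub = bpd.subcluster_by_features(members, PARAMS)
        assert len(set(sub.values())) == 1

    def test_colocated_mover_with_different_area_separated(self):
        members = [_obs(0, 0, 100, 100), _obs(1, 1, 100, 100),
                   _obs("mover", 1, 101, 100, area=400.0, perimeter=75.0)]
        sub = bpd.subcluster_by_features(members, PARAMS)
        assert sub[0] == sub[1] != sub["mover"]

    def test_infinite_tolerance_degenerates_to_position_cluster(self):
        members = [_obs(0, 0, 100, 100, area=10.0), _obs(1, 1, 100, 100, area=900.0)]
        params = bpd.BpdParams(feature_tolerance=np.inf)
        sub = bpd.subcluster_by_features(members, params)
        assert len(set(sub.values())) == 1

    def test_missing_feature_is_schema_error(self):
        members = [
            bpd.ParticleObs(uid=i, frame_index=i, centroid_xy=(0, 0), features={"area": 1.0})
            for i in range(2)
        ]
        with pytest.raises(KeyError):
            bpd.subcluster_by_features(members, PARAMS)


class TestFlagBackground:
    def _window(self, particles):
        return bpd.build_window(particles, (0, 1, 2), PARAMS)

    def test_two_of_three_rule_flags_both(self):
        # copies in frames 0 and 2 only
        window = self._window([_obs("a", 0, 100, 100), _obs("b", 2, 102, 100)])
        assert window.flags == {"a": True, "b": True}

    def test_same_frame_subcluster_not_flagged(self):
        window = self._window([_obs("a", 1, 100, 100), _obs("b", 1, 104, 100)])
        assert window.flags == {"a": False, "b": False}

    def test_noise_particle_never_flagged(self):
        window = self._window([_obs("solo", 0, 50, 50)])
        assert window.flags == {"solo": False}


class TestRunBpd:
    def test_needs_three_frames(self):
        with pytest.raises(ValueError):
            bpd.run_bpd([[], []], PARAMS)

    def test_unique_per_frame_particles_unflagged(self, rng):
        frames = []
        for t in range(5):
            frames.append(
                [_obs(f"{t}_{i}", t, 60 + 110 * i, 60 + 90 * t, area=30.0 + 17 * i + 3 * t)
                 for i in range(3)]
            )
        labels = bpd.run_bpd(frames, PARAMS)
        assert not any(labels.values())

    def test_three_frames_equal_single_window(self):
        particles = [
            [_obs("a0", 0, 100, 100)], [_obs("a1", 1, 104, 100)], [_obs("a2", 2, 99, 103)]
        ]
        labels = bpd.run_bpd(particles, PARAMS)
        window = bpd.build_window([p for fr in particles for p in fr], (0, 1, 2), PARAMS)
        assert labels == window.flags

    def test_persistent_particle_flagged_everywhere(self):
        cfg = sg.SceneConfig(n_frames=10, n_targets_per_frame=5, n_background=2, seed=21)
        frames, truth = sg.render_sequence(cfg)
        obs, is_bg = bpd.particles_from_truth(frames, truth, cfg)
        labels = bpd.run_bpd(obs, PARAMS)
        for uid, background in is_bg.items():
            if background:
                assert labels[uid]

    def test_duplicate_uids_rejected(self):
        frames = [[_obs("x", 0, 10, 10)], [_obs("x", 1, 10, 10)], []]
        with pytest.raises(ValueError):
            bpd.run_bpd(frames, PARAMS)

    def test_idempotent_after_removal(self):
        cfg = sg.SceneConfig(n_frames=8, n_targets_per_frame=6, n_background=3, seed=22)
        frames, truth = sg.render_sequence(cfg)
        obs, _ = bpd.particles_from_truth(frames, truth, cfg)
        labels = bpd.run_bpd(obs, PARAMS)
        survivors = [[p for p in fr if not labels[p.uid]] for fr in obs]
        again = bpd.run_bpd(survivors, PARAMS)
        assert not any(again.values())


class TestEvaluate:
    def test_perfect_labels(self):
        truth = {i: i < 3 for i in range(10)}
        acc, fp, fn = bpd.evaluate_bpd(dict(truth), truth)
        assert (acc, fp, fn) == (1.0, 0, 0)

    def test_all_valid_predictor_arithmetic(self):
        truth = {i: i < 4 for i in range(20)}
        labels = {i: False for i in range(20)}
        acc, fp, fn = bpd.evaluate_bpd(labels, truth)
        assert acc == pytest.approx((20 - 4) / 20)
        assert (fp, fn) == (0, 4)

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError):
            bpd.evaluate_bpd({}, {1: True})


class TestOracleEquivalence:
    """On well-separated scenes the detector must agree exactly with a
    brute-force nearest-neighbor tracker."""

    @staticmethod
    def _brute_force(frame_particles, params):
        flat = [p for fr in frame_particles for p in fr]
        labels = {p.uid: False for p in flat}
        n = len(frame_particles)
        for p in flat:
            for q in flat:
                if p.uid == q.uid or p.frame_index == q.frame_index:
                    continue
                if abs(p.frame_index - q.frame_index) > 2:
                    continue
                # must share a 3-frame window
                lo = max(p.frame_index, q.frame_index) - 2
                hi = min(p.frame_index, q.frame_index)
                if not any(0 <= t <= n - 3 for t in range(lo, hi + 1)):
                    continue
                d = np.hypot(
                    p.centroid_xy[0] - q.centroid_xy[0],
                    p.centroid_xy[1] - q.centroid_xy[1],
                )
                if d > params.distance_threshold_px:
                    continue
                fd = bpd._feature_distance_matrix([p, q], params.feature_subset)[0, 1]
                if fd <= params.feature_tolerance:
                    labels[p.uid] = True
        return labels

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_agreement(self, seed):
        rng = np.random.default_rng(seed)
        eps = PARAMS.distance_threshold_px
        n_frames = 6
        frames = [[] for _ in range(n_frames)]
        # stationary background particles, displacement < eps/2 from base
        anchors = [(80.0 + 130 * i, 80.0) for i in range(3)]
        for j, (bx, by) in enumerate(anchors):
            area = 30.0 + 25 * j
            for t in range(n_frames):
                dx, dy = rng.uniform(-eps / 4, eps / 4, 2)
                frames[t].append(
                    _obs((t, f"b{j}"), t, bx + dx, by + dy, area=area,
                         median_intensity=60.0 + 11 * j)
                )
        # free particles on a sparse grid, all pairwise distances > 2 eps
        k = 0
        for t in range(n_frames):
            for i in range(4):
                x = 80.0 + 130 * i
                y = 200.0 + 60 * ((t + i) % 3)
                frames[t].append(
                    _obs((t, f"f{k}"), t, x, y, area=20.0 + 13 * k,
                         median_intensity=40.0 + 7 * (k % 9))
                )
                k += 1
        labels = bpd.run_bpd(frames, PARAMS)
        oracle = self._brute_force(frames, PARAMS)
        assert labels == oracle
        assert sum(labels.values()) == 3 * n_frames  # all background copies


class TestCalibrateTolerance:
    def test_zero_displacement_full_detection(self):
        curve = bpd.calibrate_tolerance(
            [0.0], n_particles=24, n_frames=4, n_background=6, seed=1
        )
        assert curve["detection_rate"].iloc[0] == 1.0

    def test_huge_displacement_never_detected(self):
        curve = bpd.calibrate_tolerance(
            [120.0], n_particles=12, n_frames=4, n_background=4, seed=2
        )
        assert curve["detection_rate"].iloc[0] <= 0.1
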