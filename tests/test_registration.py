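"""Point selection, Lucas-Kanade tracking, MLS interpolation, warping."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates, shift as nd_shift

from chromatrack import registration as reg
from chromatrack import segmentation as segm
from chromatrack.config import RegistrationConfig


def _cfg(**kw):
    return RegistrationConfig(**kw)


class TestSelectTrackPoints:
    def _mask_with_blobs(self, centers, radius=4, shape=(128, 128)):
        m = np.zeros(shape, np.uint8)
        gr, gc = np.mgrid[0:shape[0], 0:shape[1]]
        for r, c in centers:
            m[np.hypot(gr - r, gc - c) <= radius] = 1
        return m

    def test_circular_blob_centroid_selected(self):
        m = self._mask_with_blobs([(40, 40), (40, 90), (90, 40), (90, 90)])
        pts = reg.select_track_points(m, _cfg()).points
        assert len(pts) == 4
        d = np.hypot(*(np.sort(pts, axis=0) - np.sort(
            np.array([(40, 40), (40, 90), (90, 40), (90, 90)], float), axis=0)).T)
        assert d.max() < 0.5

    def test_elongated_blob_excluded_by_eccentricity(self):
        m = self._mask_with_blobs([(30, 30), (30, 90), (90, 30), (90, 90)])
        m[60:62, 20:100] = 1  # 2 x 80 bar
        # oracle: eccentricity of the moment-matched ellipse of a 2 x 80
        # bar is far above 0.9 (a/b ~ 40)
        rr, cc = np.nonzero(m[55:65, :])
        pts = reg.select_track_points(m, _cfg(eccentricity_max=0.9)).points
        assert len(pts) == 4
        assert not any(abs(p[0] - 60.5) < 2 for p in pts)

    def test_edge_points_excluded(self):
        m = self._mask_with_blobs([(3, 64), (40, 40), (40, 90), (90, 40), (90, 90)])
        pts = reg.select_track_points(m, _cfg(edge_offset_fraction=0.05)).points
        assert len(pts) == 4
        assert all(p[0] > 6 for p in pts)

    def test_too_few_points_raises(self):
        m = self._mask_with_blobs([(64, 64)])
        with pytest.raises(reg.RegistrationError):
            reg.select_track_points(m, _cfg())

    def test_grid_subsampling_caps_density(self):
        rng = np.random.default_rng(0)
        centers = [(r, c) for r in range(20, 120, 10) for c in range(20, 120, 10)]
        m = self._mask_with_blobs(centers, radius=3)
        pts = reg.select_track_points(m, _cfg(grid_cells=4, max_points_per_cell=2)).points
        assert len(pts) <= 4 * 4 * 2


def _textured(shape=(128, 128), seed=0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), 2.0)
    return 128 + 40 * img / img.std()


class TestLKTracking:
    def test_static_video_zero_displacement(self):
        img = _textured()
        frames = [img] * 5
        pts = reg.TrackPointSet(points=np.array([[40.0, 40.0], [80.0, 60.0],
                                                 [30.0, 90.0], [90.0, 90.0]]))
        out = reg.track_points(frames, pts, _cfg(), max_step=5.0)
        assert np.abs(out.positions - out.positions[0]).max() < 0.1
        assert out.alive.all()

    def test_global_translation_recovered(self):
        img = _textured((160, 160), seed=1)
        frames = [nd_shift(img, (3.0 * t, 2.0 * t), order=3, mode="nearest")
                  for t in range(4)]
        pts = reg.TrackPointSet(points=np.array(
            [[60.0, 60.0], [60.0, 100.0], [100.0, 60.0], [100.0, 100.0]]))
        out = reg.track_points(frames, pts, _cfg(), max_step=8.0)
        for t in range(1, 4):
            step = out.positions[t] - out.positions[t - 1]
            assert np.abs(step - np.array([3.0, 2.0])).max() < 0.25

    def test_occluded_point_killed_others_survive(self):
        img = _textured((128, 128), seed=2)
        frames = [img.copy() for _ in range(5)]
        for t in (2, 3, 4):
            frames[t] = frames[t].copy()
            frames[t][20:60, 20:60] = 128.0  # flat occluder
        pts = reg.TrackPointSet(points=np.array(
            [[40.0, 40.0], [90.0, 40.0], [40.0, 90.0], [90.0, 90.0], [64.0, 110.0]]))
        out = reg.track_points(frames, pts, _cfg(alive_min_fraction=0.2),
                               max_step=3.0)
        assert not out.alive[-1, 0]
        assert out.alive[-1, 1:].all()

    def test_abort_when_too_many_lost(self):
        img = _textured((128, 128), seed=3)
        flat = np.full((128, 128), 128.0)
        frames = [img, img, flat, flat]
        pts = reg.TrackPointSet(points=np.array(
            [[40.0, 40.0], [90.0, 40.0], [40.0, 90.0], [90.0, 90.0]]))
        with pytest.raises(reg.RegistrationError, match="halted"):
            reg.track_points(frames, pts, _cfg(alive_min_fraction=0.9),
                             max_step=0.5)


class TestMLS:
    def test_constant_displacement_reproduced(self):
        src = np.array([[10.0, 10.0], [10.0, 50.0], [50.0, 10.0], [50.0, 50.0]])
        dst = src + np.array([5.0, 0.0])
        ev = np.array([[30.0, 30.0], [5.0, 60.0], [45.0, 22.0]])
        out = reg.mls_transform(src, dst, ev)
        assert np.abs(out - (ev + [5.0, 0.0])).max() < 1e-6

    def test_affine_field_reproduced_off_controls(self):
        rng = np.random.default_rng(0)
        A = np.array([[1.02, 0.03], [-0.01, 0.98]])
        b = np.array([2.0, -1.0])
        src = rng.uniform(0, 64, (12, 2))
        dst = src @ A.T + b
        ev = rng.uniform(5, 59, (50, 2))
        out = reg.mls_transform(src, dst, ev)
        assert np.abs(out - (ev @ A.T + b)).max() < 0.05

    def test_interpolates_control_points(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 64, (8, 2))
        dst = src + rng.normal(0, 2, (8, 2))
        out = reg.mls_transform(src, dst, src)
        assert np.abs(out - dst).max() < 0.01

    def test_collinear_controls_fall_back_to_similarity(self):
        src = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0], [40.0, 40.0]])
        dst = src + 3.0
        out = reg.mls_transform(src, dst, np.array([[25.0, 10.0]]))
        assert np.isfinite(out).all()
        assert np.abs(out - np.array([[28.0, 13.0]])).max() < 1e-3

    def test_matches_brute_force_weighted_least_squares(self):
        # oracle: per eval point, solve the weighted affine LSQ directly
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 16, (10, 2))
        dst = src + rng.normal(0, 1.5, (10, 2))
        gr, gc = np.mgrid[0:16, 0:16]
        ev = np.stack([gr.ravel(), gc.ravel()], axis=1).astype(float)
        got = reg.mls_transform(src, dst, ev, alpha=1.0)
        X = np.column_stack([src, np.ones(len(src))])
        for i, v in enumerate(ev):
            w = 1.0 / (((src - v) ** 2).sum(1) ** 1.0 + 1e-8)
            W = np.diag(w)
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ dst)
            expect = np.array([v[0], v[1], 1.0]) @ beta
            assert np.abs(got[i] - expect).max() < 1e-6

    def test_dense_field_close_to_pointwise_mls(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(8, 56, (9, 2))
        dst = src + rng.normal(0, 1.0, (9, 2))
        field = reg.mls_dense_field(src, dst, (64, 64), grid_step=4)
        probe = rng.uniform(8, 56, (20, 2))
        direct = reg.mls_transform(src, dst, probe)
        sampled = np.stack([
            map_coordinates(field[i], probe.T, order=1) for i in range(2)
        ], axis=1)
        assert np.abs(sampled - direct).max() < 0.25


class TestWarping:
    def test_identity_map_is_noop(self):
        img = _textured((32, 32))
        coords = np.mgrid[0:32, 0:32].astype(float)
        assert np.allclose(reg.warp_image(img, coords), img)

    def test_warp_roundtrip_recovers_image(self):
        img = _textured((64, 64), seed=5)
        shift_field = np.mgrid[0:64, 0:64].astype(float)
        fwd = shift_field + 3.0   # sample 3 px down/right
        back = shift_field - 3.0
        once = reg.warp_image(img, fwd)
        back_img = reg.warp_image(once, back)
        interior = np.s_[8:56, 8:56]
        assert np.abs(back_img[interior] - img[interior]).max() < 1.0

    def test_label_masks_warp_nearest(self):
        mask = np.zeros((32, 32), np.int32)
        mask[10:20, 10:20] = 7
        coords = np.mgrid[0:32, 0:32].astype(float) + 0.49
        out = reg.warp_image(mask, coords, order=0)
        assert set(np.unique(out)) <= {0, 7}


class TestRegisteredResidual:
    def test_anchor_residual_small_on_deforming_chunk(self, small_video,
                                                      small_config):
        frames, gt = small_video
        masks = segm.segment_video(frames[:25], segm.default_lookup_for_synthetic())
        creg = reg.register_chunk(
            frames[:25], masks[0], small_config.registration,
            max_step=small_config.lk_max_step(), masks=masks)
        res = []
        for t in range(0, 25, 4):
            dm = creg.displacement_map(t)
            for ci in range(len(gt.specs)):
                p = gt.anchor_positions[ci, t]
                r0 = gt.anchor_positions[ci, 0]
                m = np.array([
                    map_coordinates(dm.frame_to_ref[i], p.reshape(2, 1), order=1)[0]
                    for i in range(2)
                ])
                res.append(np.hypot(*(m - r0)))
        res = np.array(res)
        assert np.median(res) <= 1.0
        assert res.max() <= 3.0

    def test_reference_frame_map_is_identity(self, small_video, small_config):
        frames, gt = small_video
        masks = segm.segment_video(frames[:3], segm.default_lookup_for_synthetic())
        creg = reg.register_chunk(frames[:3], masks[0], small_config.registration,
                                  max_step=12.0, masks=masks)
        dm = creg.displacement_map(0)
        assert np.abs(dm.displacement()).max() < 1e-6
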