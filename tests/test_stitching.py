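"""Masterframes, ellipse fits, phase correlation, reprojection error."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as nd_shift

from chromatrack import stitching as st
from chromatrack.config import StitchingConfig


def _textured(shape=(128, 128), seed=0, sigma=3.0, amp=30.0):
    """Masterframe-like image: multiscale mottle plus dark blobs."""
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), sigma)
    fine = gaussian_filter(rng.standard_normal(shape), 1.0)
    out = 150 + amp * img / img.std() + 8 * fine / fine.std()
    gr, gc = np.mgrid[0:shape[0], 0:shape[1]]
    for _ in range(max(4, shape[0] * shape[1] // 2000)):
        r, c = rng.uniform(5, shape[0] - 5), rng.uniform(5, shape[1] - 5)
        rad = rng.uniform(3, 6)
        out[np.hypot(gr - r, gc - c) <= rad] = 40
    return out


class TestMasterframe:
    def test_single_frame_is_itself(self):
        f = _textured((16, 16))
        assert np.allclose(st.compute_masterframe([f]), f)

    def test_two_frame_mean(self):
        a = np.zeros((4, 4))
        b = np.full((4, 4), 100.0)
        assert np.allclose(st.compute_masterframe([a, b]), 50.0)

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(1)
        frames = [rng.uniform(0, 255, (32, 32)) for _ in range(50)]
        oracle = sum(frames) / 50.0
        assert np.allclose(st.compute_masterframe(frames), oracle)


def _raster_ellipse(shape, center, a, b, angle=0.0):
    gr, gc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = gr - center[0], gc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa      # along the major axis placed along rows? no:
    u = dc * ca + dr * sa      # along-major (col-aligned at angle 0)
    v = -dc * sa + dr * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestEllipseFit:
    def test_axis_aligned_ellipse_recovered(self):
        mask = _raster_ellipse((200, 200), (100, 100), 60, 30)
        fit = st.fit_ellipse(mask)
        assert np.hypot(fit.center[0] - 100, fit.center[1] - 100) < 0.5
        assert fit.semi_major == pytest.approx(60, rel=0.02)
        assert fit.semi_minor == pytest.approx(30, rel=0.02)
        assert min(fit.angle, np.pi - fit.angle) < np.deg2rad(2)

    def test_moments_match_brute_force(self):
        mask = _raster_ellipse((160, 160), (80, 70), 50, 25, np.deg2rad(20))
        fit = st.fit_ellipse(mask)
        rr, cc = np.nonzero(mask)
        assert fit.center[0] == pytest.approx(rr.mean(), abs=1e-9)
        assert fit.center[1] == pytest.approx(cc.mean(), abs=1e-9)

    def test_disk_angle_zero_by_convention(self):
        mask = _raster_ellipse((120, 120), (60, 60), 40, 40)
        fit = st.fit_ellipse(mask)
        assert fit.semi_major == pytest.approx(fit.semi_minor, rel=0.01)
        assert fit.angle == 0.0

    def test_rotated_mask_angle_recovered(self):
        mask = _raster_ellipse((220, 220), (110, 110), 70, 30, np.deg2rad(30))
        fit = st.fit_ellipse(mask)
        # mask construction measures angle from the column axis toward rows
        assert fit.angle == pytest.approx(np.deg2rad(30), abs=np.deg2rad(2))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="manual"):
            st.fit_ellipse(np.zeros((10, 10), bool))


class TestCoarseAlign:
    def test_identical_ellipses_identity(self):
        e = st.fit_ellipse(_raster_ellipse((200, 200), (100, 100), 60, 30))
        tr = st.coarse_align(e, e)
        p = np.array([[40.0, 60.0]])
        assert np.abs(tr.apply(p) - p).max() < 1e-9

    def test_translation_recovered(self):
        m1 = _raster_ellipse((220, 220), (100, 100), 60, 30)
        m2 = _raster_ellipse((220, 220), (120, 90), 60, 30)
        tr = st.coarse_align(st.fit_ellipse(m1), st.fit_ellipse(m2))
        p = np.array([[120.0, 90.0]])
        assert np.abs(tr.apply(p) - np.array([[100.0, 100.0]])).max() < 1.0

    def test_rotation_recovered(self):
        m1 = _raster_ellipse((240, 240), (120, 120), 70, 30, 0.0)
        m2 = _raster_ellipse((240, 240), (120, 120), 70, 30, np.deg2rad(10))
        tr = st.coarse_align(st.fit_ellipse(m1), st.fit_ellipse(m2))
        assert abs(abs(tr.rotation) - np.deg2rad(10)) < np.deg2rad(1)

    def test_correspondence_fallback(self):
        pa = np.array([[10.0, 10.0], [10.0, 60.0], [60.0, 10.0]])
        pb = pa + np.array([5.0, -3.0])
        tr = st.coarse_align(correspondences=(pa, pb))
        assert np.abs(tr.apply(pb) - pa).max() < 1e-6

    def test_circular_ellipses_require_correspondences(self):
        e = st.fit_ellipse(_raster_ellipse((120, 120), (60, 60), 40, 40))
        with pytest.raises(ValueError, match="circular"):
            st.coarse_align(e, e)


class TestPhaseCorrelation:
    def test_identical_patches_zero_shift(self):
        a = _textured((64, 64), seed=2)
        shift, peak = st.phase_correlation(a, a)
        assert np.abs(shift).max() < 0.05
        assert peak > 0.5

    @pytest.mark.parametrize("d", [(4.0, -3.0), (-2.0, 5.0)])
    def test_known_integer_shift_recovered(self, d):
        a = _textured((64, 64), seed=3)
        b = nd_shift(a, d, order=3, mode="wrap")
        shift, peak = st.phase_correlation(a, b)
        assert np.abs(shift - np.array(d)).max() < 0.3
        # cross-check against the library phase correlation
        from skimage.registration import phase_cross_correlation
        lib_shift, _, _ = phase_cross_correlation(b, a, upsample_factor=10)
        assert np.abs(shift - lib_shift).max() < 0.5

    def test_subpixel_shift_recovered(self):
        a = _textured((96, 96), seed=4, sigma=4.0)
        b = nd_shift(a, (1.5, -2.25), order=3, mode="wrap")
        shift, _ = st.phase_correlation(a, b)
        assert np.abs(shift - np.array([1.5, -2.25])).max() < 0.35

    def test_constant_patch_zero_peak(self):
        a = np.full((32, 32), 77.0)
        shift, peak = st.phase_correlation(a, a)
        assert peak < 0.15


class TestRefineAlignment:
    def test_known_shift_everywhere(self):
        a = _textured((256, 256), seed=5, sigma=3.0)
        b = nd_shift(a, (4.0, -3.0), order=3, mode="nearest")
        pa, pb = st.refine_alignment(a, b, st.SimilarityTransform(),
                                     StitchingConfig())
        assert len(pa) > 10
        disp = pb - pa
        assert np.abs(disp - np.array([4.0, -3.0])).max() < 0.5

    def test_featureless_image_fails(self):
        a = np.full((200, 200), 100.0)
        with pytest.raises(RuntimeError, match="dropped"):
            st.refine_alignment(a, a, st.SimilarityTransform(), StitchingConfig())


class TestReprojectionError:
    def _identity(self, shape=(32, 32)):
        return st.identity_field(shape)

    def test_identity_maps_zero(self):
        m = np.ones((32, 32), bool)
        assert st.reprojection_error(self._identity(), self._identity(), m) == 0.0

    def test_consistent_shift_zero(self):
        ab = self._identity() + np.array([5.0, 0.0])[:, None, None]
        ba = self._identity() - np.array([5.0, 0.0])[:, None, None]
        m = np.zeros((32, 32), bool)
        m[8:24, 8:24] = True
        assert st.reprojection_error(ab, ba, m) == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_shift_measures_gap(self):
        ab = self._identity() + np.array([5.0, 0.0])[:, None, None]
        ba = self._identity() - np.array([3.0, 0.0])[:, None, None]
        m = np.zeros((32, 32), bool)
        m[8:24, 8:24] = True
        assert st.reprojection_error(ab, ba, m) == pytest.approx(2.0, abs=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            st.reprojection_error(self._identity(), self._identity(),
                                  np.zeros((32, 32), bool))


class TestComposition:
    def test_compose_with_identity(self):
        f = st.identity_field((16, 16)) + 2.0
        ident = st.identity_field((16, 16))
        assert np.allclose(st.compose_fields(ident, f), f)
        # outer lookup applied to identity inner stays the outer field
        assert np.allclose(st.compose_fields(f, ident)[:, :14, :14],
                           f[:, :14, :14])


class TestStitchPair:
    def test_shifted_masterframe_accepted_and_accurate(self):
        a = _textured((256, 256), seed=6, sigma=3.0)
        b = nd_shift(a, (7.0, -5.0), order=3, mode="nearest")
        al = st.stitch_pair(a, b, StitchingConfig())
        assert al.accepted
        assert al.reprojection_error_px <= 2.0
        # the map must send A pixels to their shifted location in B
        inner = np.s_[64:192, 64:192]
        disp = al.a_to_b - st.identity_field((256, 256))
        assert np.abs(disp[0][inner] - 7.0).max() < 0.5
        assert np.abs(disp[1][inner] + 5.0).max() < 0.5
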