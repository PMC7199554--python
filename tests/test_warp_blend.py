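import numpy as np
import pytest

from retimosaic import warp_blend as wb
from retimosaic.camera import Camera, Intrinsics
from .conftest import rot_y


def cam(f=700.0, w=700, h=605, R=None):
    return Camera(Intrinsics.centered(f, w, h),
                  np.eye(3) if R is None else R)


class TestSphericalMapping:
    def test_principal_point_maps_to_equator(self):
        c = Camera(Intrinsics(700, 700, 0.0, 0.0))
        u, w_, v = wb.pixel_to_sphere(np.array([[0.0, 0.0]]), c)
        assert u[0] == pytest.approx(0.0)
        assert w_[0] == pytest.approx(0.0)
        assert v[0] == pytest.approx(np.pi / 2)

    def test_one_pixel_right_of_center(self):
        c = Camera(Intrinsics(700, 700, 0.0, 0.0))
        u, _, v = wb.pixel_to_sphere(np.array([[1.0, 0.0]]), c)
        assert u[0] == pytest.approx(np.arctan(1 / 700))
        assert v[0] == pytest.approx(np.pi / 2)

    def test_equator_backprojects_to_principal_point(self):
        c = Camera(Intrinsics(700, 700, 0.0, 0.0))
        x, y, ok = wb.sphere_to_pixel(np.array(0.0), np.array(np.pi / 2), c)
        assert ok and x == pytest.approx(0.0, abs=1e-12) \
            and y == pytest.approx(0.0, abs=1e-12)

    def test_pole_is_invalid(self):
        c = cam()
        _, _, ok = wb.sphere_to_pixel(np.array(0.0), np.array(0.0), c)
        assert not ok

    def test_round_trip_inverse_consistency(self, rng):
        c = cam(R=rot_y(0.2))
        pts = rng.random((1000, 2)) * [699, 604]
        u, _, v = wb.pixel_to_sphere(pts, c)
        x, y, ok = wb.sphere_to_pixel(u, v, c)
        assert ok.all()
        err = np.hypot(x - pts[:, 0], y - pts[:, 1])
        assert err.max() < 1e-9


class TestWarpImage:
    def test_near_identity_warp_preserves_center_and_area(self, rng):
        # smooth image so sub-pixel resampling differences stay small
        yy, xx = np.mgrid[0:100, 0:120].astype(float)
        img = 100 + 50 * np.sin(xx / 25) + 40 * np.cos(yy / 20)
        c = cam(f=5000.0, w=120, h=100)
        layer = wb.warp_image(img, c, sphere_scale=5000.0)
        assert abs(int(layer.valid.sum()) - img.size) / img.size < 0.02
        cy, cx = layer.valid.shape[0] // 2, layer.valid.shape[1] // 2
        assert abs(layer.image[cy, cx] - img[50, 60]) < 3

    def test_yaw_shifts_footprint_in_azimuth(self):
        img = np.full((60, 80), 128.0)
        f = 2000.0
        base = wb.warp_image(img, cam(f=f, w=80, h=60), f)
        yawed = wb.warp_image(img, cam(f=f, w=80, h=60, R=rot_y(0.3)), f)
        dx = (yawed.offset[0] + yawed.valid.shape[1] / 2) \
            - (base.offset[0] + base.valid.shape[1] / 2)
        assert dx == pytest.approx(f * 0.3, rel=0.05)

    def test_valid_mask_respects_footprint(self, rng):
        img = rng.random((60, 80)) * 255
        fp = np.zeros((60, 80), np.uint8)
        fp[10:50, 20:60] = 1
        layer = wb.warp_image(img, cam(f=3000.0, w=80, h=60), 3000.0,
                              footprint=fp)
        assert layer.valid.sum() <= fp.sum() * 1.05
        assert layer.image[layer.valid == 0].max() == 0.0


class TestGainCompensation:
    def _layer(self, img, offset=(0, 0)):
        arr = np.asarray(img, dtype=np.float64)
        return wb.WarpedLayer(arr, np.ones(arr.shape[:2], np.uint8), offset)

    def test_identical_layers_get_unit_gains(self, rng):
        img = rng.random((40, 40)) * 200
        gains = wb.gain_compensate([self._layer(img), self._layer(img)])
        assert np.allclose(gains, 1.0, atol=1e-6)

    def test_half_brightness_layer_compensated(self, rng):
        # oracle: solve the regularised 2x2 normal equations by hand.
        # Minimising (a g1 - b g2)^2/sn^2 + ((1-g1)^2 + (1-g2)^2)/sg^2 at
        # stationarity gives e = (a-b)/(1 + (a^2+b^2) k), g1 = 1 - a e k,
        # g2 = 1 + b e k with k = sg^2/sn^2
        img = rng.random((40, 60)) * 100 + 100
        gains = wb.gain_compensate([self._layer(img),
                                    self._layer(img * 0.5)])
        a = float(img.mean())
        b = a / 2.0
        k = 0.01 / 100.0  # sg^2 / sn^2
        e = (a - b) / (1.0 + (a * a + b * b) * k)
        assert gains[0] == pytest.approx(1 - a * e * k, rel=1e-6)
        assert gains[1] == pytest.approx(1 + b * e * k, rel=1e-6)
        # the darker layer is brightened relative to the brighter one
        assert gains[1] / gains[0] > 1.5

    def test_single_layer_unit_gain(self, rng):
        gains = wb.gain_compensate([self._layer(rng.random((20, 20)))])
        assert gains.tolist() == [1.0]

    def test_disjoint_layers_unit_gains(self, rng):
        a = self._layer(rng.random((20, 20)), offset=(0, 0))
        b = self._layer(rng.random((20, 20)), offset=(100, 100))
        assert np.allclose(wb.gain_compensate([a, b]), 1.0)


class TestPyramids:
    def test_reconstruction_identity(self, rng):
        img = rng.random((97, 123)) * 255
        _, lap = wb.build_pyramids(img, levels=5)
        assert len(lap) == 5
        rec = wb.collapse_pyramid(lap)
        assert np.abs(rec - img).max() < 1e-6

    def test_level_dims_ceil_halve(self, rng):
        g, _ = wb.build_pyramids(rng.random((97, 123)), levels=5)
        dims = [lvl.shape for lvl in g]
        assert dims == [(97, 123), (49, 62), (25, 31), (13, 16), (7, 8)]

    def test_constant_image_laplacians_vanish(self):
        img = np.full((64, 64), 77.0)
        _, lap = wb.build_pyramids(img, levels=5)
        for lvl in lap[:-1]:
            assert np.abs(lvl).max() < 1e-9
        assert np.allclose(lap[-1], 77.0)

    def test_small_image_reduces_levels(self):
        _, lap = wb.build_pyramids(np.ones((5, 5)), levels=5)
        assert 1 <= len(lap) < 5
        assert np.abs(wb.collapse_pyramid(lap) - 1.0).max() < 1e-9

    def test_color_reconstruction(self, rng):
        img = rng.random((40, 50, 3)) * 255
        _, lap = wb.build_pyramids(img, levels=4)
        assert np.abs(wb.collapse_pyramid(lap) - img).max() < 1e-6


class TestMultibandBlend:
    def _layer(self, img, valid=None, offset=(0, 0)):
        arr = np.asarray(img, dtype=np.float64)
        if valid is None:
            valid = np.ones(arr.shape[:2], np.uint8)
        return wb.WarpedLayer(arr, valid, offset)

    def test_self_blend_is_idempotent(self, rng):
        img = np.round(rng.random((80, 96)) * 255)
        out, cov, origin = wb.multiband_blend(
            [self._layer(img), self._layer(img.copy())])
        assert origin == (0, 0)
        assert cov.all()
        assert np.abs(out - img).max() <= 1.0

    def test_equal_constant_layers(self):
        a = self._layer(np.full((60, 60), 100.0), offset=(0, 0))
        b = self._layer(np.full((60, 60), 100.0), offset=(30, 0))
        out, cov, _ = wb.multiband_blend([a, b])
        assert np.abs(out[cov > 0] - 100.0).max() <= 1.0

    def test_seam_transition_stays_in_range(self):
        a = self._layer(np.full((60, 60), 80.0), offset=(0, 0))
        b = self._layer(np.full((60, 60), 120.0), offset=(30, 0))
        out, cov, _ = wb.multiband_blend([a, b])
        vals = out[cov > 0]
        assert vals.min() >= 79.0 and vals.max() <= 121.0
        # far sides keep their own intensity
        assert np.abs(out[30, 5] - 80.0) <= 1.0
        assert np.abs(out[30, 85] - 120.0) <= 1.0

    def test_single_layer_returned_as_is(self, rng):
        img = rng.random((32, 32)) * 255
        out, cov, _ = wb.multiband_blend([self._layer(img)])
        assert np.abs(out - img).max() < 1e-9
        assert cov.all()

    def test_uncovered_pixels_are_zero_and_flagged(self):
        valid = np.zeros((40, 40), np.uint8)
        valid[:, :20] = 1
        a = self._layer(np.full((40, 40), 90.0), valid=valid)
        out, cov, _ = wb.multiband_blend(
            [a, self._layer(np.full((20, 20), 90.0), offset=(60, 0))])
        assert (out[cov == 0] == 0).all()
        assert cov[0, 10] == 1 and cov[0, 30] == 0


class TestGroundTruthSceneMosaic:
    def test_two_view_mosaic_matches_scene(self):
        from scipy import ndimage
        from retimosaic import synthetic as syn
        from retimosaic.pipeline import fov_footprint

        seq = syn.generate_sequence(seed=5, n_views=2, overlap_target=0.5,
                                    view_size=(420, 364), vignette=0.0)
        f = seq.cameras_gt[0].K.fx
        layers = [wb.warp_image(img.astype(float), c, sphere_scale=f,
                                footprint=fov_footprint(img))
                  for img, c in zip(seq.images, seq.cameras_gt)]
        wb.gain_compensate(layers)
        wb.apply_gains(layers)
        mosaic, cov, (x0, y0) = wb.multiband_blend(layers)
        gt, gt_valid = syn.ground_truth_mosaic(
            seq.scene, (x0, y0, mosaic.shape[1], mosaic.shape[0]), f)

        def placed(layer):
            m = np.zeros(cov.shape, bool)
            sy, sx = layer.offset[1] - y0, layer.offset[0] - x0
            m[sy:sy + layer.valid.shape[0],
              sx:sx + layer.valid.shape[1]] = layer.valid > 0
            return m

        ma, mb = placed(layers[0]), placed(layers[1])
        overlap = ma & mb & (gt_valid > 0)
        da = ndimage.distance_transform_edt(ma)
        db = ndimage.distance_transform_edt(mb)
        seam_side = db > da
        seam_band = ndimage.binary_dilation(seam_side, iterations=2) \
            & ndimage.binary_dilation(~seam_side, iterations=2)
        region = overlap & ~seam_band
        assert region.sum() > 10000
        mae = np.abs(mosaic[region] - gt[region]).mean()
        assert mae <= 3.0
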