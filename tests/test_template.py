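"""Cortex segmentation, boundary landmarks, R-table and 3D edge cloud."""

import numpy as np
import pytest

from bonereg import (SectionImage, VolumeImage, build_rtable, gradient_edges_3d,
                     make_landmarks, segment_cortices)
from bonereg.imagecore import BinaryMask


def _two_rectangles(specks=0):
    img = np.zeros((60, 80))
    img[8:20, 10:70] = 1.0
    img[40:52, 10:70] = 1.0
    rng = np.random.default_rng(5)
    for _ in range(specks):
        r, c = rng.integers(27, 34), rng.integers(5, 75)
        img[r, c] = 1.0
    return SectionImage(img, (1, 1))


class TestSegmentCortices:
    def test_two_bright_rectangles_recovered(self):
        img = _two_rectangles()
        mask = segment_cortices(img)
        np.testing.assert_array_equal(mask.data, img.data > 0.5)

    def test_specks_removed_by_area_ranking(self):
        img = _two_rectangles(specks=5)
        mask = segment_cortices(img)
        # area-ranking oracle: the two rectangles are the two largest
        # components; every speck pixel must be absent
        clean = _two_rectangles().data > 0.5
        np.testing.assert_array_equal(mask.data, clean)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            segment_cortices(SectionImage(np.ones((20, 20)), (1, 1)))

    def test_single_component_raises(self):
        img = np.zeros((30, 30))
        img[5:25, 5:25] = 1.0
        with pytest.raises(ValueError, match="component"):
            segment_cortices(SectionImage(img, (1, 1)))

    def test_invariant_under_affine_intensity_rescale(self):
        img = _two_rectangles(specks=3)
        a = segment_cortices(img)
        b = segment_cortices(SectionImage(7.0 * img.data + 42.0, (1, 1)))
        np.testing.assert_array_equal(a.data, b.data)


class TestLandmarks:
    def _circle(self, radius=20, shape=(64, 64)):
        yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        c = (shape[0] - 1) / 2
        rho = np.hypot(yy - c, xx - c)
        mask = rho <= radius
        img = np.where(mask, 1.0, 0.0)
        return BinaryMask(mask, (1, 1)), SectionImage(img, (1, 1)), c, radius

    def test_circle_landmarks_match_analytic_gradient(self):
        mask, img, c, radius = self._circle()
        lms = make_landmarks(mask, img, 16)
        assert len(lms) == 16
        for lm in lms:
            r = np.hypot(lm.position[0] - c, lm.position[1] - c)
            assert abs(r - radius) <= 1.0
            # gradient of a bright disk points toward the centre (radially in)
            inward = np.arctan2(c - lm.position[0], c - lm.position[1])
            diff = np.angle(np.exp(1j * (lm.boundary_angle - inward)))
            assert abs(np.degrees(diff)) < 10

    def test_clipping_when_n_exceeds_perimeter(self):
        mask, img, *_ = self._circle(radius=4, shape=(16, 16))
        with pytest.warns(UserWarning, match="clipping"):
            lms = make_landmarks(mask, img, 360)
        assert len(lms) <= int(mask.data.sum())

    def test_landmarks_on_every_component(self):
        img = _two_rectangles()
        mask = segment_cortices(img)
        lms = make_landmarks(mask, img, 40)
        rows = np.array([lm.position[0] for lm in lms])
        assert (rows < 30).any() and (rows > 30).any()


class TestRTable:
    def test_single_landmark_degenerate(self):
        from bonereg.template import Landmark2D
        rt = build_rtable([Landmark2D(position=(0, 0), boundary_angle=0.0)],
                          np.deg2rad(5))
        assert np.allclose(rt.reference_point, (0, 0))
        (offsets,) = rt.bins.values()
        np.testing.assert_allclose(offsets[0], (0, 0))

    def test_centroid_reference_and_reconstruction(self):
        from bonereg.template import Landmark2D
        corners = [(0, 0), (0, 1), (1, 0), (1, 1)]
        lms = [Landmark2D(position=p, boundary_angle=a)
               for p, a in zip(corners, (-3.0, -1.0, 1.0, 3.0))]
        rt = build_rtable(lms, np.deg2rad(5))
        np.testing.assert_allclose(rt.reference_point, (0.5, 0.5))
        for lm in lms:
            b = int(rt.bin_index(lm.boundary_angle))
            offs = np.asarray(rt.bins[b])
            # offset + position = reference point, exactly, for some entry
            assert any(np.allclose(lm.position + o, rt.reference_point)
                       for o in offs)


class TestGradientEdges:
    def _ball(self, n=32, radius=10.0, spacing=2.0):
        zz, yy, xx = np.meshgrid(*(np.arange(n) * spacing,) * 3, indexing="ij")
        c = (n - 1) / 2 * spacing
        rho = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        return VolumeImage((rho <= radius).astype(float), (spacing,) * 3), c, radius

    def test_ball_edges_on_sphere_surface(self):
        vol, c, radius = self._ball()
        cloud = gradient_edges_3d(vol, 90.0)
        r = np.linalg.norm(cloud.points - c, axis=1)
        assert np.mean(np.abs(r - radius)) < vol.spacing[0]

    def test_ball_directions_near_radial(self):
        vol, c, radius = self._ball()
        cloud = gradient_edges_3d(vol, 90.0)
        radial = (cloud.points - c)
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cosang = np.abs(np.sum(cloud.gradient_dirs * radial, axis=1))
        assert np.median(np.degrees(np.arccos(np.clip(cosang, -1, 1)))) < 15

    def test_percentile_count(self):
        rng = np.random.default_rng(0)
        vol = VolumeImage(rng.random((16, 16, 16)), (1, 1, 1))
        import scipy.ndimage as ndi
        data = ndi.gaussian_filter(vol.data, 1.0)
        gz, gy, gx = np.gradient(data, 1.0)
        mag = np.sqrt(gz ** 2 + gy ** 2 + gx ** 2)
        n_nonzero = (mag > 0).sum()
        cloud = gradient_edges_3d(vol, 99.0)
        assert abs(cloud.points.shape[0] - 0.01 * n_nonzero) <= 0.002 * n_nonzero + 2

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError):
            gradient_edges_3d(VolumeImage(np.ones((8, 8, 8)), (1, 1, 1)), 95.0)
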