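"""Core types, I/O round-trips, projection and downsampling."""

import numpy as np
import pytest

from bonereg import (AffineTransform2D, CuttingPlane, RegistrationMetrics,
                     SectionImage, VolumeImage, ZStack, downsample,
                     max_projection, read_volume, write_volume)
from bonereg.imagecore import cross


def _vol(rng, shape=(8, 8, 8), spacing=(1.0, 2.0, 3.0)):
    return VolumeImage(data=rng.random(shape).astype(np.float32), spacing=spacing)


@pytest.mark.parametrize("suffix", [".nrrd", ".mha", ".tif"])
def test_volume_roundtrip_lossless(tmp_path, suffix):
    rng = np.random.default_rng(3)
    vol = _vol(rng)
    path = tmp_path / f"v{suffix}"
    write_volume(vol, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.data, vol.data)
    assert back.spacing == pytest.approx(vol.spacing)


def test_tiff_volume_needs_spacing_sidecar(tmp_path):
    import tifffile
    tifffile.imwrite(str(tmp_path / "raw.tif"), np.zeros((4, 4, 4), np.float32))
    with pytest.raises(ValueError, match="spacing"):
        read_volume(tmp_path / "raw.tif")
    # explicit spacing substitutes for the sidecar (μCT voxel size)
    v = read_volume(tmp_path / "raw.tif", spacing=(10.5, 10.5, 10.5))
    assert v.spacing == (10.5, 10.5, 10.5)


def test_read_errors(tmp_path):
    with pytest.raises(IOError):
        read_volume(tmp_path / "missing.nrrd")
    bad = tmp_path / "truncated.nrrd"
    bad.write_bytes(b"NRRD0004\n# truncated")
    with pytest.raises(IOError):
        read_volume(bad)


def test_max_projection_matches_elementwise_oracle():
    rng = np.random.default_rng(1)
    arr = rng.random((3, 12, 10))
    stack = ZStack(slices=[SectionImage(a, (1, 1)) for a in arr], z_spacing=2.0)
    proj = max_projection(stack)
    np.testing.assert_array_equal(proj.data, arr.max(axis=0))
    # single-slice identity
    single = ZStack(slices=[SectionImage(arr[0], (1, 1))], z_spacing=1.0)
    np.testing.assert_array_equal(max_projection(single).data, arr[0])


def test_max_projection_commutes_with_monotone_rescale():
    rng = np.random.default_rng(2)
    arr = rng.random((4, 9, 9))
    stack = ZStack(slices=[SectionImage(a, (1, 1)) for a in arr], z_spacing=1.0)
    scaled = ZStack(slices=[SectionImage(3 * a + 1, (1, 1)) for a in arr], z_spacing=1.0)
    np.testing.assert_allclose(max_projection(scaled).data,
                               3 * max_projection(stack).data + 1)


class TestDownsample:
    def test_factor_one_is_identity(self):
        rng = np.random.default_rng(0)
        img = SectionImage(rng.random((16, 16)), (0.6, 0.6))
        out = downsample(img, 1)
        np.testing.assert_array_equal(out.data, img.data)
        assert out.spacing == img.spacing

    def test_constant_preserved(self):
        img = SectionImage(np.full((32, 32), 5.0), (1, 1))
        out = downsample(img, 4)
        np.testing.assert_allclose(out.data, 5.0)

    def test_spacing_arithmetic(self):
        # 0.6 μm section decimated x16 -> 9.6 μm pixels
        img = SectionImage(np.zeros((64, 64)), (0.6, 0.6))
        assert downsample(img, 16).spacing == pytest.approx((9.6, 9.6))

    def test_composition_on_smooth_image(self):
        yy, xx = np.meshgrid(np.linspace(0, 1, 128), np.linspace(0, 1, 128),
                             indexing="ij")
        img = SectionImage(np.sin(4 * yy) * np.cos(3 * xx), (1, 1))
        once = downsample(img, 4)
        twice = downsample(downsample(img, 2), 2)
        rng_dyn = img.data.max() - img.data.min()
        assert np.abs(once.data - twice.data).max() < 0.02 * rng_dyn

    def test_invalid_factor(self):
        img = SectionImage(np.zeros((8, 8)), (1, 1))
        with pytest.raises(ValueError):
            downsample(img, 0)


class TestDomainTypes:
    def test_cutting_plane_frame_invariants(self):
        p = CuttingPlane.from_normal((0, 0, 0), (1.0, 0.4, 0.2))
        assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-9)
        assert abs(p.axis_u @ p.axis_v) < 1e-9
        np.testing.assert_allclose(cross(p.axis_u, p.axis_v), p.normal, atol=1e-9)

    def test_cutting_plane_rejects_bad_frame(self):
        with pytest.raises(ValueError):
            CuttingPlane(center=(0, 0, 0), axis_u=(1, 0, 0), axis_v=(1, 0, 0))

    def test_cutting_plane_json_roundtrip(self, tmp_path):
        p = CuttingPlane.from_normal((10, 20, 30), (0.9, 0.1, 0.4))
        p.to_json(tmp_path / "p.json")
        q = CuttingPlane.from_json(tmp_path / "p.json")
        np.testing.assert_allclose(q.center, p.center)
        np.testing.assert_allclose(q.normal, p.normal)

    def test_affine_requires_invertible_matrix(self):
        with pytest.raises(ValueError):
            AffineTransform2D(matrix=np.zeros((2, 2)))

    def test_metrics_enforce_average_invariant(self):
        with pytest.raises(ValueError):
            RegistrationMetrics(dsc_proximal=1.0, dsc_distal=0.0, dsc=0.9,
                                ssim_proximal=1, ssim_distal=1, ssim=1,
                                jacobian_min=1, jacobian_mean=1, jacobian_max=1)

    def test_metrics_csv_roundtrip(self, tmp_path):
        m = RegistrationMetrics(dsc_proximal=0.9, dsc_distal=0.7, dsc=0.8,
                                ssim_proximal=0.5, ssim_distal=0.3, ssim=0.4,
                                jacobian_min=0.8, jacobian_mean=1.01, jacobian_max=1.3)
        m.to_csv(tmp_path / "m.csv")
        back = RegistrationMetrics.from_csv(tmp_path / "m.csv")
        assert back == m
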