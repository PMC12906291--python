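"""Oblique slice extraction, resizing, channel propagation and GHT voting."""

import numpy as np
import pytest

from bonereg import (AffineTransform2D, CuttingPlane, SectionImage, VolumeImage,
                     ZStack, extract_oblique_slice, generate_orientations,
                     ght_search, propagate_to_channel, resize_to_section)
from bonereg.template import EdgeCloud3D, Landmark2D, build_rtable


def _axis_plane(vol, k):
    center = np.array([k * vol.spacing[0],
                       (vol.shape[1] - 1) / 2 * vol.spacing[1],
                       (vol.shape[2] - 1) / 2 * vol.spacing[2]])
    return CuttingPlane(center=center, axis_u=(0, 0, 1.0), axis_v=(0, 1.0, 0))


class TestExtractObliqueSlice:
    def test_axis_aligned_plane_returns_volume_slice(self):
        rng = np.random.default_rng(1)
        vol = VolumeImage(rng.random((6, 10, 12)), (2.0, 2.0, 2.0))
        sl, valid = extract_oblique_slice(vol, _axis_plane(vol, 3),
                                          (10, 12), vol.spacing[1:])
        np.testing.assert_allclose(sl.data, vol.data[3], atol=1e-12)
        assert valid.data.all()

    def test_half_voxel_shift_in_linear_ramp(self):
        # volume whose value is the z index: shifting the plane by half a
        # voxel along z must shift values by half the per-voxel increment
        data = np.broadcast_to(np.arange(8.0)[:, None, None], (8, 8, 8)).copy()
        vol = VolumeImage(data, (1.0, 1.0, 1.0))
        plane = _axis_plane(vol, 3)
        shifted = CuttingPlane(center=plane.center + np.array([0.5, 0, 0]),
                               axis_u=plane.axis_u, axis_v=plane.axis_v)
        sl, valid = extract_oblique_slice(vol, shifted, (8, 8), (1.0, 1.0))
        np.testing.assert_allclose(sl.data[valid.data], 3.5, atol=1e-12)

    def test_plane_outside_volume_is_zero_and_invalid(self):
        vol = VolumeImage(np.ones((6, 6, 6)), (1, 1, 1))
        plane = _axis_plane(vol, 3)
        far = CuttingPlane(center=plane.center + np.array([100.0, 0, 0]),
                           axis_u=plane.axis_u, axis_v=plane.axis_v)
        sl, valid = extract_oblique_slice(vol, far, (6, 6), (1, 1))
        assert not valid.data.any()
        np.testing.assert_array_equal(sl.data, 0.0)

    def test_matches_brute_force_trilinear_oracle(self):
        """Tilted-plane extraction vs an independent per-pixel trilinear
        interpolation written out longhand."""
        rng = np.random.default_rng(7)
        vol = VolumeImage(rng.random((16, 16, 16)), (1.0, 1.5, 2.0))
        plane = CuttingPlane.from_normal((8.0, 11.0, 14.0), (0.9, 0.3, 0.2))
        out_shape, out_sp = (9, 11), (1.1, 0.9)
        sl, valid = extract_oblique_slice(vol, plane, out_shape, out_sp)

        def trilinear(p):
            idx = (p - np.zeros(3)) / np.asarray(vol.spacing)
            if np.any(idx < 0) or np.any(idx > np.asarray(vol.shape) - 1):
                return 0.0, False
            i0 = np.floor(idx).astype(int)
            i0 = np.minimum(i0, np.asarray(vol.shape) - 2)
            f = idx - i0
            acc = 0.0
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        w = ((f[0] if dz else 1 - f[0]) * (f[1] if dy else 1 - f[1])
                             * (f[2] if dx else 1 - f[2]))
                        acc += w * vol.data[i0[0] + dz, i0[1] + dy, i0[2] + dx]
            return acc, True

        R, C = (out_shape[0] - 1) / 2, (out_shape[1] - 1) / 2
        for r in range(out_shape[0]):
            for c in range(out_shape[1]):
                p = (plane.center + (c - C) * out_sp[1] * plane.axis_u
                     + (r - R) * out_sp[0] * plane.axis_v)
                val, ok = trilinear(p)
                assert valid.data[r, c] == ok
                if ok:
                    assert abs(sl.data[r, c] - val) < 1e-9


class TestResize:
    def test_identity_shape(self):
        img = SectionImage(np.arange(12.0).reshape(3, 4), (2, 2))
        out = resize_to_section(img, img)
        np.testing.assert_array_equal(out.data, img.data)

    def test_constancy_under_upsampling(self):
        img = SectionImage(np.full((8, 8), 3.0), (2, 2))
        target = SectionImage(np.zeros((16, 16)), (1, 1))
        np.testing.assert_allclose(resize_to_section(img, target).data, 3.0)

    def test_up_down_roundtrip_on_smooth_image(self):
        yy, xx = np.meshgrid(np.linspace(0, 1, 32), np.linspace(0, 1, 32),
                             indexing="ij")
        img = SectionImage(np.sin(3 * yy + 2 * xx), (2, 2))
        up = resize_to_section(img, SectionImage(np.zeros((64, 64)), (1, 1)))
        back = resize_to_section(up, img)
        assert np.abs(back.data - img.data).max() < 0.02 * np.ptp(img.data)


class TestPropagate:
    def _blob(self, at, shape=(40, 40)):
        img = np.zeros(shape)
        img[at[0] - 2:at[0] + 3, at[1] - 2:at[1] + 3] = 1.0
        return SectionImage(img, (1.0, 1.0))

    def _centroid(self, img):
        w = img.data
        idx = np.argwhere(w > 0.5)
        return idx.mean(axis=0)

    def test_identity_affine_is_noop(self):
        img = self._blob((20, 20))
        out = propagate_to_channel(img, AffineTransform2D())
        np.testing.assert_allclose(out.data, img.data, atol=1e-12)

    def test_translation_moves_blob_centroid(self):
        img = self._blob((15, 20))
        aff = AffineTransform2D(translation=np.array([5.0, 0.0]))
        out = propagate_to_channel(img, aff)
        np.testing.assert_allclose(self._centroid(out), [20, 20], atol=0.01)

    def test_zstack_propagates_slicewise(self):
        img = self._blob((15, 20))
        stack = ZStack(slices=[img, img], z_spacing=1.0)
        aff = AffineTransform2D(translation=np.array([0.0, 3.0]))
        out = propagate_to_channel(stack, aff)
        assert len(out) == 2
        np.testing.assert_allclose(self._centroid(out.slices[0]), [15, 23], atol=0.01)

    def test_shape_mismatch_rejected(self):
        img = self._blob((15, 20), shape=(30, 30))
        with pytest.raises(ValueError, match="shape"):
            propagate_to_channel(img, AffineTransform2D(), reference_shape=(40, 40))


class TestGHTVoting:
    def _planted(self, psi0=0.0):
        """A rectangle-outline template planted in 3D at a known pose on the
        plane z = 30 with centre (30, 60, 60).

        For normal z the voting frame is u = x (columns), v = cross(n, u) =
        -y (rows); the planted points and gradient directions are expressed
        in exactly that frame.
        """
        # rectangle outline (2-fold symmetric: psi determined mod 180 deg)
        pts, angs = [], []
        for s in np.linspace(-20, 20, 12, endpoint=False):
            pts += [(-10.0, s), (10.0, s)]
            angs += [-np.pi / 2, np.pi / 2]
        for s in np.linspace(-10, 10, 6, endpoint=False):
            pts += [(s, -20.0), (s, 20.0)]
            angs += [-np.pi, 0.0]
        lms = [Landmark2D(position=(r + 50.0, c + 50.0), boundary_angle=a)
               for (r, c), a in zip(pts, angs)]
        rtable = build_rtable(lms, np.deg2rad(10))
        cp, sp = np.cos(psi0), np.sin(psi0)
        u0, v0 = np.array([0.0, 0.0, 1.0]), np.array([0.0, -1.0, 0.0])
        center0 = np.array([30.0, 60.0, 60.0])
        points, dirs = [], []
        for (r, c), a in zip(pts, angs):
            col = cp * c - sp * r
            row = sp * c + cp * r
            points.append(center0 + col * u0 + row * v0)
            ga = a + psi0
            dirs.append(np.cos(ga) * u0 + np.sin(ga) * v0)
        edges = EdgeCloud3D(points=np.array(points), gradient_dirs=np.array(dirs),
                            gradient_mags=np.ones(len(points)))
        return rtable, edges

    def test_planted_pose_recovered(self):
        psi0 = np.deg2rad(30)
        rtable, edges = self._planted(psi0)
        hyps, acc = ght_search(edges, rtable, translation_step=4.0, top_k=3,
                               orientations=(np.array([[1.0, 0, 0]]),
                                             np.deg2rad(np.arange(0, 360, 10.0))))
        best = hyps[0]
        assert abs(best.plane.normal @ np.array([1.0, 0, 0])) > 0.999
        dpsi = np.angle(np.exp(2j * (best.in_plane_rotation - psi0))) / 2
        assert abs(np.degrees(dpsi)) <= 10.0
        # reference lands at the planted square centre depth
        assert abs(best.plane.center[0] - 30.0) <= 4.0

    def test_vote_counts_equivariant_under_rotation(self):
        """Rotating edges and the evaluated orientations together must not
        change the vote counts."""
        from bonereg.slicefinder import _rodrigues
        rtable, edges = self._planted(0.0)
        normals = np.array([[1.0, 0, 0]])
        psis = np.deg2rad(np.arange(0, 360, 30.0))
        _, acc_a = ght_search(edges, rtable, translation_step=4.0, top_k=1,
                              orientations=(normals, psis))
        # rotate about the frame's up-hint axis (x) so the voting frames of
        # the rotated normals are exactly the rotated frames
        R = _rodrigues(np.array([0.0, 0.0, 1.0]), np.deg2rad(90))
        edges_rot = EdgeCloud3D(points=edges.points @ R.T,
                                gradient_dirs=edges.gradient_dirs @ R.T,
                                gradient_mags=edges.gradient_mags)
        _, acc_b = ght_search(edges_rot, rtable, translation_step=4.0, top_k=1,
                              orientations=(normals @ R.T, psis))
        np.testing.assert_allclose(acc_a.best_votes, acc_b.best_votes, atol=1e-6)

    def test_empty_edges_rejected(self):
        rtable, edges = self._planted()
        empty = EdgeCloud3D(points=np.zeros((0, 3)), gradient_dirs=np.zeros((0, 3)),
                            gradient_mags=np.zeros(0))
        with pytest.raises(ValueError):
            ght_search(empty, rtable, translation_step=4.0)
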