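"""Surface projection: alignment, segmentation, mapping, layer sampling."""

import numpy as np
import pytest

from anpflow.projection import (AlignedFrame, AlignmentError,
                                SegmentationError, align_frame,
                                build_projection, extract_surface,
                                project_volume, segment_embryo,
                                unproject_points)


def _flat_frame():
    return AlignedFrame(0.0, np.array([0.0, 0.0]),
                        np.array([[0.0, 0.0], [10.0, 0.0]]),
                        np.array([0.0, 1.0]), np.array([1.0, 0.0]))


def _flat_map(n=41, z0=0.0):
    xs = np.arange(n, dtype=float)
    ys = np.arange(n, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel(),
                           np.full(X.size, z0)])
    frame = AlignedFrame(0.0, np.array([n // 2, n // 2], dtype=float),
                         np.array([[0.0, 0.0], [10.0, 0.0]]),
                         np.array([0.0, 1.0]), np.array([1.0, 0.0]))
    return build_projection(pts, frame, voxel_size=(1, 1, 1),
                            orientation="max_z", z_smooth_sigma=2.0)


class TestAlignFrame:
    def test_unrotated_front_gives_near_zero_rotation(self, phantom):
        vol, _ = phantom
        af = align_frame(vol.channels["marker"], chord_range=(20, 60))
        assert abs(af.rotation_z) < np.pi / 36

    def test_recovers_applied_rotation(self, rotated_phantom):
        vol, truth = rotated_phantom
        af = align_frame(vol.channels["marker"], chord_range=(20, 60))
        err = (af.rotation_z - truth.rotation_applied + np.pi / 2) \
            % np.pi - np.pi / 2
        assert abs(err) < np.pi / 36

    def test_axes_orthonormal_and_away_from_marker(self, phantom):
        vol, truth = phantom
        af = align_frame(vol.channels["marker"], chord_range=(20, 60))
        assert abs(af.axis_u @ af.axis_v) < 1e-9
        # marker sits at −y in the unrotated phantom: u points to +y
        assert af.axis_u[1] > 0.8

    def test_empty_marker_channel_raises_alignment_error(self):
        with pytest.raises(AlignmentError):
            align_frame(np.zeros((5, 50, 50)))

    def test_no_chords_in_range_raises_naming_the_step(self, phantom):
        vol, _ = phantom
        with pytest.raises(AlignmentError, match="chord"):
            align_frame(vol.channels["marker"], chord_range=(4000, 5000))


class TestSegmentEmbryo:
    def test_solid_hemisphere_recovered_with_high_dice(self):
        rng = np.random.default_rng(0)
        z, y, x = np.mgrid[0:60, 0:120, 0:120]
        truth = (x - 60) ** 2 + (y - 60) ** 2 + (z - 55) ** 2 <= 50 ** 2
        img = 0.8 * truth + 0.05 * rng.random(truth.shape)
        mask = segment_embryo(img)
        dice = 2 * np.logical_and(mask, truth).sum() / (mask.sum() +
                                                        truth.sum())
        assert dice > 0.95

    def test_constant_image_raises(self):
        with pytest.raises(SegmentationError):
            segment_embryo(np.ones((20, 40, 40)))

    def test_largest_component_kept(self):
        img = np.zeros((30, 80, 80))
        img[5:25, 5:55, 5:55] = 1.0       # large blob
        img[10:14, 70:74, 70:74] = 1.0    # small blob
        rng = np.random.default_rng(1)
        img += 0.02 * rng.random(img.shape)
        mask = segment_embryo(img, phansalkar_radius=10)
        assert mask[12, 30, 30]
        assert not mask[12, 72, 72]


class TestExtractSurface:
    def _hemisphere_mask(self, pole_at_zero: bool):
        z, y, x = np.mgrid[0:40, 0:80, 0:80]
        zc = 39.0 if pole_at_zero else 0.0
        r = np.sqrt((x - 40.) ** 2 + (y - 40.) ** 2 + (z - zc) ** 2)
        return r <= 38

    def test_orientation_flips_with_stack(self):
        m = self._hemisphere_mask(pole_at_zero=True)
        _, orient = extract_surface(m, np.array([40.0, 40.0]))
        _, orient_flipped = extract_surface(m[::-1],
                                            np.array([40.0, 40.0]))
        assert {orient, orient_flipped} == {"min_z", "max_z"}

    def test_surface_close_to_analytic_sphere(self, phantom):
        vol, truth = phantom
        pts, orient = extract_surface(truth.cell_labels > 0,
                                      truth.sphere_center[:2])
        assert orient == "max_z"
        d = np.linalg.norm(pts - truth.sphere_center, axis=1)
        # columns near the cap rim graze the sphere; in the central cap
        # the per-column top voxel is within one voxel of the surface
        inplane = np.linalg.norm(pts[:, :2] - truth.sphere_center[:2],
                                 axis=1)
        central = inplane < 0.8 * truth.sphere_radius * np.sin(
            truth.cap_half_angle)
        frac = np.mean(np.abs(d[central] - truth.sphere_radius) <= 1.0)
        assert frac > 0.99

    def test_single_slice_mask_raises(self):
        m = np.zeros((5, 20, 20), dtype=bool)
        m[2, 5:15, 5:15] = True
        with pytest.raises(ValueError, match="single z-slice"):
            extract_surface(m, np.array([10.0, 10.0]))

    def test_degenerate_cylinder_ties_to_min_z_with_warning(self):
        m = np.zeros((20, 40, 40), dtype=bool)
        m[:, 10:30, 10:30] = True
        with pytest.warns(UserWarning, match="tie"):
            _, orient = extract_surface(m, np.array([20.0, 20.0]))
        assert orient == "min_z"


class TestBuildProjection:
    def test_flat_surface_forward_map_is_identity(self):
        smap = _flat_map()
        pts = np.array([[3.0, 7.0, 0.0], [-5.0, 2.0, 0.0]])
        pts_abs = pts + smap.origin_um
        q = smap.forward(pts_abs)
        np.testing.assert_allclose(q, pts[:, :2], atol=1e-9)

    def test_sphere_chord_closed_form(self, phantom):
        """Point at polar angle φ maps to planar radius 2R·sin(φ/2)."""
        vol, truth = phantom
        from anpflow.projection import align_frame
        af = align_frame(vol.channels["marker"], chord_range=(20, 60))
        pts, orient = extract_surface(truth.cell_labels > 0, af.origin)
        smap = build_projection(pts, af, voxel_size=vol.voxel_size,
                                orientation=orient)
        R = truth.sphere_radius
        rng = np.random.default_rng(0)
        th = rng.uniform(0.05, truth.cap_half_angle * 0.9, 200)
        ph = rng.uniform(0, 2 * np.pi, 200)
        p3 = truth.sphere_center + R * np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
             np.cos(th)])
        q = smap.forward(p3)
        o_dir = (smap.origin_um - truth.sphere_center) / \
            np.linalg.norm(smap.origin_um - truth.sphere_center)
        p_dir = (p3 - truth.sphere_center) / R
        phi = np.arccos(np.clip(p_dir @ o_dir, -1, 1))
        chord = 2 * R * np.sin(phi / 2)
        assert np.percentile(
            np.abs(np.hypot(q[:, 0], q[:, 1]) - chord), 95) < 0.5

    def test_roundtrip_forward_inverse(self, phantom):
        vol, truth = phantom
        af = align_frame(vol.channels["marker"], chord_range=(20, 60))
        pts, orient = extract_surface(truth.cell_labels > 0, af.origin)
        smap = build_projection(pts, af, voxel_size=vol.voxel_size,
                                orientation=orient)
        rng = np.random.default_rng(1)
        sel = pts[rng.choice(len(pts), 300, replace=False)]
        q = smap.forward(sel)
        back, ok = smap.inverse(q)
        q2 = smap.forward(back[ok])
        err = np.hypot(*(q2 - q[ok]).T)
        assert np.mean(ok) * np.mean(err < 1.0) > 0.95

    def test_nonfinite_surface_raises(self):
        pts = np.array([[0.0, 0.0, np.nan], [1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            build_projection(pts, _flat_frame())


class TestProjectVolume:
    def test_flat_surface_layers_equal_z_slices(self):
        smap = _flat_map(n=31, z0=5.0)
        vol = np.zeros((10, 31, 31))
        for k in range(10):
            vol[k] = k * 10.0
        stack = project_volume(vol, smap, n_layers_below=3)
        for k in range(4):
            vals = stack.layers[k][stack.mask[k]]
            assert np.all(vals == (5 - k) * 10.0)

    def test_zero_layers_gives_surface_only(self):
        smap = _flat_map(n=31, z0=2.0)
        vol = np.random.default_rng(0).random((5, 31, 31))
        stack = project_volume(vol, smap, n_layers_below=0)
        assert stack.layers.shape[0] == 1

    def test_depth_monotone_toward_sphere_centre(self, phantom):
        vol, truth = phantom
        af = align_frame(vol.channels["marker"], chord_range=(20, 60))
        pts, orient = extract_surface(truth.cell_labels > 0, af.origin)
        smap = build_projection(pts, af, voxel_size=vol.voxel_size,
                                orientation=orient)
        S = smap.surface_xyz
        N = smap.normals
        ok = smap.valid
        dists = []
        for k in (0, 3, 6):
            P = (S - k * N)[ok]
            orig = smap.to_original(P)
            dists.append(np.nanmedian(
                np.linalg.norm(orig - truth.sphere_center, axis=1)))
        assert dists[0] > dists[1] > dists[2]

    def test_out_of_volume_samples_become_masked_sentinels(self):
        smap = _flat_map(n=31, z0=1.0)
        vol = np.ones((3, 31, 31))
        stack = project_volume(vol, smap, n_layers_below=4)
        assert not stack.mask[4].any()      # below the stack
        assert np.all(np.isnan(stack.layers[4]))


class TestUnprojectPoints:
    def test_flat_identity_at_zero_depth(self):
        smap = _flat_map()
        q = np.array([[2.0, 3.0], [-4.0, 1.0]])
        pts, ok = unproject_points(q, smap, depth=0.0)
        assert ok.all()
        np.testing.assert_allclose(pts[:, :2] - smap.origin_um[:2], q,
                                   atol=1e-9)

    def test_flat_depth_moves_z_down_exactly(self):
        smap = _flat_map(z0=0.0)
        pts, ok = unproject_points(np.array([[1.0, 1.0]]), smap,
                                   depth=3.0)
        assert ok.all()
        assert pts[0, 2] == pytest.approx(-3.0, abs=1e-9)

    def test_forward_of_unprojected_point_roundtrips(self, phantom):
        vol, truth = phantom
        af = align_frame(vol.channels["marker"], chord_range=(20, 60))
        pts, orient = extract_surface(truth.cell_labels > 0, af.origin)
        smap = build_projection(pts, af, voxel_size=vol.voxel_size,
                                orientation=orient)
        q = np.array([[10.0, 20.0], [-15.0, 5.0], [0.0, 30.0]])
        p3, ok = unproject_points(q, smap, depth=0.0)
        q2 = smap.forward(p3[ok])
        assert np.all(np.hypot(*(q2 - q[ok]).T) < 0.5)

    def test_point_outside_domain_flagged(self):
        smap = _flat_map(n=21)
        pts, ok = unproject_points(np.array([[500.0, 500.0]]), smap)
        assert not ok[0]
        assert np.all(np.isnan(pts[0]))
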