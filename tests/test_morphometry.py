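"""Tissue and cell shape measurements and the validation protocol."""

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from anpflow.fields import Track
from anpflow.morphometry import (DomainOrientation, cell_metrics,
                                 domain_orientation, internalisation_depth,
                                 segment_cells_2d, tissue_shape,
                                 validate_segmentation)


class TestTissueShape:
    def test_rectangle_area_and_width_exact(self):
        img = np.zeros((200, 200))
        img[40:140, 50:130] = 1.0          # H=100, W=80
        shape = tissue_shape(img, smooth_sigma=0.0)
        assert shape.area == 100 * 80
        assert shape.width_ml == 80

    def test_ellipse_area_within_two_percent(self):
        img = np.zeros((520, 520))
        rr, cc = draw_ellipse(260, 260, 200, 120, shape=img.shape)
        img[rr, cc] = 1.0
        shape = tissue_shape(img, smooth_sigma=0.0)
        assert shape.area == pytest.approx(np.pi * 200 * 120, rel=0.02)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            tissue_shape(np.zeros((50, 50)))


class TestCellMetrics:
    def _ellipse_labels(self, a, b, deg):
        img = np.zeros((301, 301), dtype=np.int32)
        rr, cc = draw_ellipse(150, 150, b, a, shape=img.shape,
                              rotation=np.deg2rad(-deg))
        img[rr, cc] = 1
        return img

    def test_rotated_ellipse_orientation_and_axes(self):
        rec = cell_metrics(self._ellipse_labels(100, 60, 30))[0]
        assert abs(np.degrees(rec.orientation) - 30) < 2.0
        assert rec.major == pytest.approx(200, rel=0.02)
        assert rec.minor == pytest.approx(120, rel=0.02)

    def test_rotation_equivariance(self):
        r1 = cell_metrics(self._ellipse_labels(100, 60, 20))[0]
        r2 = cell_metrics(self._ellipse_labels(100, 60, 50))[0]
        d = np.degrees(r2.orientation - r1.orientation)
        d = (d + 90) % 180 - 90
        assert abs(d - 30) < 1.0

    def test_circle_orientation_flagged_undefined(self):
        img = np.zeros((201, 201), dtype=np.int32)
        rr, cc = draw_ellipse(100, 100, 60, 60, shape=img.shape)
        img[rr, cc] = 1
        rec = cell_metrics(img)[0]
        assert not rec.orientation_defined
        assert np.isnan(rec.orientation)
        assert rec.major == pytest.approx(rec.minor, rel=0.01)

    def test_identity_map_back_projection(self):
        rec = cell_metrics(self._ellipse_labels(80, 40, 0),
                           surface_map=None)[0]
        assert rec.major_3d == pytest.approx(rec.major, rel=1e-9)
        assert np.all(rec.axis_endpoints_3d[:, 2] == 0)

    def test_border_touching_flagged(self):
        img = np.zeros((60, 60), dtype=np.int32)
        img[0:20, 10:30] = 1
        rec = cell_metrics(img)[0]
        assert rec.touches_border


class TestSegmentCells:
    def test_blank_image_gives_no_labels(self):
        assert segment_cells_2d(np.zeros((64, 64))).max() == 0

    def test_single_ring_one_interior_label(self):
        img = np.zeros((101, 101))
        yy, xx = np.mgrid[0:101, 0:101]
        r = np.hypot(yy - 50, xx - 50)
        img[np.abs(r - 30) < 2.5] = 1.0
        labels = segment_cells_2d(img)
        interior = set(np.unique(labels)) - {0}
        border_labels = set(labels[0]) | set(labels[-1]) | \
            set(labels[:, 0]) | set(labels[:, -1])
        enclosed = interior - border_labels
        assert len(enclosed) == 1

    def test_phantom_layer_benchmark(self, phantom):
        """Most phantom cells segment at IoU > 0.6, on par with the
        reported 76% success rate of the experimental protocol."""
        from anpflow.projection import (align_frame, build_projection,
                                        extract_surface, project_volume)
        vol, truth = phantom
        af = align_frame(vol.channels["marker"], chord_range=(20, 60))
        pts, orient = extract_surface(truth.cell_labels > 0, af.origin)
        smap = build_projection(pts, af, voxel_size=vol.voxel_size,
                                orientation=orient)
        mem = project_volume(vol, smap, 4, channel="membrane")
        lab = project_volume(truth.cell_labels.astype(float), smap, 4,
                             interpolation="nearest")
        from scipy import ndimage
        layer = mem.layers[3]
        truth_layer = np.nan_to_num(lab.layers[3], nan=0.0).astype(int)
        pred = segment_cells_2d(layer, smooth_sigma=1.0, h_rel=0.04)
        # score interior cells: at the cap rim the phantom tissue simply
        # ends, so edge cells have no closing membrane ridge — an
        # artifact of the finite phantom, not of the segmentation
        ok = np.isfinite(layer)
        tissue = truth_layer > 0
        keep = np.zeros_like(truth_layer)
        for t in np.unique(truth_layer):
            if t == 0:
                continue
            m = truth_layer == t
            if m.sum() < 60 or not np.all(ok[m]):
                continue
            ring = ndimage.binary_dilation(m, iterations=3)
            if np.all(tissue[ring]):
                keep[m] = t
        report = validate_segmentation(pred, keep)
        assert report.n_truth >= 30
        assert report.success_rate >= 0.76


class TestDomainOrientation:
    def _records(self, thetas, t=0.0):
        from anpflow.morphometry import CellShapeRecord
        recs = []
        for i, th in enumerate(thetas):
            recs.append(CellShapeRecord(
                label=i + 1, centroid=np.array([5.0 * i - 10, 0.0]),
                area=100.0, orientation=th, orientation_defined=True,
                major=20.0, minor=10.0,
                axis_endpoints_3d=np.zeros((4, 3)),
                major_3d=20.0, minor_3d=10.0))
        return [(t, recs)]

    def test_aligned_cells_give_their_common_orientation(self):
        series = self._records([np.deg2rad(30)] * 5)
        out = domain_orientation(series, lambda t: np.zeros(2), box=60.0)
        assert np.degrees(out.mean_orientation) == pytest.approx(30.0)
        assert out.mean_elongation == pytest.approx(2.0)

    def test_axial_antipodes_flagged_undefined(self):
        series = self._records([np.deg2rad(45), np.deg2rad(-45)])
        out = domain_orientation(series, lambda t: np.zeros(2), box=60.0)
        assert not out.defined
        assert out.resultant_length < 1e-6

    def test_orientations_track_rotational_flow_tangent(self):
        """Cells riding a rotational flow with tangent orientations: the
        domain mean follows the local flow direction."""
        from anpflow.morphometry import CellShapeRecord
        rng = np.random.default_rng(0)
        center = np.array([30.0, 0.0])
        series = []
        for k, t in enumerate(np.linspace(-8, 8, 5)):
            recs = []
            for i in range(12):
                pos = center + rng.uniform(-12, 12, 2)
                tangent = np.arctan2(pos[0], -pos[1])  # ⟂ radius
                tangent = (tangent + np.pi / 2) % np.pi - np.pi / 2
                recs.append(CellShapeRecord(
                    label=i, centroid=pos, area=80.0,
                    orientation=tangent, orientation_defined=True,
                    major=15.0, minor=8.0,
                    axis_endpoints_3d=np.zeros((4, 3)),
                    major_3d=15.0, minor_3d=8.0))
            series.append((t, recs))
        out = domain_orientation(series, lambda t: center, box=30.0,
                                 window=20.0, time=0.0)
        flow_dir = np.arctan2(center[0], -center[1])
        flow_dir = (flow_dir + np.pi / 2) % np.pi - np.pi / 2
        diff = np.degrees(out.mean_orientation - flow_dir)
        diff = (diff + 90) % 180 - 90
        assert abs(diff) < 5.0

    def test_empty_box_window_masked(self):
        out = domain_orientation(self._records([0.4]),
                                 lambda t: np.array([500.0, 500.0]),
                                 box=10.0)
        assert not out.defined and out.n_cells == 0


class TestInternalisationDepth:
    def _sphere_surface(self, R=100.0):
        center = np.array([0.0, 0.0, -R])
        th = np.linspace(0, np.pi / 3, 150)
        ph = np.linspace(0, 2 * np.pi, 300)
        T, P = np.meshgrid(th, ph)
        return center, center + R * np.stack(
            [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)],
            axis=-1).reshape(-1, 3)

    def test_point_on_surface_zero_depth(self):
        center, surf = self._sphere_surface()
        track = Track(0, np.array([0.0]), np.array([surf[10, 0]]),
                      np.array([surf[10, 1]]), np.array([surf[10, 2]]))
        depths, valid = internalisation_depth(track, surf)
        assert depths[0] == pytest.approx(0.0, abs=1e-9)

    def test_radially_interior_point_depth_matches_analytic(self):
        center, surf = self._sphere_surface(R=100.0)
        d_true = 12.0
        direction = np.array([np.sin(0.4), 0.0, np.cos(0.4)])
        p = center + (100.0 - d_true) * direction
        track = Track(0, np.array([0.0]), np.array([p[0]]),
                      np.array([p[1]]), np.array([p[2]]))
        depths, valid = internalisation_depth(track, surf)
        assert valid[0]
        assert depths[0] == pytest.approx(d_true, abs=0.5)

    def test_descending_track_monotone_depth(self):
        center, surf = self._sphere_surface()
        d = np.array([0.0, 2.0, 5.0, 9.0])
        direction = np.array([0.0, 0.0, 1.0])
        pts = center + (100.0 - d)[:, None] * direction
        track = Track(0, np.arange(4.0), pts[:, 0], pts[:, 1], pts[:, 2])
        depths, valid = internalisation_depth(track, surf)
        assert np.all(np.diff(depths[valid]) >= -1e-9)


class TestValidation:
    def _cells(self, seed=0):
        rng = np.random.default_rng(seed)
        truth = np.zeros((240, 240), dtype=np.int32)
        lab = 1
        for cy in range(30, 240, 60):
            for cx in range(30, 240, 60):
                rr, cc = draw_ellipse(cy, cx, rng.uniform(12, 20),
                                      rng.uniform(8, 12),
                                      shape=truth.shape,
                                      rotation=rng.uniform(-1.2, 1.2))
                truth[rr, cc] = lab
                lab += 1
        return truth

    def test_identity_is_fixed_point(self):
        truth = self._cells()
        rep = validate_segmentation(truth, truth)
        assert rep.success_rate == 1.0
        assert rep.metric_correlations["area"] == pytest.approx(1.0)
        assert rep.metric_correlations["length"] == pytest.approx(1.0)
        assert rep.mean_relative_differences["area"] == 0.0
        assert rep.mean_angle_difference == 0.0

    def test_one_pixel_dilation_keeps_success(self):
        """Dilating a disc of radius r by 1 px gives IoU = (r/(r+1))²,
        still above 0.6 for 30 px cells."""
        from scipy import ndimage
        truth = np.zeros((100, 100), dtype=np.int32)
        rr, cc = draw_ellipse(50, 50, 15, 15, shape=truth.shape)
        truth[rr, cc] = 1
        dilated = ndimage.binary_dilation(truth > 0).astype(np.int32)
        rep = validate_segmentation(dilated, truth)
        assert rep.success_rate == 1.0
        # area ratio follows the disc-dilation closed form
        assert rep.mean_relative_differences["area"] == pytest.approx(
            (16 / 15) ** 2 - 1, abs=0.03)

    def test_large_shift_fails_all_cells(self):
        truth = self._cells()
        shifted = np.roll(truth, (30, 30), axis=(0, 1))
        rep = validate_segmentation(shifted, truth)
        assert rep.success_rate == 0.0

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            validate_segmentation(np.zeros((10, 10), dtype=int),
                                  np.zeros((10, 10), dtype=int))
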