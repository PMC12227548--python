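"""Flow quantification: PIV surrogate, binning, symmetrisation, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anpflow.fields import GridSpec, VelocityField
from anpflow.flow import (axis_profiles, bin_and_average, piv_block_match,
                          symmetrise)
from anpflow.synthetic import make_image_pair


def _uniform_disp(dx, dy, shape=(160, 160)):
    grid = GridSpec(np.arange(float(shape[1])), np.arange(float(shape[0])))
    return VelocityField(grid, np.full(shape, float(dx)),
                         np.full(shape, float(dy)))


def _interior(piv):
    inner = piv.mask.copy()
    inner[:2] = inner[-2:] = False
    inner[:, :2] = inner[:, -2:] = False
    return inner


class TestPiv:
    def test_identical_frames_give_zero_field(self):
        img, _ = make_image_pair(_uniform_disp(0, 0), texture_seed=0)
        piv = piv_block_match(img, img, window_px=32)
        assert np.all(piv.u == 0) and np.all(piv.v == 0)

    def test_integer_shift_recovered_exactly(self):
        a, b = make_image_pair(_uniform_disp(3, 0), texture_seed=0)
        piv = piv_block_match(a, b, window_px=32, step_px=16, dt=2.0)
        inner = _interior(piv)
        np.testing.assert_array_equal(piv.u[inner], 1.5)   # 3 px / 2 min
        np.testing.assert_array_equal(piv.v[inner], 0.0)

    @pytest.mark.parametrize("shift", [0.5, 2.5])
    def test_subpixel_shift_within_fifth_of_pixel(self, shift):
        a, b = make_image_pair(_uniform_disp(shift, 0), texture_seed=0)
        piv = piv_block_match(a, b, window_px=32, step_px=16)
        inner = _interior(piv)
        assert np.abs(piv.u[inner] - shift).max() < 0.2
        assert np.sqrt(np.mean(piv.v[inner] ** 2)) < 0.15

    def test_translation_bias_small_up_to_quarter_window(self):
        biases = []
        for shift in (1.5, 4.5, 7.5):
            a, b = make_image_pair(_uniform_disp(shift, 0),
                                   texture_seed=3)
            piv = piv_block_match(a, b, window_px=32, step_px=16)
            inner = _interior(piv)
            biases.append(abs(np.mean(piv.u[inner]) - shift))
        assert max(biases) < 0.05

    def test_flat_window_masked(self):
        a = np.zeros((64, 64))
        a[40:, 40:] = np.random.default_rng(0).random((24, 24))
        piv = piv_block_match(a, a, window_px=32, step_px=16)
        assert not piv.mask[0, 0]


class TestBinAndAverage:
    def test_constant_field_unchanged(self):
        g = GridSpec(np.linspace(-45, 45, 31), np.linspace(-45, 45, 31))
        fld = VelocityField(g, np.full(g.shape, 2.0),
                            np.full(g.shape, -1.0))
        out = bin_and_average([fld], box=30.0)
        assert np.all(out.u[out.mask] == 2.0)
        assert np.all(out.v[out.mask] == -1.0)

    def test_opposite_samples_cancel(self):
        from anpflow.fields import Track, TrackSet
        t1 = Track(0, np.array([0.0, 1.0]), np.array([5.0, 6.0]),
                   np.array([5.0, 5.0]))
        t2 = Track(1, np.array([0.0, 1.0]), np.array([8.0, 7.0]),
                   np.array([6.0, 6.0]))
        out = bin_and_average(TrackSet([t1, t2]), box=30.0)
        assert out.u[out.mask] == pytest.approx(0.0, abs=1e-12)

    def test_commutes_with_constant_offset(self):
        rng = np.random.default_rng(0)
        g = GridSpec(np.linspace(-45, 45, 31), np.linspace(-45, 45, 31))
        fld = VelocityField(g, rng.random(g.shape), rng.random(g.shape))
        shifted = VelocityField(g, fld.u + 3.0, fld.v - 2.0)
        b1 = bin_and_average([fld], box=30.0)
        b2 = bin_and_average([shifted], box=30.0)
        np.testing.assert_allclose(b2.u[b2.mask], b1.u[b1.mask] + 3.0,
                                   atol=1e-12)

    def test_binned_advected_tracks_match_model(self):
        """Tracks advected through a singularity flow, binned, land close
        to the model field at the box centres."""
        from anpflow.brinkman import evaluate_model, velocity_at
        from anpflow.singularities import (ForceSingularity,
                                           SingularityConfig)
        from anpflow.synthetic import advect_particles

        cfg = SingularityConfig(
            forces=(ForceSingularity(0.0, np.pi, 30.0, 30.0),),
            gamma2=0.002)
        g = GridSpec(np.linspace(-120, 120, 49),
                     np.linspace(-120, 120, 49))
        fld = evaluate_model(cfg, g)
        rng = np.random.default_rng(4)
        starts = rng.uniform(-85, 85, (600, 2))
        fields = [fld] * 3
        tracks = advect_particles(fields, starts, dt=1.0)
        binned = bin_and_average(tracks, box=30.0)
        X, Y = binned.grid.meshgrid()
        pts = np.column_stack([X[binned.mask], Y[binned.mask]])
        ref = velocity_at(cfg, pts)
        obs = np.column_stack([binned.u[binned.mask],
                               binned.v[binned.mask]])
        rms_err = np.sqrt(np.mean(np.sum((obs - ref) ** 2, axis=1)))
        rms_ref = np.sqrt(np.mean(np.sum(ref ** 2, axis=1)))
        assert rms_err / rms_ref < 0.10

    def test_zero_box_raises(self):
        with pytest.raises(ValueError):
            bin_and_average([], box=0.0)


class TestSymmetrise:
    def _random_field(self, seed):
        rng = np.random.default_rng(seed)
        g = GridSpec(np.linspace(-60, 60, 25), np.linspace(0, 120, 25))
        return VelocityField(g, rng.standard_normal(g.shape),
                             rng.standard_normal(g.shape))

    def test_mirror_consistent_field_unchanged(self):
        g = GridSpec(np.linspace(-60, 60, 25), np.linspace(0, 120, 25))
        X, Y = g.meshgrid()
        fld = VelocityField(g, X * 0.01, np.cos(X / 20.0))
        out = symmetrise(fld)
        np.testing.assert_allclose(out.u, fld.u, atol=1e-12)
        np.testing.assert_allclose(out.v, fld.v, atol=1e-12)

    @given(seed=st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_linear_contraction(self, seed):
        fld = self._random_field(seed)
        s1 = symmetrise(fld)
        s2 = symmetrise(s1)
        np.testing.assert_allclose(s2.u, s1.u, atol=1e-12)
        np.testing.assert_allclose(s2.v, s1.v, atol=1e-12)
        norm_in = np.sqrt(np.sum(fld.u ** 2 + fld.v ** 2))
        norm_out = np.sqrt(np.sum(s1.u ** 2 + s1.v ** 2))
        assert norm_out <= norm_in + 1e-12

    def test_output_parity_exact(self):
        fld = self._random_field(3)
        out = symmetrise(fld)
        np.testing.assert_allclose(out.u, -out.u[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(out.v, out.v[:, ::-1], atol=1e-12)

    def test_asymmetric_grid_resampled_with_warning(self):
        g = GridSpec(np.linspace(-50, 70, 25), np.linspace(0, 100, 25))
        fld = VelocityField(g, np.ones(g.shape), np.ones(g.shape))
        with pytest.warns(UserWarning, match="not symmetric"):
            out = symmetrise(fld)
        np.testing.assert_allclose(out.x, -out.x[::-1], atol=1e-9)

    def test_reduces_distance_to_clean_field(self):
        from anpflow import regimes
        from anpflow.brinkman import evaluate_model
        from anpflow.synthetic import make_flow_field

        cfg = regimes.panel_config("antiparallel_anterior_dominant")
        g = regimes.default_grid(49)
        clean = evaluate_model(cfg, g)
        noisy, _ = make_flow_field(cfg, g, noise_sigma=0.2, seed=8)
        sym = symmetrise(noisy)

        def l2(a):
            return np.sqrt(np.sum((a.u - clean.u) ** 2 +
                                  (a.v - clean.v) ** 2))

        assert l2(sym) < l2(noisy)


class TestAxisProfiles:
    def test_uniform_posterior_flow_sign_convention(self):
        g = GridSpec(np.linspace(-50, 50, 21), np.linspace(0, 100, 21))
        fld = VelocityField(g, np.zeros(g.shape), np.full(g.shape, 2.0))
        ap, ml = axis_profiles(fld, transect_y=50.0)
        assert np.all(ap[:, 1] == 2.0)
        ap_plot, _ = axis_profiles(fld, transect_y=50.0,
                                   anterior_positive=True)
        assert np.all(ap_plot[:, 1] == -2.0)

    def test_axis_sink_profile_changes_sign_at_sink(self):
        from anpflow.brinkman import evaluate_model
        from anpflow.singularities import (SingularityConfig,
                                           SinkSingularity)
        g = GridSpec(np.linspace(-50, 50, 21), np.linspace(0, 100, 41))
        cfg = SingularityConfig(sinks=(SinkSingularity(50.0, 100.0, 8.0),),
                                gamma2=0.01)
        fld = evaluate_model(cfg, g)
        ap, _ = axis_profiles(fld, transect_y=50.0)
        v = ap[:, 1]
        y = ap[:, 0]
        assert np.all(v[y < 45] > 0)      # flow toward the sink
        assert np.all(v[y > 55] < 0)

    def test_zero_field_zero_profiles(self):
        g = GridSpec(np.linspace(-50, 50, 21), np.linspace(0, 100, 21))
        fld = VelocityField(g, np.zeros(g.shape), np.zeros(g.shape))
        ap, ml = axis_profiles(fld, transect_y=20.0)
        assert np.all(ap[:, 1] == 0) and np.all(ml[:, 1] == 0)

    def test_transect_outside_grid_raises(self):
        g = GridSpec(np.linspace(-50, 50, 21), np.linspace(0, 100, 21))
        fld = VelocityField(g, np.zeros(g.shape), np.zeros(g.shape))
        with pytest.raises(ValueError):
            axis_profiles(fld, transect_y=500.0)
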