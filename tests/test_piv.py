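"""Multipass FFT cross-correlation PIV and its post-processing chain."""

import warnings

import numpy as np
import pytest

import ccsflow as cf
from ccsflow.piv import FlowField, compute_flow_pair, postprocess_flow, time_average

PASSES_SMALL = (128, 64, 32)


def uniform_field(shape=(8, 8), vx=1.0, vy=-2.0):
    gy, gx = np.mgrid[0:shape[0], 0:shape[1]]
    return FlowField(
        x=gx * 16.0, y=gy * 16.0,
        vx=np.full(shape, vx), vy=np.full(shape, vy),
        valid=np.ones(shape, dtype=bool),
    )


class TestComputeFlowPair:
    def test_identical_frames_give_zero_field(self, smooth_texture):
        a, _ = smooth_texture
        f = compute_flow_pair(a, a, passes=PASSES_SMALL)
        assert f.valid.all()
        np.testing.assert_allclose(f.vx, 0.0, atol=1e-10)
        np.testing.assert_allclose(f.vy, 0.0, atol=1e-10)

    def test_known_integer_shift_recovered(self, smooth_texture):
        a, b = smooth_texture
        f = compute_flow_pair(a, b, passes=PASSES_SMALL)
        assert f.valid.all()
        np.testing.assert_allclose(f.vx, 8.0, atol=0.1)
        np.testing.assert_allclose(f.vy, 0.0, atol=0.1)

    def test_swapping_frame_order_negates_vectors(self, smooth_texture):
        a, b = smooth_texture
        fwd = compute_flow_pair(a, b, passes=PASSES_SMALL)
        rev = compute_flow_pair(b, a, passes=PASSES_SMALL)
        np.testing.assert_allclose(rev.vx, -fwd.vx, atol=0.2)
        np.testing.assert_allclose(rev.vy, -fwd.vy, atol=0.2)

    def test_translation_equivariance(self, smooth_texture):
        """Translating both frames identically changes nothing: PIV measures
        relative displacement only."""
        a, b = smooth_texture
        base = compute_flow_pair(a, b, passes=PASSES_SMALL)
        moved = compute_flow_pair(np.roll(a, 5, axis=0), np.roll(b, 5, axis=0),
                                  passes=PASSES_SMALL)
        inner = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(moved.vx[inner], base.vx[inner], atol=0.1)
        np.testing.assert_allclose(moved.vy[inner], base.vy[inner], atol=0.1)

    def test_fully_masked_image_yields_no_valid_vectors(self, smooth_texture):
        a, b = smooth_texture
        f = compute_flow_pair(a, b, passes=PASSES_SMALL,
                              mask=np.zeros(a.shape, dtype=bool))
        assert f.valid.sum() == 0

    def test_oversized_first_window_shrunk_with_warning(self, smooth_texture):
        a, b = smooth_texture
        with pytest.warns(UserWarning, match="shrunk"):
            f = compute_flow_pair(a, b, passes=(1024, 64))
        np.testing.assert_allclose(f.vx[f.valid], 8.0, atol=0.1)

    def test_window_schedule_validation(self, smooth_texture):
        a, b = smooth_texture
        with pytest.raises(ValueError, match="decreasing"):
            compute_flow_pair(a, b, passes=(64, 64))
        with pytest.raises(ValueError, match="final window"):
            compute_flow_pair(a, b, passes=(64, 8))

    def test_deformation_variant_matches_offset_seeding(self, smooth_texture):
        a, b = smooth_texture
        off = compute_flow_pair(a, b, passes=PASSES_SMALL, deform=False)
        def_ = compute_flow_pair(a, b, passes=PASSES_SMALL, deform=True)
        both = off.valid & def_.valid
        # image resampling near frame edges costs a little accuracy
        np.testing.assert_allclose(def_.vx[both], off.vx[both], atol=0.5)


def test_actin_preset_maps_physical_box_sizes_to_windows():
    """0.5 um source / 1.0 um search boxes at 0.1 um/px calibration."""
    assert cf.actin_preset(pixel_size=0.1)["passes"] == (32, 16)
    assert cf.actin_preset(pixel_size=0.021)["passes"] == (48, 24)


class TestPostprocess:
    def test_uniform_field_is_fixed_point(self):
        f = uniform_field()
        out = postprocess_flow(f)
        np.testing.assert_allclose(out.vx, f.vx)
        np.testing.assert_allclose(out.vy, f.vy)
        assert out.valid.all()

    def test_single_outlier_replaced_by_neighborhood_value(self):
        f = uniform_field(shape=(9, 9), vx=1.0, vy=0.0)
        rng = np.random.default_rng(0)
        f.vx += rng.normal(0, 0.05, f.vx.shape)
        f.vx[4, 4] = 50.0  # far beyond 4 SD and 4 px/frame of the median
        out = postprocess_flow(f)
        assert abs(out.vx[4, 4] - 1.0) < 0.5
        # distant vectors unchanged up to the 3x3 smoothing
        corner = out.vx[:2, :2]
        np.testing.assert_allclose(corner, 1.0, atol=0.2)

    def test_clean_field_passes_validation_untouched(self):
        f = uniform_field(shape=(6, 6))
        f.vx = f.vx + np.linspace(0, 0.1, 36).reshape(6, 6)
        out = postprocess_flow(f, smooth=False)
        np.testing.assert_allclose(out.vx, f.vx)
        assert out.valid.all()

    def test_too_few_valid_vectors_refuses_interpolation(self):
        f = uniform_field(shape=(5, 5))
        f.valid[:] = False
        f.valid[0, 0] = f.valid[0, 1] = True
        with pytest.warns(UserWarning, match="refused"):
            out = postprocess_flow(f)
        assert out.valid.sum() == 2

    def test_interpolation_fills_hole_with_neighbor_consistent_value(self):
        f = uniform_field(shape=(7, 7), vx=2.0, vy=3.0)
        f.valid[3, 3] = False
        f.vx[3, 3] = np.nan
        f.vy[3, 3] = np.nan
        out = postprocess_flow(f, smooth=False)
        assert out.valid[3, 3]
        assert out.vx[3, 3] == pytest.approx(2.0, abs=1e-6)
        assert out.vy[3, 3] == pytest.approx(3.0, abs=1e-6)


class TestTimeAverage:
    def test_copies_average_to_themselves(self):
        f = uniform_field()
        avg = time_average([f.copy() for _ in range(5)])
        np.testing.assert_allclose(avg.vx, f.vx)
        np.testing.assert_allclose(avg.vy, f.vy)

    def test_field_plus_negation_average_to_zero(self):
        f = uniform_field()
        g = f.copy()
        g.vx = -g.vx
        g.vy = -g.vy
        avg = time_average([f, g])
        np.testing.assert_allclose(avg.vx, 0.0, atol=1e-12)
        np.testing.assert_allclose(avg.vy, 0.0, atol=1e-12)

    def test_matches_per_point_nanmean_oracle(self):
        rng = np.random.default_rng(7)
        fields = []
        for _ in range(6):
            f = uniform_field(shape=(5, 5))
            f.vx = rng.normal(size=(5, 5))
            f.vy = rng.normal(size=(5, 5))
            f.valid = rng.uniform(size=(5, 5)) > 0.2
            f.vx[~f.valid] = np.nan
            f.vy[~f.valid] = np.nan
            fields.append(f)
        avg = time_average(fields, min_valid_fraction=0.5)
        stack = np.stack([np.where(f.valid, f.vx, np.nan) for f in fields])
        counts = np.sum([f.valid for f in fields], axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            expected = np.nanmean(stack, axis=0)
        ok = counts >= 3
        np.testing.assert_allclose(avg.vx[ok], expected[ok])
        np.testing.assert_array_equal(avg.valid, ok)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            time_average([])


class TestAgainstGroundTruth:
    def test_piv_radial_speed_does_not_exceed_true_particle_speeds(
        self, centripetal_data, centripetal_result
    ):
        """Windowed correlation averages over particles and background, so
        the peak radial speed it reports stays at or below the fastest true
        advection speed."""
        _, truth = centripetal_data
        true_max = truth.mobile_speeds().max() * 0.021 / 5.0
        prof = centripetal_result.profile
        assert np.nanmax(np.abs(prof.vr_um_s)) <= true_max * 1.05

    def test_radial_profile_stable_under_final_window_halving(self):
        """In the well-sampled regime (>= ~5 puncta per final window) the
        profile changes by < 5% when the final interrogation window is
        halved from 64 to 32 px."""
        model = cf.FlowModel("centripetal", (256.0, 256.0),
                             speed=cf.linear_ramp(0.5, 230.0))
        movie, _ = cf.generate_ccs_movie(
            model, n_particles=600, static_fraction=0.3, n_frames=40,
            shape=(512, 512), seed=7, cell_radius=230.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res64 = cf.run_flow_pipeline(cf.PipelineConfig(seed=7), movie=movie)
            res32 = cf.run_flow_pipeline(
                cf.PipelineConfig(seed=7, passes=(512, 128, 32)), movie=movie
            )
        v64 = res64.profile.vr_um_s
        v32 = res32.profile.vr_um_s
        ok = (res64.profile.count > 0) & (res32.profile.count > 0)
        rel = np.linalg.norm(v64[ok] - v32[ok]) / np.linalg.norm(v64[ok])
        assert rel < 0.05
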