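"""Spot detection, trajectory linking, velocities and kymographs."""

import numpy as np
import pytest

import ccsflow as cf
from ccsflow.synthetic import _render_frame
from ccsflow.tracking import (Trajectory, detect_and_link, kymograph,
                              mean_instantaneous_velocity,
                              radial_displacement_series)


def render_movie(tracks, shape=(64, 64), amplitude=200.0, background=0.0,
                 pixel_size=0.021, frame_interval=5.0):
    """Noiseless movie from explicit (n_particles, n_frames, 2) tracks."""
    n_frames = tracks.shape[1]
    frames = np.stack([
        _render_frame(shape, tracks[:, t], amplitude, 1.5, background)
        for t in range(n_frames)
    ])
    return cf.Movie(frames=frames, pixel_size=pixel_size,
                    frame_interval=frame_interval)


def make_traj(x, y, frames=None, pixel_size=0.021, frame_interval=5.0):
    x = np.asarray(x, dtype=float)
    if frames is None:
        frames = np.arange(len(x))
    return Trajectory(particle_id=0, frames=frames, x_px=x,
                      y_px=np.asarray(y, dtype=float),
                      pixel_size=pixel_size, frame_interval=frame_interval)


class TestDetectAndLink:
    def test_single_punctum_tracked_subpixel(self):
        tracks = np.zeros((1, 8, 2))
        tracks[0, :, 0] = 20.3 + 0.7 * np.arange(8)
        tracks[0, :, 1] = 30.6
        movie = render_movie(tracks)
        trajs = detect_and_link(movie)
        assert len(trajs) == 1
        tr = trajs[0]
        assert len(tr) == 8
        np.testing.assert_allclose(tr.x_px, tracks[0, :, 0], atol=0.2)
        np.testing.assert_allclose(tr.y_px, tracks[0, :, 1], atol=0.2)

    def test_two_separated_puncta_give_two_full_tracks(self):
        tracks = np.zeros((2, 10, 2))
        tracks[0, :, 0] = 10 + np.arange(10)
        tracks[0, :, 1] = 15
        tracks[1, :, 0] = 45 - np.arange(10)
        tracks[1, :, 1] = 48
        movie = render_movie(tracks)
        trajs = detect_and_link(movie)
        assert len(trajs) == 2
        assert all(len(tr) == 10 for tr in trajs)

    def test_low_density_movie_links_match_ground_truth(self):
        """>= 90% of frame-to-frame links agree with the generator's truth,
        and recovered speeds are within 10% of the imposed speed."""
        model = cf.FlowModel("centripetal", (256.0, 256.0), speed=0.5)
        movie, truth = cf.generate_ccs_movie(
            model, n_particles=50, static_fraction=0.0, n_frames=20,
            shape=(512, 512), seed=8, cell_radius=200.0,
        )
        trajs = detect_and_link(movie, max_disp=3.0)
        n_links = 0
        n_correct = 0
        final = truth.tracks  # (50, 20, 2)
        for tr in trajs:
            for i in range(len(tr) - 1):
                f0, f1 = tr.frames[i], tr.frames[i + 1]
                d0 = np.hypot(final[:, f0, 0] - tr.x_px[i],
                              final[:, f0, 1] - tr.y_px[i])
                d1 = np.hypot(final[:, f1, 0] - tr.x_px[i + 1],
                              final[:, f1, 1] - tr.y_px[i + 1])
                n_links += 1
                if d0.argmin() == d1.argmin() and d0.min() < 2 and d1.min() < 2:
                    n_correct += 1
        assert n_links > 0
        assert n_correct / n_links >= 0.9
        speeds = [
            mean_instantaneous_velocity(tr) for tr in trajs if len(tr) >= 10
        ]
        imposed = 0.5 * movie.pixel_size / movie.frame_interval
        assert np.mean(speeds) == pytest.approx(imposed, rel=0.1)

    def test_empty_movie_rejected(self):
        movie = cf.Movie(frames=np.zeros((3, 32, 32)), pixel_size=0.021,
                         frame_interval=5.0)
        with pytest.raises(ValueError, match="no detections"):
            detect_and_link(movie)


class TestVelocity:
    def test_stationary_trajectory_has_zero_velocity(self):
        tr = make_traj([5, 5, 5, 5], [7, 7, 7, 7])
        assert mean_instantaneous_velocity(tr) == 0.0

    def test_straight_motion_velocity_by_definition(self):
        # 0.1 um per 5 s interval -> 0.02 um/s
        step_px = 0.1 / 0.021
        tr = make_traj(np.arange(6) * step_px, np.zeros(6))
        assert mean_instantaneous_velocity(tr) == pytest.approx(0.02)

    def test_random_walk_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.normal(size=50))
        y = np.cumsum(rng.normal(size=50))
        tr = make_traj(x, y)
        # independently coded mean step length / frame interval
        expected = np.mean(
            [np.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) * 0.021 / 5.0
             for i in range(49)]
        )
        assert mean_instantaneous_velocity(tr) == pytest.approx(expected)

    def test_invariant_to_global_translation(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(size=20))
        y = np.cumsum(rng.normal(size=20))
        v0 = mean_instantaneous_velocity(make_traj(x, y))
        v1 = mean_instantaneous_velocity(make_traj(x + 123.4, y - 55.5))
        assert v0 == pytest.approx(v1)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            mean_instantaneous_velocity(make_traj([1.0], [1.0]))


class TestRadialDisplacement:
    def test_inward_motion_is_negative_and_decreasing(self):
        tr = make_traj(np.linspace(100, 60, 9), np.zeros(9))
        series = radial_displacement_series(tr, (0.0, 0.0))
        assert series[0] == 0.0
        assert np.all(np.diff(series) < 0)
        assert np.all(series[1:] < 0)

    def test_stationary_trajectory_is_all_zero(self):
        tr = make_traj([30] * 5, [40] * 5)
        np.testing.assert_array_equal(
            radial_displacement_series(tr, (0.0, 0.0)), 0.0
        )

    def test_outward_motion_is_positive(self):
        tr = make_traj(np.linspace(60, 100, 9), np.zeros(9))
        series = radial_displacement_series(tr, (0.0, 0.0))
        assert np.all(series[1:] > 0)


class TestKymograph:
    def test_static_pattern_gives_identical_rows(self):
        rng = np.random.default_rng(6)
        pattern = rng.uniform(size=(48, 48))
        movie = cf.Movie(frames=np.repeat(pattern[None], 5, axis=0),
                         pixel_size=0.021, frame_interval=5.0)
        kymo = kymograph(movie, ((5.0, 24.0), (42.0, 24.0)))
        for row in kymo[1:]:
            np.testing.assert_allclose(row, kymo[0])

    def test_moving_punctum_traces_streak_of_imposed_slope(self):
        n_frames = 10
        tracks = np.zeros((1, n_frames, 2))
        tracks[0, :, 0] = 10 + 2.0 * np.arange(n_frames)  # 2 px/frame
        tracks[0, :, 1] = 24
        movie = render_movie(tracks, shape=(48, 64))
        kymo = kymograph(movie, ((0.0, 24.0), (63.0, 24.0)))
        peaks = kymo.argmax(axis=1)
        slope = np.polyfit(np.arange(n_frames), peaks, 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_stalled_punctum_gives_vertical_line(self):
        tracks = np.zeros((1, 8, 2))
        tracks[0, :, 0] = 30
        tracks[0, :, 1] = 24
        movie = render_movie(tracks, shape=(48, 64))
        kymo = kymograph(movie, ((0.0, 24.0), (63.0, 24.0)))
        assert np.ptp(kymo.argmax(axis=1)) == 0

    def test_zero_length_line_rejected(self):
        movie = cf.Movie(frames=np.ones((2, 16, 16)), pixel_size=1.0,
                         frame_interval=1.0)
        with pytest.raises(ValueError):
            kymograph(movie, ((4.0, 4.0), (4.0, 4.0)))


def test_tracking_speed_not_below_piv_radial_speed(centripetal_data,
                                                   centripetal_result):
    """Single-particle tracking measures each punctum directly, while PIV
    averages over window content and projects onto the radial direction, so
    near-membrane tracked speeds bound the PIV peak radial speed from
    above."""
    movie, truth = centripetal_data
    trajs = detect_and_link(movie, max_disp=3.0)
    step_speeds = []
    for tr in trajs:
        if len(tr) < 10:
            continue
        d0 = np.hypot(truth.tracks[:, tr.frames[0], 0] - tr.x_px[0],
                      truth.tracks[:, tr.frames[0], 1] - tr.y_px[0])
        p = d0.argmin()
        if d0[p] >= 2 or truth.is_static[p]:
            continue
        r = np.hypot(tr.x_px - 256.0, tr.y_px - 256.0)
        steps = np.hypot(np.diff(tr.x_px), np.diff(tr.y_px))
        sel = r[:-1] > 180.0  # near the membrane, where Vr(r) peaks
        step_speeds.extend(steps[sel] * movie.pixel_size / movie.frame_interval)
    prof = centripetal_result.profile
    assert np.mean(step_speeds) >= np.nanmax(np.abs(prof.vr_um_s))
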