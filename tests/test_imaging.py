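import numpy as np
import pytest

import polku as pk
from polku.imaging import (ChannelMap, DetectionParams, FieldLayout,
                           assign_positions, colocalize, correct_drift,
                           detect_spots, extract_intensity,
                           extract_trajectories, register_channels,
                           render_movie)
from polku.trajectories import TrajectorySet


def constant_set(counts, n_frames=5, n_molecules=1, dt=0.2):
    time = np.arange(n_frames) * dt
    flat = [np.full(n_frames, float(counts))] * n_molecules
    zero = [np.zeros(n_frames)] * n_molecules
    return TrajectorySet.from_molecule_arrays(
        list(range(n_molecules)), time, flat, zero, zero, dt)


class TestRenderMovie:
    def test_rendered_photons_conserved(self):
        layout = FieldLayout(camera_background=0.0)
        stack = render_movie(constant_set(1000), layout,
                             positions=np.array([[20.0, 30.0]]),
                             noiseless=True)
        total = stack.channels["F_DD"][0].sum()
        assert total == pytest.approx(1000.0, rel=0.01)

    def test_empty_set_renders_background_only(self):
        layout = FieldLayout(camera_background=3.0)
        empty = TrajectorySet.from_molecule_arrays([], np.arange(4) * 0.2,
                                                   [], [], [], 0.2)
        stack = render_movie(empty, layout, positions=np.empty((0, 2)),
                             seed=0, n_frames=4)
        assert stack.channels["F_DD"].shape[1:] == layout.shape
        assert stack.channels["F_DD"].mean() == pytest.approx(3.0, abs=0.2)

    def test_positions_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_movie(constant_set(100), FieldLayout(),
                         positions=np.array([[500.0, 10.0]]))

    def test_tiff_round_trip(self, tmp_path):
        layout = FieldLayout()
        stack = render_movie(constant_set(800, n_molecules=4), layout, seed=1)
        stack.save(tmp_path, prefix="mv")
        again = pk.imaging.ImageStack.load(tmp_path, prefix="mv")
        assert again.frame_interval == stack.frame_interval
        assert np.allclose(again.channels["F_DD"],
                           np.round(stack.channels["F_DD"]))
        assert np.allclose(again.metadata["positions"],
                           stack.metadata["positions"])


class TestDetectSpots:
    def test_subpixel_position_of_rendered_spot(self):
        layout = FieldLayout(camera_background=0.0)
        stack = render_movie(constant_set(1000), layout,
                             positions=np.array([[20.3, 30.6]]),
                             noiseless=True)
        (spot,) = detect_spots(stack.channels["F_DD"][0])
        assert abs(spot.x - 20.3) < 0.5
        assert abs(spot.y - 30.6) < 0.5
        assert spot.corrected_intensity == pytest.approx(1000, rel=0.05)

    def test_blank_frame_yields_nothing(self):
        rng = np.random.default_rng(0)
        frame = rng.poisson(2.0, (64, 64)).astype(float)
        assert detect_spots(frame) == []

    def test_close_pair_discarded_by_neighbor_rule(self):
        layout = FieldLayout(camera_background=0.0, spacing=10.0)
        traj = constant_set(1000, n_molecules=2)
        stack = render_movie(traj, layout,
                             positions=np.array([[40.0, 40.0], [44.0, 40.0]]),
                             noiseless=True)
        params = DetectionParams(nn_min_distance=5.0)
        spots = detect_spots(stack.channels["F_DD"][0], params)
        assert spots == []  # both members of the too-close pair dropped

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((3, 3)))

    def test_translation_equivariance(self):
        layout = FieldLayout(camera_background=2.0)
        stack = render_movie(constant_set(900, n_molecules=3), layout, seed=2)
        frame = stack.channels["F_DD"][0]
        base = detect_spots(frame)
        shifted = detect_spots(np.roll(frame, (5, 7), axis=(0, 1)))
        assert len(base) == len(shifted) >= 3
        got = sorted((s.x, s.y) for s in shifted)
        want = sorted((s.x + 7, s.y + 5) for s in base)
        assert np.allclose(got, want, atol=0.05)


class TestRegisterChannels:
    def test_identity_for_identical_sets(self):
        pts = np.array([[1.0, 2.0], [30.0, 4.0], [10.0, 50.0], [7.0, 7.0]])
        cmap = register_channels(pts, pts)
        assert np.allclose(cmap.matrix, np.eye(3), atol=1e-12)
        assert cmap.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self):
        pts = np.array([[1.0, 2.0], [30.0, 4.0], [10.0, 50.0]])
        cmap = register_channels(pts, pts + [3.0, -2.0])
        assert np.allclose(cmap.apply(pts), pts + [3.0, -2.0], atol=1e-9)

    def test_small_rotation_plus_shift_recovered(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(5, 120, (12, 2))
        th = np.deg2rad(0.5)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        dst = src @ rot.T + [1.5, -0.7]
        cmap = register_channels(src, dst)
        assert np.allclose(cmap.matrix[:2, :2], rot, atol=1e-6)
        assert cmap.residual_rms < 1e-9

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="3 fiducial"):
            register_channels(np.zeros((2, 2)), np.zeros((2, 2)))
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="collinear"):
            register_channels(line, line)


class TestCorrectDrift:
    @staticmethod
    def _spot_frame(positions, shape=(96, 96)):
        layout = FieldLayout(shape=shape, camera_background=0.0)
        stack = render_movie(constant_set(2000), layout,
                             positions=positions[:1], noiseless=True)
        return stack.channels["F_DD"][0]

    @staticmethod
    def _drifting_stack(n_frames=60, velocity=0.02):
        # several fixed emitters, shifted by Fourier translation per frame
        rng = np.random.default_rng(3)
        layout = FieldLayout(shape=(96, 96), camera_background=1.0)
        pos = assign_positions(6, layout)
        base = render_movie(constant_set(2000, n_molecules=6), layout,
                            positions=pos, noiseless=True).channels["F_DD"][0]
        fx = np.fft.fftfreq(96)[None, :]
        fy = np.fft.fftfreq(96)[:, None]
        frames = []
        for i in range(n_frames):
            dx = velocity * i
            shifted = np.real(np.fft.ifft2(np.fft.fft2(base)
                                           * np.exp(-2j * np.pi * fx * dx)))
            frames.append(shifted)
        return np.array(frames)

    def test_stationary_movie_has_zero_offsets(self):
        stack = np.repeat(self._drifting_stack(1, 0.0), 20, axis=0)
        offsets = correct_drift(stack)
        assert np.allclose(offsets, 0.0, atol=0.05)

    def test_linear_drift_slope_recovered(self):
        stack = self._drifting_stack(100, velocity=0.01)  # 1 px / 100 frames
        offsets = correct_drift(stack)
        slope = np.polyfit(np.arange(100), offsets[:, 0], 1)[0]
        assert slope == pytest.approx(0.01, rel=0.10)
        assert np.allclose(offsets[:, 1], 0.0, atol=0.1)

    def test_reversed_movie_negates_offsets(self):
        stack = self._drifting_stack(80, velocity=0.02)
        fwd = correct_drift(stack)
        rev = correct_drift(stack[::-1])
        # linear drift: offsets relative to the first frame flip sign
        assert np.allclose(rev[:, 0], -fwd[:, 0], atol=0.15)

    def test_featureless_stack_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="featureless"):
            offsets = correct_drift(np.zeros((12, 32, 32)))
        assert np.allclose(offsets, 0.0)


class TestExtractIntensity:
    def test_uniform_background_cancels(self):
        rng = np.random.default_rng(5)
        stack = rng.poisson(10.0, (100, 64, 64)).astype(float)
        series = extract_intensity(stack, 30.0, 30.0)
        assert abs(series.mean()) < 1.0

    def test_rendered_spot_recovered_within_2_percent(self):
        layout = FieldLayout(camera_background=10.0)
        stack = render_movie(constant_set(1000, n_frames=20), layout,
                             positions=np.array([[40.0, 40.0]]),
                             noiseless=True)
        series = extract_intensity(stack.channels["F_DD"], 40.0, 40.0)
        assert series.mean() == pytest.approx(1000.0, rel=0.02)

    def test_edge_position_rejected(self):
        stack = np.zeros((5, 64, 64))
        with pytest.raises(ValueError, match="annulus"):
            extract_intensity(stack, 2.0, 30.0)
        with pytest.raises(ValueError):
            extract_intensity(stack, 30.0, 30.0, r_disc=5.0, r_in=4.0)


class TestColocalize:
    def test_partner_at_mapped_position_colocalizes(self):
        layout = FieldLayout(camera_background=0.0)
        stack = render_movie(constant_set(1000), layout,
                             positions=np.array([[50.0, 50.0]]),
                             noiseless=True)
        (dna,) = detect_spots(stack.channels["F_DD"][0], channel="dna")
        (partner,) = detect_spots(stack.channels["F_DD"][0], channel="cy5")
        (pair,) = colocalize([dna], [partner], distance_threshold=2.0)
        assert pair.colocalized
        assert pair.separation < 0.1

    def test_partner_far_beyond_threshold_does_not(self):
        layout = FieldLayout(camera_background=0.0)
        stack = render_movie(constant_set(1000, n_molecules=2), layout,
                             positions=np.array([[30.0, 30.0], [40.0, 40.0]]),
                             noiseless=True)
        spots = detect_spots(stack.channels["F_DD"][0])
        (pair,) = colocalize(spots[:1], spots[1:], distance_threshold=2.0)
        assert not pair.colocalized
        assert pair.separation > 6.0

    def test_grid_with_partial_occupancy_counts_exactly(self):
        layout = FieldLayout(shape=(128, 128), camera_background=0.0)
        pos = assign_positions(25, layout)
        stack_dna = render_movie(constant_set(1000, n_molecules=25), layout,
                                 positions=pos, noiseless=True)
        occupied = pos[:12]
        stack_p = render_movie(constant_set(1000, n_molecules=12), layout,
                               positions=occupied, noiseless=True)
        dna = detect_spots(stack_dna.channels["F_DD"][0])
        partner = detect_spots(stack_p.channels["F_DD"][0])
        pairs = colocalize(dna, partner, distance_threshold=2.0)
        assert sum(p.colocalized for p in pairs) == 12

    def test_dark_spot_false_colocalization_below_1_percent(self):
        """Background-only partner frames colocalize with <1% of DNA spots."""
        rng = np.random.default_rng(11)
        layout = FieldLayout(shape=(128, 128))
        pos = assign_positions(100, layout)
        dna = [pk.imaging.Spot(0, "dna", x, y, 1000, 2, 998, 1.0, np.inf)
               for x, y in pos]
        false_hits = 0
        for _ in range(10):
            frame = rng.poisson(2.0, (128, 128)).astype(float)
            partner = detect_spots(frame)
            pairs = colocalize(dna, partner, distance_threshold=2.0)
            false_hits += sum(p.colocalized for p in pairs)
        assert false_hits / (10 * len(dna)) < 0.01


def test_render_detect_extract_round_trip(ku_scenario):
    """Rendering then extracting reproduces simulated counts within noise."""
    scen = ku_scenario.replace(n_molecules=12, movie_length=8.0, seed=14)
    trajset, _ = pk.simulate_colocalization(scen)
    layout = FieldLayout(shape=(128, 128))
    stack = render_movie(trajset, layout, noiseless=True)
    again = extract_trajectories(stack)
    for mid in trajset.molecule_ids():
        a, b = trajset.get(mid), again.get(mid)
        bright = a.f_dd > 100
        rel = np.abs(b.f_dd[bright] - a.f_dd[bright]) / a.f_dd[bright]
        assert rel.mean() < 0.02
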