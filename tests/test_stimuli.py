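import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionenergy.stimuli import (
    FrameSequence,
    ParameterError,
    RingStimulusSpec,
    SteppingFeetSpec,
    apply_camera_jitter,
    gen_counterphase_grating,
    gen_drifting_grating,
    gen_ring_stimulus,
    gen_stepping_feet,
    jitter_path,
    stepping_feet_positions,
)


class TestFrameSequence:
    def test_values_are_clipped_and_shape_validated(self):
        seq = FrameSequence(np.array([[[-1.0, 2.0], [0.3, 0.7]]]))
        assert seq.frames.min() >= 0.0 and seq.frames.max() <= 1.0
        with pytest.raises(ParameterError):
            FrameSequence(np.zeros((4, 4)))  # not a (T, H, W) stack


class TestDriftingGrating:
    def test_zero_contrast_is_constant_at_mean(self):
        seq = gen_drifting_grating((16, 16), 8, 0, 1.0, 0.0, 5, mean_luminance=0.4)
        assert np.allclose(seq.frames, 0.4)

    def test_zero_speed_frames_are_bit_identical(self):
        seq = gen_drifting_grating((16, 16), 8, 30.0, 0.0, 1.0, 5)
        assert all(np.array_equal(f, seq.frames[0]) for f in seq.frames)

    def test_spectral_peak_matches_wavelength_and_speed(self):
        """Fourier oracle: the 3-D spectrum's non-DC peak sits at spatial
        frequency 1/16 cyc/px and temporal frequency 2/16 cyc/frame."""
        seq = gen_drifting_grating((64, 64), 16, 0.0, 2.0, 1.0, 32)
        vol = seq.frames - seq.frames.mean()
        F = np.abs(np.fft.fftn(vol))
        ft, fy, fx = np.unravel_index(np.argmax(F), F.shape)
        freq_t = np.fft.fftfreq(32)[ft]
        freq_y = np.fft.fftfreq(64)[fy]
        freq_x = np.fft.fftfreq(64)[fx]
        assert np.isclose(abs(freq_x), 1 / 16)
        assert np.isclose(freq_y, 0.0)
        assert np.isclose(abs(freq_t), 2 / 16)

    @pytest.mark.parametrize("contrast,mean", [(1.2, 0.5), (1.0, 0.8), (0.5, 0.1)])
    def test_out_of_range_contrast_or_mean_rejected(self, contrast, mean):
        with pytest.raises(ParameterError):
            gen_drifting_grating((8, 8), 8, 0, 1.0, contrast, 3, mean_luminance=mean)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        wavelength=st.floats(4, 32),
        orientation=st.floats(-180, 180),
        speed=st.floats(0, 4),
        contrast=st.floats(0, 1),
    )
    def test_output_always_satisfies_sequence_invariants(
        self, wavelength, orientation, speed, contrast
    ):
        seq = gen_drifting_grating((24, 24), wavelength, orientation, speed, contrast, 6)
        assert seq.frames.shape == (6, 24, 24)
        assert seq.frames.min() >= 0.0 and seq.frames.max() <= 1.0


class TestCounterphaseGrating:
    def test_equals_sum_of_opposite_drifting_gratings(self):
        """Product-to-sum identity: a counterphase grating is two opposite
        half-contrast drifting gratings superimposed."""
        wl, tf, c = 8.0, 0.1, 0.8
        cp = gen_counterphase_grating((32, 32), wl, 25.0, tf, c, 12)
        g1 = gen_drifting_grating((32, 32), wl, 25.0, tf * wl, c / 2, 12)
        g2 = gen_drifting_grating((32, 32), wl, 25.0 + 180.0, tf * wl, c / 2, 12)
        combined = (g1.frames - 0.5) + (g2.frames - 0.5) + 0.5
        assert np.max(np.abs(cp.frames - combined)) < 1e-6

    def test_zero_contrast_constant(self):
        seq = gen_counterphase_grating((16, 16), 8, 0, 0.1, 0.0, 4)
        assert np.allclose(seq.frames, 0.5)

    def test_temporal_spectrum_peaks_at_plus_minus_tf(self):
        tf = 0.125
        seq = gen_counterphase_grating((32, 32), 8, 0.0, tf, 1.0, 32)
        trace = seq.frames[:, 16, 16] - 0.5
        F = np.abs(np.fft.fft(trace))
        peak = np.argmax(F)
        assert np.isclose(abs(np.fft.fftfreq(32)[peak]), tf)


class TestSteppingFeet:
    def test_centroids_advance_exactly_speed_per_frame(self):
        spec = SteppingFeetSpec(speed=1.5, background_contrast=0.0)
        n = 20
        seq = gen_stepping_feet(spec, (64, 128), n)
        xs, (yb, yd), (fw, fh) = stepping_feet_positions(spec, (64, 128), n)
        x = np.arange(128, dtype=float)
        rows = slice(int(yb), int(yb + fh))
        centroids = []
        for t in range(n):
            dev = np.abs(seq.frames[t][rows] - 0.5).sum(axis=0)
            centroids.append((dev * x).sum() / dev.sum())
        steps = np.diff(centroids)
        assert np.allclose(steps, spec.speed, atol=1e-9)

    def test_zero_background_contrast_gives_uniform_background(self):
        spec = SteppingFeetSpec(background_contrast=0.0)
        seq = gen_stepping_feet(spec, (64, 128), 4)
        frame = seq.frames[0]
        # everything outside the feet band is mid-gray
        assert np.allclose(frame[:20], 0.5) and np.allclose(frame[-20:], 0.5)
        assert frame.max() > 0.5 and frame.min() < 0.5  # feet are visible

    def test_leading_edge_contrast_is_periodic_in_grating_period(self):
        """Sampling the background luminance just ahead of the foot along
        one traversal: edge contrast repeats with the stripe period."""
        spec = SteppingFeetSpec(speed=1.0, grating_period=16.0)
        n = 40
        seq = gen_stepping_feet(spec, (64, 128), n)
        xs, (yb, _), (fw, fh) = stepping_feet_positions(spec, (64, 128), n)
        row = int(yb + fh / 2)
        lum_b = spec.foot_luminances[0]
        edge = np.array(
            [abs(lum_b - seq.frames[t][row, int(xs[t] + fw + 2)]) for t in range(n)]
        )
        period = int(spec.grating_period / spec.speed)
        assert np.allclose(edge[:-period], edge[period:], atol=1e-9)

    def test_feet_leaving_frame_is_an_error(self):
        with pytest.raises(ParameterError):
            gen_stepping_feet(SteppingFeetSpec(speed=5.0), (64, 64), 40)

    def test_identical_luminances_rejected(self):
        with pytest.raises(ParameterError):
            SteppingFeetSpec(foot_luminances=(0.5, 0.5))


class TestRingStimulus:
    def test_static_rates_give_identical_frames(self):
        spec = RingStimulusSpec(center=(32, 32), base_radius=12, element_sigma=3)
        seq = gen_ring_stimulus(spec, (64, 64), 5)
        assert all(np.array_equal(f, seq.frames[0]) for f in seq.frames)

    def test_nfold_symmetry_rotation_step_maps_frame_to_itself(self):
        n = 12
        spec = RingStimulusSpec(
            center=(32, 32), base_radius=12, rotation_rate=360.0 / n,
            n_elements=n, element_sigma=3,
        )
        seq = gen_ring_stimulus(spec, (64, 64), 4)
        for t in range(3):
            assert np.allclose(seq.frames[t + 1], seq.frames[t], atol=1e-7)

    def test_expanding_gabor_ring_element_radius_tracks_base_plus_t(self):
        """Centroid fit: radial center of mass of the rendered pattern
        follows base_radius + t within half a pixel at 1 px/frame."""
        spec = RingStimulusSpec(
            center=(64, 64), base_radius=24, expansion_rate=1.0,
            element_kind="gabor_elements", n_elements=12, element_sigma=3.0,
        )
        seq = gen_ring_stimulus(spec, (128, 128), 12)
        y, x = np.mgrid[0:128, 0:128].astype(float)
        rho = np.hypot(x - 64, y - 64)
        for t in range(12):
            w = (seq.frames[t] - 0.5) ** 2
            fitted = (w * rho).sum() / w.sum()
            assert abs(fitted - (24 + t)) < 0.5

    def test_ring_exiting_frame_is_an_error(self):
        spec = RingStimulusSpec(center=(32, 32), base_radius=20, expansion_rate=2.0)
        with pytest.raises(ParameterError):
            gen_ring_stimulus(spec, (64, 64), 10)

    def test_negative_radius_is_an_error(self):
        spec = RingStimulusSpec(center=(32, 32), base_radius=8, expansion_rate=-2.0)
        with pytest.raises(ParameterError):
            gen_ring_stimulus(spec, (64, 64), 6)

    def test_gabor_elements_need_at_least_four(self):
        with pytest.raises(ParameterError):
            RingStimulusSpec(center=(0, 0), base_radius=10,
                             element_kind="gabor_elements", n_elements=3)


class TestCameraJitter:
    def test_zero_amplitude_is_identity(self):
        seq = gen_drifting_grating((16, 16), 8, 0, 1.0, 1.0, 4)
        out = apply_camera_jitter(seq, 0.0, seed=3)
        assert np.array_equal(out.frames, seq.frames)

    def test_same_seed_is_deterministic(self):
        seq = gen_drifting_grating((24, 24), 8, 0, 1.0, 1.0, 6)
        a = apply_camera_jitter(seq, 0.7, seed=11)
        b = apply_camera_jitter(seq, 0.7, seed=11)
        assert np.array_equal(a.frames, b.frames)
        c = apply_camera_jitter(seq, 0.7, seed=12)
        assert not np.array_equal(a.frames, c.frames)

    def test_random_walk_increment_statistics(self):
        """Over 1000 frames the walk's increments are zero-mean with RMS
        within 10% of the requested amplitude."""
        rms = 0.8
        path = jitter_path(1000, rms, seed=5)
        inc = np.diff(path, axis=0, prepend=np.zeros((1, 2)))
        assert np.all(np.abs(inc.mean(axis=0)) < 0.1 * rms)
        assert np.all(np.abs(np.sqrt((inc**2).mean(axis=0)) - rms) < 0.1 * rms)

    def test_jitter_preserves_shape_and_range(self):
        seq = gen_drifting_grating((20, 20), 8, 0, 1.0, 1.0, 5)
        out = apply_camera_jitter(seq, 1.5, seed=0)
        assert out.frames.shape == seq.frames.shape
        assert out.frames.min() >= 0 and out.frames.max() <= 1
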