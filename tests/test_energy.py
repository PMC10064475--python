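import numpy as np
import pytest

from conftest import batch_opponent_oracle, energy_series
from motionenergy.energy import (
    EngineNotReady,
    FrameVolume,
    MotionEnergyEngine,
    compute_energy,
    compute_opponent,
    process_stream,
    push_frame,
)
from motionenergy.stimuli import (
    ParameterError,
    gen_counterphase_grating,
    gen_drifting_grating,
)


class TestFrameVolume:
    def test_fifo_retains_exactly_depth_frames(self):
        vol = FrameVolume(4)
        for i in range(9):
            push_frame(vol, np.full((3, 3), i / 10))
        assert len(vol) == 4
        assert np.allclose(vol.frames[:, 0, 0], [0.5, 0.6, 0.7, 0.8])

    def test_last_pushed_frame_is_newest(self):
        vol = FrameVolume(3)
        vol.push(np.zeros((2, 2)))
        f = np.ones((2, 2))
        vol.push(f)
        assert np.array_equal(vol[-1], f)

    def test_warmup_and_shape_mismatch(self):
        vol = FrameVolume(3)
        img = np.zeros((4, 4))
        for _ in range(3):
            vol.push(img)
        assert vol.is_warm
        with pytest.raises(ParameterError):
            vol.push(np.zeros((5, 5)))


class TestComputeEnergy:
    def test_cold_buffer_signals_not_ready(self, bank):
        vol = FrameVolume(bank.n_taps)
        vol.push(np.zeros((8, 8)))
        with pytest.raises(EngineNotReady):
            compute_energy(vol, bank)

    def test_static_volume_has_zero_opponent_energy(self, bank):
        rng = np.random.default_rng(1)
        img = rng.random((24, 24))
        vol = FrameVolume(bank.n_taps)
        for _ in range(bank.n_taps):
            vol.push(img)
        E = compute_energy(vol, bank)
        O = compute_opponent(E)
        assert np.abs(O).max() < 1e-6 * E.max()

    def test_energy_scales_quadratically_with_contrast(self, bank):
        e = {}
        for c in (0.8, 0.4):
            seq = gen_drifting_grating((32, 32), 8, 0.0, 1.0, c, bank.n_taps)
            vol = FrameVolume(bank.n_taps)
            for f in seq:
                vol.push(f)
            e[c] = compute_energy(vol, bank)
        assert np.max(np.abs(e[0.8] - 4 * e[0.4])) < 1e-5 * e[0.8].max()

    def test_matched_grating_argmax_is_motion_direction_channel(self, bank):
        """Cross-checked against the brute-force 3-D convolution oracle."""
        seq = gen_drifting_grating((24, 24), 8, 0.0, 1.0, 1.0, 32)
        Ob = batch_opponent_oracle(seq.frames, bank)
        vol = FrameVolume(bank.n_taps)
        for f in seq:
            vol.push(f)
        E = compute_energy(vol, bank)
        assert int(np.argmax(E.mean(axis=(0, 1)))) == 0
        # oracle agrees that rightward opponent evidence dominates
        assert Ob[-1][..., 0].mean() > 0
        assert Ob[-1][..., 0].mean() == pytest.approx(
            np.abs(Ob[-1]).mean(axis=(0, 1)).max(), rel=1e-9
        )


class TestOpponent:
    def test_antisymmetry_is_exact(self, bank):
        rng = np.random.default_rng(2)
        E = rng.random((5, 5, bank.K))
        O = compute_opponent(E)
        half = bank.K // 2
        assert np.array_equal(O[..., :half], -O[..., half:])

    def test_counterphase_grating_opponent_nearly_vanishes(self, bank):
        seq = gen_counterphase_grating((32, 32), 8, 0.0, 0.125, 1.0, bank.n_taps + 8)
        Es, Os = energy_series(seq.frames, bank)
        for E, O in zip(Es, Os):
            assert np.abs(O).max() < 0.05 * E.max()

    def test_drifting_grating_opponent_positive_in_motion_channel(self, bank):
        seq = gen_drifting_grating((32, 32), 8, 90.0, 1.0, 1.0, bank.n_taps)
        _, Os = energy_series(seq.frames, bank)
        k_down = 2  # 90 deg = downward on screen
        assert np.median(Os[0][..., k_down]) > 0

    def test_odd_channel_count_rejected(self):
        with pytest.raises(ParameterError):
            compute_opponent(np.zeros((4, 4, 7)))


class TestStreaming:
    def test_stream_equals_batch_oracle_on_random_sequence(self, bank):
        rng = np.random.default_rng(7)
        frames = rng.random((32, 24, 24))
        Os = np.stack(process_stream(frames, bank))
        Ob = batch_opponent_oracle(frames, bank)
        assert Os.shape == Ob.shape
        assert np.max(np.abs(Os - Ob)) < 1e-5

    def test_output_length_is_frames_minus_warmup(self, bank):
        frames = np.random.default_rng(0).random((bank.n_taps + 5, 12, 12))
        out = process_stream(frames, bank)
        assert len(out) == 6

    def test_constant_sequence_gives_zero_opponent(self, bank):
        frames = np.full((bank.n_taps + 2, 12, 12), 0.3)
        for O in process_stream(frames, bank):
            assert np.abs(O).max() < 1e-12

    def test_too_short_sequence_is_an_error(self, bank):
        with pytest.raises(ParameterError):
            process_stream(np.zeros((bank.n_taps - 1, 8, 8)), bank)

    def test_engine_reset_clears_warmup(self, bank):
        eng = MotionEnergyEngine(bank)
        for _ in range(bank.n_taps):
            eng.push(np.zeros((8, 8)))
        assert eng.is_warm
        eng.reset()
        assert not eng.is_warm
        assert eng.push(np.zeros((8, 8))) is None


class TestSymmetries:
    @pytest.mark.parametrize("orientation", [0.0, 30.0, 45.0, 135.0])
    def test_time_reversal_swaps_opposite_channels(self, bank, orientation):
        """Channel-energy profiles (interior spatiotemporal means) of a
        drifting grating and its time-reversed copy are opposite-channel
        permutations of each other."""
        seq = gen_drifting_grating((64, 64), 8, orientation, 1.0, 1.0, bank.n_taps + 8)
        Es, _ = energy_series(seq.frames, bank)
        Er, _ = energy_series(seq.frames[::-1], bank)
        b = 10
        m = np.stack(Es)[:, b:-b, b:-b].mean(axis=(0, 1, 2))
        mr = np.stack(Er)[:, b:-b, b:-b].mean(axis=(0, 1, 2))
        assert np.max(np.abs(m - np.roll(mr, bank.K // 2))) < 1e-5 * m.max()

    def test_rot90_of_frames_permutes_channels_by_quarter_turn(self, bank):
        seq = gen_drifting_grating((64, 64), 8, 20.0, 1.0, 1.0, bank.n_taps)
        Es, _ = energy_series(seq.frames, bank)
        rot = np.stack([np.rot90(f) for f in seq.frames])
        Er, _ = energy_series(rot, bank)
        E, Erot = Es[-1], Er[-1]
        Emap = np.stack([np.rot90(E[:, :, k]) for k in range(bank.K)], axis=-1)
        err = np.max(np.abs(Erot - np.roll(Emap, -bank.K // 4, axis=-1)))
        assert err < 1e-5 * E.max()

    def test_divisive_normalization_flattens_contrast_dependence(self, bank):
        def peak_mag(contrast):
            seq = gen_drifting_grating((32, 32), 8, 0.0, 1.0, contrast, bank.n_taps)
            out = process_stream(seq.frames, bank, normalize=True)
            return np.abs(out[-1]).max()

        ratio = peak_mag(0.8) / peak_mag(0.2)
        assert ratio < 4.0  # raw energy would give 16x
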