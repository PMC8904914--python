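import numpy as np
import pytest

from eegmotion.data import EEGRecording
from eegmotion.exceptions import (
    ConfigurationError,
    InputTooShortError,
    UndefinedInputError,
)
from eegmotion.features import (
    FeatureLayout,
    SpectrumFrame,
    dwt_block,
    extract_feature_vector,
    extract_feature_matrix,
    frame_signal,
    fluctuation_index,
    haar_dwt,
    log_band_power,
    magnitude_spectrum,
    relative_energy,
    spectral_decrease,
    spectral_flatness,
    spectral_rolloff,
)

SQRT2 = np.sqrt(2.0)


def _frame(mags, fs=2.0):
    mags = np.asarray(mags, dtype=float)
    freqs = np.arange(len(mags)) * (fs / 2) / max(len(mags) - 1, 1)
    return SpectrumFrame(magnitudes=mags, bin_freqs=freqs)


class TestFraming:
    def test_even_split(self):
        frames = frame_signal(np.arange(8.0), 2)
        assert [len(f) for f in frames] == [4, 4]

    def test_remainder_dropped(self):
        frames = frame_signal(np.arange(9.0), 2)
        assert [len(f) for f in frames] == [4, 4]

    def test_concatenation_covers_prefix(self, rng):
        x = rng.normal(size=29)
        for n_frames in (1, 2, 3, 4):
            frames = frame_signal(x, n_frames)
            seg = len(x) // n_frames
            np.testing.assert_array_equal(
                np.concatenate(frames), x[: n_frames * seg]
            )

    def test_too_short_raises(self):
        with pytest.raises(InputTooShortError):
            frame_signal(np.arange(3.0), 2)


class TestSpectrum:
    def test_pure_cosine_hits_single_bin(self):
        n, k = 16, 3
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        spec = magnitude_spectrum(x, fs=16.0)
        assert int(np.argmax(spec.magnitudes)) == k
        others = np.delete(spec.magnitudes, k)
        assert others.max() < 1e-9 * spec.magnitudes[k]

    def test_zero_segment_gives_zero_spectrum(self):
        spec = magnitude_spectrum(np.zeros(8), fs=8.0)
        assert not spec.magnitudes.any()

    def test_parseval_against_dense_dft(self, rng):
        """Time-domain energy equals (1/n) * sum of dense-DFT |X|^2."""
        x = rng.normal(size=16)
        n = len(x)
        # O(n^2) DFT oracle, independent of the FFT route
        dft = np.array(
            [sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)) for k in range(n)]
        )
        assert np.sum(np.abs(x) ** 2) == pytest.approx(np.sum(np.abs(dft) ** 2) / n)
        spec = magnitude_spectrum(x, fs=1.0)
        np.testing.assert_allclose(spec.magnitudes, np.abs(dft[: n // 2 + 1]), atol=1e-10)


class TestHaar:
    def test_single_level_pair(self):
        approx, details = haar_dwt(np.array([1.0, 3.0]), level=1)
        assert approx[0] == pytest.approx(2 * SQRT2)
        assert details[-1][0] == pytest.approx(-SQRT2)

    def test_constant_signal_has_zero_details(self):
        _, details = haar_dwt(np.full(64, 7.0), level=3)
        for d in details:
            np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_orthonormal_energy_conservation(self, rng):
        x = rng.normal(size=256)
        approx, details = haar_dwt(x, level=4)
        energy = (approx**2).sum() + sum((d**2).sum() for d in details)
        assert energy == pytest.approx((x**2).sum())

    def test_matrix_oracle_one_level(self, rng):
        """One Haar level equals multiplying pairs by [[1,1],[1,-1]]/sqrt(2)."""
        x = rng.normal(size=32)
        approx, details = haar_dwt(x, level=1)
        pairs = x.reshape(-1, 2)
        np.testing.assert_allclose(approx, pairs.sum(axis=1) / SQRT2, atol=1e-12)
        np.testing.assert_allclose(
            details[0], (pairs[:, 0] - pairs[:, 1]) / SQRT2, atol=1e-12
        )

    def test_dwt_block_length_and_level(self, recording40):
        layout = FeatureLayout()
        block = dwt_block(recording40, layout)
        assert block.shape == (64,)
        # 512 samples -> level 3 leaves exactly 64 approximation coeffs,
        # so no zero-padding should occur for a generic signal
        assert np.all(block != 0)

    def test_too_short_signal_raises(self):
        rec = EEGRecording(signal=np.ones((1, 16)), fs=128.0)
        with pytest.raises(InputTooShortError):
            dwt_block(rec, FeatureLayout(dwt_len=64))


class TestSpectralFlatness:
    def test_equal_bins_give_one(self):
        assert spectral_flatness(_frame([0, 2, 2, 2, 2])) == pytest.approx(1.0)

    def test_single_tone_gives_zero(self):
        assert spectral_flatness(_frame([0, 0, 5, 0, 0])) == 0.0

    def test_power_bins_one_four(self):
        # power bins [1, 4]: GM = 2, AM = 2.5
        assert spectral_flatness(_frame([9, 1, 2])) == pytest.approx(0.8)

    def test_zero_spectrum_undefined(self):
        with pytest.raises(UndefinedInputError):
            spectral_flatness(_frame([0, 0, 0]))


class TestLogBandPower:
    def test_unit_band_power_gives_zero(self):
        # single cosine at bin 2 of n=8, amplitude chosen so |X_k|^2 = 1
        n, fs = 8, 8.0
        x = (2.0 / n) * np.cos(2 * np.pi * 2 * np.arange(n) / n)
        assert log_band_power(x, (1.5, 2.5), fs) == pytest.approx(0.0, abs=1e-10)

    def test_scaling_shifts_by_two_log_c(self, rng):
        x = rng.normal(size=64)
        base = log_band_power(x, (0.5, 20.0), 128.0)
        scaled = log_band_power(5.0 * x, (0.5, 20.0), 128.0)
        assert scaled - base == pytest.approx(2 * np.log(5.0))

    def test_sinusoid_matches_time_domain_parseval(self):
        """For an exact-bin unit sinusoid, in-band power is n^2/4 per one-sided bin."""
        n, fs, k = 256, 128.0, 20
        x = np.sin(2 * np.pi * k * np.arange(n) / n)
        expected = (n / 2) ** 2  # |X_k| = n/2 for unit amplitude
        got = log_band_power(x, (8.0, 12.0), fs)  # bin 20 <-> 10 Hz
        assert got == pytest.approx(np.log(expected), abs=1e-9)

    def test_out_of_range_band_rejected(self):
        with pytest.raises(ConfigurationError):
            log_band_power(np.ones(16), (0.0, 100.0), 16.0)

    def test_zero_band_power_undefined(self):
        with pytest.raises(UndefinedInputError):
            log_band_power(np.zeros(64), (20.0, 30.0), 64.0)


class TestFluctuationIndex:
    def test_constant_is_zero(self):
        rec = EEGRecording(signal=np.full((2, 10), 3.0), fs=1.0)
        assert fluctuation_index(rec) == 0.0

    def test_alternating_binary_channel(self):
        rec = EEGRecording(signal=np.array([[0.0, 1.0, 0.0, 1.0]]), fs=1.0)
        assert fluctuation_index(rec) == pytest.approx(0.75)

    def test_ramp_closed_form(self):
        n, d = 10, 0.5
        rec = EEGRecording(signal=(d * np.arange(n))[None, :], fs=1.0)
        assert fluctuation_index(rec) == pytest.approx((n - 1) * d / n)

    def test_scales_linearly_with_amplitude(self, toy_recording):
        base = fluctuation_index(toy_recording)
        scaled = fluctuation_index(toy_recording.replace_signal(3.0 * toy_recording.signal))
        assert scaled == pytest.approx(3.0 * base)


class TestSpectralDecrease:
    def test_flat_spectrum_is_zero(self):
        assert spectral_decrease(_frame([1, 2, 2, 2, 2])) == 0.0

    @pytest.mark.parametrize(
        "mags,expected",
        [([0, 1, 2], 0.5), ([0, 2, 1, 0], -2.0)],
    )
    def test_hand_computed_values(self, mags, expected):
        assert spectral_decrease(_frame(mags)) == pytest.approx(expected)

    def test_zero_denominator_undefined(self):
        with pytest.raises(UndefinedInputError):
            spectral_decrease(_frame([0, 5, 0, 0]))


class TestSpectralRolloff:
    def test_single_bin_for_any_fraction(self):
        frame = _frame([0, 0, 0, 4, 0, 0], fs=10.0)
        for fraction in (0.1, 0.5, 0.85, 1.0):
            assert spectral_rolloff(frame, fraction) == pytest.approx(frame.bin_freqs[3])

    def test_ten_equal_bins_fraction_085(self):
        frame = _frame([0] + [1] * 10, fs=20.0)
        # cumulative power fractions 0.1..1.0; first >= 0.85 at the 9th bin
        assert spectral_rolloff(frame, 0.85) == pytest.approx(frame.bin_freqs[9])

    def test_fraction_one_hits_last_nonzero_bin(self):
        frame = _frame([0, 1, 2, 3, 0, 0], fs=10.0)
        assert spectral_rolloff(frame, 1.0) == pytest.approx(frame.bin_freqs[3])

    def test_zero_energy_undefined(self):
        with pytest.raises(UndefinedInputError):
            spectral_rolloff(_frame([3, 0, 0]), 0.85)


class TestRelativeEnergy:
    def test_full_band_is_one(self, recording40):
        fs = recording40.fs
        assert relative_energy(recording40, (0.0, fs / 2)) == pytest.approx(1.0)

    def test_signal_outside_band_is_zero(self):
        n, fs = 256, 128.0
        x = np.sin(2 * np.pi * 40 * np.arange(n) / fs)
        rec = EEGRecording(signal=x[None, :], fs=fs)
        assert relative_energy(rec, (1.0, 4.0)) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_tones_split_half(self):
        n, fs = 256, 128.0
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 40 * t)
        rec = EEGRecording(signal=x[None, :], fs=fs)
        assert relative_energy(rec, (8.0, 13.0)) == pytest.approx(0.5, abs=1e-9)


class TestAssembly:
    def test_default_block_sizes_forty_channels(self, recording40):
        fv = extract_feature_vector(recording40)
        sizes = {k: s.stop - s.start for k, s in fv.spans.items()}
        assert sizes == {"q1": 64, "q2": 80, "q3": 40, "q4": 1, "q5": 80, "q6": 80, "q7": 1}
        assert len(fv.values) == 346

    def test_single_channel_minimal_layout(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(signal=rng.normal(size=(1, 128)), fs=128.0)
        layout = FeatureLayout(frames_per_channel=1)
        fv = extract_feature_vector(rec, layout)
        sizes = [s.stop - s.start for s in fv.spans.values()]
        assert sizes == [64, 1, 1, 1, 1, 1, 1]

    def test_blocks_match_isolated_recomputation(self, recording40):
        layout = FeatureLayout()
        fv = extract_feature_vector(recording40, layout)
        np.testing.assert_allclose(fv.block("q1"), dwt_block(recording40, layout))
        q3 = [
            log_band_power(ch, layout.logbp_bands[0], recording40.fs)
            for ch in recording40.signal
        ]
        np.testing.assert_allclose(fv.block("q3"), q3)
        assert fv.block("q4")[0] == pytest.approx(fluctuation_index(recording40))
        assert fv.block("q7")[0] == pytest.approx(
            relative_energy(recording40, layout.relative_band)
        )

    def test_scale_invariances_of_assembled_vector(self, recording40):
        """Multiplying the signal by c>0 leaves flatness/decrease/roll-off/
        relative-energy blocks unchanged, shifts log band power by 2 ln c,
        and scales the fluctuation index by c."""
        c = 3.7
        layout = FeatureLayout()
        fv = extract_feature_vector(recording40, layout)
        fv_scaled = extract_feature_vector(
            recording40.replace_signal(c * recording40.signal), layout
        )
        for block in ("q2", "q5", "q6", "q7"):
            np.testing.assert_allclose(
                fv_scaled.block(block), fv.block(block), rtol=1e-9, atol=1e-12
            )
        np.testing.assert_allclose(
            fv_scaled.block("q3"), fv.block("q3") + 2 * np.log(c), rtol=1e-9
        )
        assert fv_scaled.block("q4")[0] == pytest.approx(c * fv.block("q4")[0])

    def test_descriptor_ranges(self, recording40):
        fv = extract_feature_vector(recording40)
        assert np.all(fv.block("q2") >= 0) and np.all(fv.block("q2") <= 1)
        assert 0 <= fv.block("q7")[0] <= 1
        assert fv.block("q4")[0] >= 0
        assert np.all(fv.block("q6") >= 0)
        assert np.all(fv.block("q6") <= recording40.fs / 2)

    def test_matrix_rows_share_layout(self, small_corpus):
        fm = extract_feature_matrix(small_corpus)
        assert fm.X.shape == (10, small_corpus.recordings[0].n_channels * 7 + 66)
        assert len(set(map(len, fm.X))) == 1
        assert fm.labels.tolist() == [0] * 5 + [1] * 5

    def test_error_annotated_with_block_name(self):
        # zero signal makes q2 (flatness) undefined
        rec = EEGRecording(signal=np.zeros((1, 128)), fs=128.0)
        rec.signal[:] = 0.0
        with pytest.raises(Exception, match="q"):
            extract_feature_vector(rec, FeatureLayout(frames_per_channel=1))
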