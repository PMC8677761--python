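"""Waveform I/O, noise subtraction, spectrogram and peak-extraction tests."""

import numpy as np
import pytest
from scipy.io import wavfile

from swarmtone.audio_core import (
    AudioClip,
    band_peak_series,
    build_noise_profile,
    compute_spectrogram,
    peak_in_band,
    read_wav,
    subtract_noise,
    write_wav,
)

SR = 44100


def sine(freq, seconds=1.0, amp=1.0, sr=SR):
    t = np.arange(int(seconds * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


class TestWavIO:
    def test_zeros_round_trip(self, tmp_path):
        clip = AudioClip(np.zeros(SR), SR)
        path = tmp_path / "z.wav"
        write_wav(clip, path)
        back = read_wav(path)
        assert back.sample_rate == SR
        assert back.samples.size == SR
        assert np.all(back.samples == 0)

    def test_float32_sine_round_trip(self, tmp_path):
        x = sine(550.0)
        path = tmp_path / "s.wav"
        write_wav(AudioClip(x, SR), path)
        back = read_wav(path)
        assert np.max(np.abs(back.samples - x)) < 1e-6

    def test_pcm16_quantization(self, tmp_path):
        x = sine(550.0, amp=0.5)
        path = tmp_path / "q.wav"
        write_wav(AudioClip(x, SR), path, subtype="pcm16")
        back = read_wav(path)
        assert np.max(np.abs(back.samples - x)) < 2.0 / 32768.0

    def test_stereo_downmixed_to_mono(self, tmp_path):
        x = sine(440.0).astype(np.float32)
        path = tmp_path / "st.wav"
        wavfile.write(path, SR, np.column_stack([x, x]))
        back = read_wav(path)
        assert back.samples.ndim == 1
        assert np.max(np.abs(back.samples - x)) < 1e-6

    def test_nan_write_rejected(self, tmp_path):
        x = sine(440.0)
        x[100] = np.nan
        clip = AudioClip.__new__(AudioClip)  # bypass validation to test writer
        object.__setattr__(clip, "samples", x)
        object.__setattr__(clip, "sample_rate", SR)
        with pytest.raises(ValueError):
            write_wav(clip, tmp_path / "bad.wav")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.wav"
        path.write_bytes(b"")
        with pytest.raises(Exception):
            read_wav(path)

    def test_clip_validation(self):
        with pytest.raises(ValueError):
            AudioClip(np.zeros(10), 4000)  # sample rate too low
        with pytest.raises(ValueError):
            AudioClip(np.full(10, np.inf), SR)


class TestNoiseProfile:
    def test_digital_silence(self):
        prof = build_noise_profile(AudioClip(np.zeros(2 * SR), SR))
        assert np.all(prof.mean_mag == 0)
        assert np.all(prof.sd_mag == 0)

    def test_white_noise_flat(self, rng):
        x = 0.05 * rng.standard_normal(10 * SR)
        prof = build_noise_profile(AudioClip(x, SR))
        interior = prof.mean_mag[1:-1]  # DC/Nyquist carry window artifacts
        cv = interior.std() / interior.mean()
        assert cv < 0.2

    def test_sine_concentrated(self):
        prof = build_noise_profile(AudioClip(sine(550.0, 2.0), SR))
        peak_bin = np.argmin(np.abs(prof.bin_freqs - 550.0))
        others = np.delete(prof.mean_mag, np.arange(peak_bin - 2, peak_bin + 3))
        assert prof.mean_mag[peak_bin] >= 10 * np.median(others)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_noise_profile(AudioClip(np.zeros(100), SR))


class TestSubtractNoise:
    def test_zero_profile_identity(self):
        prof = build_noise_profile(AudioClip(np.zeros(SR), SR))
        x = sine(550.0)
        out = subtract_noise(AudioClip(x, SR), prof)
        assert out.samples.size == x.size
        assert np.max(np.abs(out.samples - x)) < 1e-3

    def test_snr_improves_by_6db(self, rng):
        sig = sine(550.0, amp=0.1)  # -20 dBFS
        noise = 0.02 * rng.standard_normal(11 * SR)
        prof = build_noise_profile(AudioClip(noise[: 10 * SR], SR))
        mix = sig + noise[10 * SR :]
        den = subtract_noise(AudioClip(mix, SR), prof)

        def snr(x):
            err = x - sig
            return 10 * np.log10(np.sum(sig**2) / np.sum(err**2))

        assert snr(den.samples) - snr(mix) >= 6.0

    def test_noise_minus_own_profile(self, rng):
        noise = 0.02 * rng.standard_normal(10 * SR)
        clip = AudioClip(noise, SR)
        prof = build_noise_profile(clip)
        out = subtract_noise(clip, prof)
        assert np.sum(out.samples**2) < 0.25 * np.sum(noise**2)

    def test_second_application_changes_little(self, rng):
        sig = sine(550.0, amp=0.1) + 0.01 * rng.standard_normal(SR)
        prof = build_noise_profile(
            AudioClip(0.01 * rng.standard_normal(10 * SR), SR)
        )
        once = subtract_noise(AudioClip(sig, SR), prof)
        twice = subtract_noise(once, prof)
        power_change = 10 * np.log10(
            np.sum(twice.samples**2) / np.sum(once.samples**2)
        )
        assert abs(power_change) < 1.0

    def test_geometry_mismatch_rejected(self):
        prof = build_noise_profile(AudioClip(np.zeros(SR), SR), window_s=0.05)
        other = build_noise_profile(AudioClip(np.zeros(SR), SR))
        assert prof.window_samples != other.window_samples
        with pytest.raises(ValueError):
            subtract_noise(AudioClip(np.zeros(2 * SR), 48000), prof)


class TestSpectrogram:
    def test_single_tone_peak_bin(self):
        spec = compute_spectrogram(AudioClip(sine(550.0), SR))
        frame = spec.mag[len(spec.times) // 2]
        peak_freq = spec.freqs[np.argmax(frame)]
        assert abs(peak_freq - 550.0) <= spec.bin_width

    def test_chirp_ridge_monotone(self):
        t = np.arange(10 * SR) / SR
        chirp = np.sin(2 * np.pi * (500.0 * t + 5.0 * t**2))  # 500 -> 600 Hz
        spec = compute_spectrogram(AudioClip(chirp, SR), fmax=800.0)
        ridge = spec.freqs[np.argmax(spec.mag, axis=1)]
        assert np.all(np.diff(ridge) >= 0)

    def test_silence_at_floor(self):
        spec = compute_spectrogram(AudioClip(np.zeros(SR), SR))
        assert np.all(spec.db == spec.db.min())
        assert spec.db.min() <= -190.0

    @pytest.mark.parametrize(
        "n,window_s,overlap",
        [(SR, 0.0929, 0.75), (SR, 0.0929, 0.0), (2 * SR, 0.05, 0.5), (SR, 0.1, 0.9)],
    )
    def test_frame_count_formula(self, n, window_s, overlap):
        spec = compute_spectrogram(AudioClip(np.zeros(n), SR), window_s, overlap)
        w = int(window_s * SR)
        hop = max(1, int(round(w * (1 - overlap))))
        assert spec.times.size == (n - w) // hop + 1

    def test_parseval_consistency(self, rng):
        x = 0.1 * rng.standard_normal(SR)
        spec = compute_spectrogram(AudioClip(x, SR), zero_pad=1)
        from scipy.signal.windows import hann

        w = hann(spec.window_samples, sym=False)
        frames = np.lib.stride_tricks.sliding_window_view(x, spec.window_samples)[
            :: spec.hop
        ]
        time_power = np.sum((frames * w) ** 2, axis=1)
        X2 = (spec.mag / spec.scale) ** 2
        spectral = (2 * X2.sum(axis=1) - X2[:, 0] - X2[:, -1]) / spec.nfft
        assert np.all(np.abs(spectral - time_power) <= 0.01 * time_power)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrogram(AudioClip(np.zeros(100), SR))


class TestPeakInBand:
    def test_tone_recovered(self):
        spec = compute_spectrogram(AudioClip(sine(552.0), SR))
        f0, amp = peak_in_band(spec, 0.5, (400.0, 700.0))
        assert abs(f0 - 552.0) < 2.0
        assert amp > -1.0  # full-scale sine reads near 0 dBFS

    def test_white_noise_gives_none(self, rng):
        x = 0.1 * rng.standard_normal(SR)
        spec = compute_spectrogram(AudioClip(x, SR))
        assert peak_in_band(spec, 0.5, (400.0, 700.0)) is None

    def test_dominant_tone_wins(self):
        x = sine(550.0, amp=0.1) + sine(600.0, amp=10 ** (-35 / 20))
        spec = compute_spectrogram(AudioClip(x, SR))
        f0, _ = peak_in_band(spec, 0.5, (400.0, 700.0))
        assert abs(f0 - 550.0) < 2.0

    def test_subbin_accuracy_over_random_tones(self, rng):
        errors = []
        for f in rng.uniform(400.0, 1000.0, 50):
            x = sine(f, amp=0.3) + 0.003 * rng.standard_normal(SR)
            spec = compute_spectrogram(AudioClip(x, SR))
            f0, _ = peak_in_band(spec, 0.5, (380.0, 1020.0))
            errors.append(abs(f0 - f))
        assert max(errors) <= spec.bin_width / 2

    def test_empty_band_rejected(self):
        spec = compute_spectrogram(AudioClip(sine(550.0), SR), fmax=1200.0)
        with pytest.raises(ValueError):
            peak_in_band(spec, 0.5, (700.0, 700.0))

    def test_band_series_matches_single_frame(self):
        spec = compute_spectrogram(AudioClip(sine(552.0), SR))
        f0s, amps, valid = band_peak_series(spec, (400.0, 700.0))
        i = len(spec.times) // 2
        single = peak_in_band(spec, spec.times[i], (400.0, 700.0))
        assert valid[i]
        assert single == pytest.approx((f0s[i], amps[i]))
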