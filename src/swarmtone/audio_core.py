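"""Waveform and time-frequency primitives for swarm audio analysis.

This module provides the substrate every downstream measurement is built
on: WAV input/output, a spectral noise profile estimated from a silent
lead-in, magnitude-domain spectral subtraction, short-time Fourier
spectrograms, and band-limited peak extraction with parabolic sub-bin
refinement.

Amplitudes are expressed in dB relative to digital full scale (dBFS):
a full-scale sine (peak amplitude 1.0) reads approximately 0 dB on the
spectrogram.  All amplitude criteria used downstream are differences, so
the absolute reference cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

__all__ = [
    "AudioClip",
    "NoiseProfile",
    "Spectrogram",
    "read_wav",
    "write_wav",
    "build_noise_profile",
    "subtract_noise",
    "compute_spectrogram",
    "peak_in_band",
    "band_peak_series",
    "DB_FLOOR",
]

#: magnitude floor used when converting to dB; keeps log finite for silence
_MAG_EPS = 1e-10
DB_FLOOR = 20.0 * np.log10(_MAG_EPS)

#: minimum sample rate accepted for swarm audio (fundamentals + overtones
#: of interest all lie below 4 kHz)
MIN_SAMPLE_RATE = 8000


@dataclass(frozen=True)
class AudioClip:
    """A mono waveform at full-scale amplitude (samples nominally in [-1, 1])."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional (mono)")
        if not np.issubdtype(samples.dtype, np.floating):
            samples = samples.astype(np.float64)
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("AudioClip samples must be finite")
        if int(self.sample_rate) < MIN_SAMPLE_RATE:
            raise ValueError(f"sample_rate must be >= {MIN_SAMPLE_RATE} Hz")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate


def read_wav(path) -> AudioClip:
    """Read a PCM or float WAV file as a mono :class:`AudioClip`.

    Integer formats are rescaled to full scale; multichannel files are
    downmixed by averaging across channels.
    """
    sample_rate, data = wavfile.read(path)
    if data.size == 0:
        raise IOError(f"empty WAV file: {path}")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioClip(x, sample_rate)


def write_wav(clip: AudioClip, path, subtype: str = "float32") -> None:
    """Write a clip to disk as ``float32`` (default) or ``pcm16`` WAV."""
    x = clip.samples
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("cannot write non-finite samples")
    if subtype == "float32":
        wavfile.write(path, clip.sample_rate, x.astype(np.float32))
    elif subtype == "pcm16":
        q = np.round(np.clip(x, -1.0, 1.0) * 32767.0).astype(np.int16)
        wavfile.write(path, clip.sample_rate, q)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


# ---------------------------------------------------------------------------
# noise profiling and spectral subtraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseProfile:
    """Per-bin magnitude statistics of a noise-only segment.

    Built at a fixed STFT geometry; :func:`subtract_noise` refuses to apply
    a profile whose geometry does not match its own.
    """

    bin_freqs: np.ndarray
    mean_mag: np.ndarray
    sd_mag: np.ndarray
    window_samples: int
    hop: int
    sample_rate: int

    def __post_init__(self) -> None:
        if not (len(self.bin_freqs) == len(self.mean_mag) == len(self.sd_mag)):
            raise ValueError("profile fields must have equal length")
        if np.any(np.diff(self.bin_freqs) <= 0):
            raise ValueError("bin_freqs must be strictly increasing")


def _stft_transform(sample_rate: int, window_samples: int, hop: int) -> ShortTimeFFT:
    win = hann(window_samples, sym=False)
    return ShortTimeFFT(win, hop, fs=sample_rate, fft_mode="onesided")


def _window_geometry(clip: AudioClip, window_s: float, overlap: float) -> tuple[int, int]:
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    window_samples = int(window_s * clip.sample_rate)
    if window_samples < 64:
        raise ValueError("window must cover at least 64 samples")
    hop = max(1, int(round(window_samples * (1.0 - overlap))))
    return window_samples, hop


def build_noise_profile(
    clip: AudioClip, window_s: float = 0.0929, overlap: float = 0.5
) -> NoiseProfile:
    """Estimate per-bin mean and SD of STFT magnitude over a noise clip.

    The clip is typically the silent lead-in recorded before any
    mosquitoes are present.
    """
    window_samples, hop = _window_geometry(clip, window_s, overlap)
    if clip.samples.size < window_samples:
        raise ValueError("clip shorter than one analysis window")
    sft = _stft_transform(clip.sample_rate, window_samples, hop)
    mag = np.abs(sft.stft(clip.samples))  # (bins, frames)
    return NoiseProfile(
        bin_freqs=sft.f.copy(),
        mean_mag=mag.mean(axis=1),
        sd_mag=mag.std(axis=1),
        window_samples=window_samples,
        hop=hop,
        sample_rate=clip.sample_rate,
    )


def subtract_noise(
    clip: AudioClip,
    profile: NoiseProfile,
    over_subtraction: float = 1.0,
    floor: float = 0.02,
) -> AudioClip:
    """Magnitude-domain spectral subtraction against a noise profile.

    Each STFT bin magnitude is reduced by
    ``over_subtraction * (mean_mag + sd_mag)`` and floored at
    ``floor`` times the original magnitude; phase is preserved and the
    output has exactly the input length.
    """
    if profile.sample_rate != clip.sample_rate:
        raise ValueError("profile sample rate does not match clip")
    sft = _stft_transform(clip.sample_rate, profile.window_samples, profile.hop)
    if len(sft.f) != len(profile.bin_freqs):
        raise ValueError("profile STFT geometry does not match clip")
    S = sft.stft(clip.samples)
    mag = np.abs(S)
    reduction = over_subtraction * (profile.mean_mag + profile.sd_mag)
    target = np.maximum(mag - reduction[:, None], floor * mag)
    gain = target / np.maximum(mag, _MAG_EPS)
    y = sft.istft(S * gain, k1=clip.samples.size)
    return AudioClip(np.asarray(y, dtype=np.float64), clip.sample_rate)


# ---------------------------------------------------------------------------
# spectrograms
# ---------------------------------------------------------------------------


@dataclass
class Spectrogram:
    """Magnitude spectrogram (frames x bins) with dBFS view.

    ``mag`` is scaled so a full-scale sine reads ~1.0 at its peak bin.
    Frame centers follow the no-padding convention: frame count equals
    ``floor((N - W) / hop) + 1``.
    """

    times: np.ndarray
    freqs: np.ndarray
    mag: np.ndarray
    sample_rate: int
    window_samples: int
    hop: int
    nfft: int
    scale: float

    @cached_property
    def db(self) -> np.ndarray:
        """Magnitude in dB re full scale, floored at ``DB_FLOOR``."""
        return (20.0 * np.log10(np.maximum(self.mag, _MAG_EPS))).astype(np.float32)

    @property
    def frame_dt(self) -> float:
        return self.hop / self.sample_rate

    @property
    def bin_width(self) -> float:
        return self.sample_rate / self.nfft


def compute_spectrogram(
    clip: AudioClip,
    window_s: float = 0.0929,
    overlap: float = 0.75,
    zero_pad: int = 4,
    fmax: float | None = None,
) -> Spectrogram:
    """Hann-windowed magnitude spectrogram with optional zero-padding.

    Parameters
    ----------
    window_s : analysis window length in seconds (floored to samples).
    overlap : fractional window overlap in [0, 1).
    zero_pad : FFT zero-padding factor; refines bin spacing to
        ``sample_rate / (zero_pad * window_samples)``.
    fmax : if given, bins above this frequency are discarded (keeps the
        stored matrix small for hour-long recordings).
    """
    window_samples, hop = _window_geometry(clip, window_s, overlap)
    n = clip.samples.size
    if n < window_samples:
        raise ValueError("clip shorter than one analysis window")
    nfft = window_samples * int(zero_pad)
    n_frames = 1 + (n - window_samples) // hop
    win = hann(window_samples, sym=False)
    scale = 2.0 / win.sum()
    freqs = rfftfreq(nfft, 1.0 / clip.sample_rate)
    if fmax is not None:
        n_bins = int(np.searchsorted(freqs, fmax, side="right"))
        if n_bins < 3:
            raise ValueError("fmax leaves fewer than 3 bins")
        freqs = freqs[:n_bins]
    else:
        n_bins = freqs.size

    frames = np.lib.stride_tricks.sliding_window_view(clip.samples, window_samples)[::hop]
    mag = np.empty((n_frames, n_bins), dtype=np.float32)
    chunk = max(1, 2048)
    for start in range(0, n_frames, chunk):
        stop = min(start + chunk, n_frames)
        X = rfft(frames[start:stop] * win, n=nfft, axis=1)
        mag[start:stop] = np.abs(X[:, :n_bins]) * scale
    times = (np.arange(n_frames) * hop + window_samples / 2.0) / clip.sample_rate
    return Spectrogram(
        times=times,
        freqs=freqs.copy(),
        mag=mag,
        sample_rate=clip.sample_rate,
        window_samples=window_samples,
        hop=hop,
        nfft=nfft,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# band-limited peak extraction
# ---------------------------------------------------------------------------

#: default prominence gate (dB above the band's median level) separating a
#: tracked tone from "no flyer in band".  Broadband noise alone produces a
#: peak-to-median spread of 8-9 dB across a few hundred Rayleigh bins, so
#: the gate sits above that.
DEFAULT_PROMINENCE_DB = 12.0

#: absolute level floor (dBFS) for a tracked tone: peaks this far below
#: full scale are window-leakage skirts of out-of-band tones, not flyers
DEFAULT_ABS_FLOOR_DB = -75.0


def _band_indices(freqs: np.ndarray, band: tuple[float, float]) -> tuple[int, int]:
    lo, hi = band
    if not hi > lo:
        raise ValueError("band must satisfy lo < hi")
    # half-open [lo, hi): adjacent bands never share a bin
    i0 = int(np.searchsorted(freqs, lo, side="left"))
    i1 = int(np.searchsorted(freqs, hi, side="left"))
    if i1 - i0 < 3:
        raise ValueError("band covers fewer than 3 spectrogram bins")
    return i0, i1


def band_peak_series(
    spec: Spectrogram,
    band: tuple[float, float],
    min_prominence_db: float = DEFAULT_PROMINENCE_DB,
    min_abs_db: float = DEFAULT_ABS_FLOOR_DB,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame dominant peak inside a frequency band.

    Returns ``(f0, amp_db, valid)`` arrays over all frames; ``valid`` is
    False where no peak clears both the prominence gate and the absolute
    level floor, or where the maximum sits on a band-edge bin (the true
    tone then lies outside the band).  Peak frequency and amplitude are
    refined by 3-point parabolic interpolation on the dB spectrum.
    """
    i0, i1 = _band_indices(spec.freqs, band)
    db = spec.db[:, i0:i1]
    j = np.argmax(db, axis=1)
    rows = np.arange(db.shape[0])
    peak_db = db[rows, j]
    median_db = np.median(db, axis=1)
    interior = (j > 0) & (j < db.shape[1] - 1)
    valid = (peak_db - median_db >= min_prominence_db) & (peak_db >= min_abs_db)
    valid &= interior

    # parabolic refinement on interior peaks
    left = np.where(interior, db[rows, np.clip(j - 1, 0, None)], peak_db)
    right = np.where(interior, db[rows, np.clip(j + 1, None, db.shape[1] - 1)], peak_db)
    denom = left - 2.0 * peak_db + right
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (left - right) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    f0 = spec.freqs[j + i0] + delta * spec.bin_width
    amp = peak_db - 0.25 * (left - right) * delta
    return np.asarray(f0, dtype=np.float64), np.asarray(amp, dtype=np.float64), valid


def peak_in_band(
    spec: Spectrogram,
    t: float,
    band: tuple[float, float],
    min_prominence_db: float = DEFAULT_PROMINENCE_DB,
    min_abs_db: float = DEFAULT_ABS_FLOOR_DB,
) -> tuple[float, float] | None:
    """Dominant spectral peak in ``band`` at the frame nearest time ``t``.

    Returns ``(f0_hz, amp_db)`` or ``None`` when no peak rises at least
    ``min_prominence_db`` above the band's median level (no flyer in band).
    """
    frame = int(np.clip(np.searchsorted(spec.times, t), 0, spec.times.size - 1))
    if frame > 0 and abs(spec.times[frame - 1] - t) < abs(spec.times[frame] - t):
        frame -= 1
    sub = Spectrogram(
        times=spec.times[frame : frame + 1],
        freqs=spec.freqs,
        mag=spec.mag[frame : frame + 1],
        sample_rate=spec.sample_rate,
        window_samples=spec.window_samples,
        hop=spec.hop,
        nfft=spec.nfft,
        scale=spec.scale,
    )
    f0, amp, valid = band_peak_series(sub, band, min_prominence_db, min_abs_db)
    if not valid[0]:
        return None
    return float(f0[0]), float(amp[0])
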