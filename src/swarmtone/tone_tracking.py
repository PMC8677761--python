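"""Per-sex fundamental flight-tone tracks and swarm-period binning.

Swarming males hold fundamentals near 850 Hz and females near 550 Hz, so
the two sexes occupy disjoint search bands (700-1100 and 400-700 Hz by
default).  A track is the per-frame dominant peak of its band, split into
segments wherever the ridge jumps by more than a continuity gate.  Tracks
are sampled on a fixed cadence (60 s in the standard protocol) and samples
are binned into the four 15-min swarm periods of the 1-h sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .audio_core import DEFAULT_PROMINENCE_DB, Spectrogram, band_peak_series

__all__ = [
    "Band",
    "BAND_RANGES",
    "SwarmPeriod",
    "PERIOD_BOUNDS",
    "swarm_period_of",
    "ToneSample",
    "ToneTrack",
    "track_band",
    "sample_track",
    "bin_by_period",
]


class Band(Enum):
    """Sex-specific fundamental search band."""

    MALE = "male"
    FEMALE = "female"


#: default fundamental search ranges (Hz); chosen around the reported
#: ~850 Hz male and ~550 Hz female baseline swarm fundamentals
BAND_RANGES: dict[Band, tuple[float, float]] = {
    Band.MALE: (700.0, 1100.0),
    Band.FEMALE: (400.0, 700.0),
}


class SwarmPeriod(Enum):
    """Quarter-hour phases of the 1-h swarm sequence."""

    PRE = "pre"
    PEAK = "peak"
    WANING = "waning"
    LATE = "late"


#: half-open [lo, hi) boundaries in seconds from recording start
PERIOD_BOUNDS: dict[SwarmPeriod, tuple[float, float]] = {
    SwarmPeriod.PRE: (0.0, 900.0),
    SwarmPeriod.PEAK: (900.0, 1800.0),
    SwarmPeriod.WANING: (1800.0, 2700.0),
    SwarmPeriod.LATE: (2700.0, 3600.0),
}

_PERIOD_ORDER = [SwarmPeriod.PRE, SwarmPeriod.PEAK, SwarmPeriod.WANING, SwarmPeriod.LATE]


def swarm_period_of(t: float) -> SwarmPeriod:
    """Map a time (seconds) to its swarm period; bins are half-open [lo, hi)."""
    if not 0.0 <= t < 3600.0:
        raise ValueError(f"time {t} s outside the 1-h swarm sequence [0, 3600)")
    return _PERIOD_ORDER[min(int(t // 900.0), 3)]


@dataclass(frozen=True)
class ToneSample:
    """One cadence sample of a track: time, fundamental, amplitude, labels.

    ``f0`` and ``amp`` are ``None`` when no tone was present within the
    snapping tolerance (an "absent" marker).
    """

    t: float
    f0: float | None
    amp: float | None
    band: Band
    period: SwarmPeriod
    interacting: bool = False

    @property
    def absent(self) -> bool:
        return self.f0 is None


@dataclass
class ToneTrack:
    """Frame-resolution fundamental track for one sex band (gaps allowed).

    ``times``/``f0``/``amp``/``segment_id`` are aligned arrays over the
    frames where a tone was present.  ``frame_dt``, ``grid_t0`` and
    ``n_frames`` describe the underlying uniform spectrogram frame grid,
    and ``duration`` the extent of the recording.
    """

    band: Band
    times: np.ndarray
    f0: np.ndarray
    amp: np.ndarray
    segment_id: np.ndarray
    frame_dt: float
    grid_t0: float
    n_frames: int
    duration: float

    def __post_init__(self) -> None:
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("track frame times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def empty(self) -> bool:
        return self.times.size == 0

    @classmethod
    def from_arrays(
        cls,
        band: Band,
        times,
        f0,
        amp,
        frame_dt: float,
        duration: float | None = None,
        max_jump_hz: float = 150.0,
    ) -> "ToneTrack":
        """Build a track from explicit arrays (used by tests and synthesis)."""
        times = np.asarray(times, dtype=np.float64)
        f0 = np.asarray(f0, dtype=np.float64)
        amp = np.asarray(amp, dtype=np.float64)
        if times.size:
            grid_t0 = float(times[0])
            n_frames = int(round((times[-1] - times[0]) / frame_dt)) + 1
            dur = duration if duration is not None else float(times[-1] + frame_dt)
        else:
            grid_t0, n_frames = 0.0, 0
            dur = duration if duration is not None else 0.0
        seg = _segment_ids(times, f0, frame_dt, max_jump_hz)
        return cls(band, times, f0, amp, seg, frame_dt, grid_t0, n_frames, dur)


def _segment_ids(
    times: np.ndarray, f0: np.ndarray, frame_dt: float, max_jump_hz: float
) -> np.ndarray:
    """Split a ridge into segments at gaps or frequency jumps > gate."""
    if times.size == 0:
        return np.empty(0, dtype=np.int64)
    breaks = np.zeros(times.size, dtype=bool)
    if times.size > 1:
        dt = np.diff(times)
        df = np.abs(np.diff(f0))
        breaks[1:] = (dt > 2.5 * frame_dt) | (df > max_jump_hz)
    return np.cumsum(breaks).astype(np.int64)


def track_band(
    spec: Spectrogram,
    band: Band,
    freq_range: tuple[float, float] | None = None,
    max_jump_hz: float = 150.0,
    min_prominence_db: float = DEFAULT_PROMINENCE_DB,
) -> ToneTrack:
    """Extract the fundamental-tone ridge of one sex band from a spectrogram.

    One entry is produced per frame where the band's dominant peak clears
    the prominence gate; frequency jumps above ``max_jump_hz`` between
    consecutive frames start a new segment (distinct flyer).
    """
    rng = freq_range if freq_range is not None else BAND_RANGES[band]
    f0, amp, valid = band_peak_series(spec, rng, min_prominence_db)
    times = spec.times[valid]
    seg = _segment_ids(times, f0[valid], spec.frame_dt, max_jump_hz)
    duration = float(spec.times[-1] + spec.window_samples / (2.0 * spec.sample_rate))
    return ToneTrack(
        band=band,
        times=times,
        f0=f0[valid],
        amp=amp[valid],
        segment_id=seg,
        frame_dt=spec.frame_dt,
        grid_t0=float(spec.times[0]),
        n_frames=int(spec.times.size),
        duration=duration,
    )


def sample_track(
    track: ToneTrack,
    interval: float = 60.0,
    t0: float = 0.0,
    snap_s: float = 2.0,
) -> list[ToneSample]:
    """Sample a track on a fixed cadence (default every 60 s).

    Each grid point ``t0 + k * interval`` inside the recording takes the
    nearest tracked frame within ``snap_s`` seconds, or is marked absent.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    samples: list[ToneSample] = []
    t = t0
    while t < track.duration:
        f0: float | None = None
        amp: float | None = None
        if not track.empty:
            i = int(np.clip(np.searchsorted(track.times, t), 0, len(track) - 1))
            if i > 0 and abs(track.times[i - 1] - t) < abs(track.times[i] - t):
                i -= 1
            if abs(track.times[i] - t) <= snap_s:
                f0 = float(track.f0[i])
                amp = float(track.amp[i])
        period = swarm_period_of(t) if t < 3600.0 else SwarmPeriod.LATE
        samples.append(ToneSample(t=t, f0=f0, amp=amp, band=track.band, period=period))
        t += interval
    return samples


def bin_by_period(samples: list[ToneSample]) -> dict[SwarmPeriod, list[ToneSample]]:
    """Partition samples by swarm period; all four bins are always present."""
    bins: dict[SwarmPeriod, list[ToneSample]] = {p: [] for p in _PERIOD_ORDER}
    for s in samples:
        bins[s.period].append(s)
    return bins


def mark_interacting(
    samples: list[ToneSample], spans: list[tuple[float, float]]
) -> list[ToneSample]:
    """Return samples with ``interacting=True`` where t falls in any span."""
    out = []
    for s in samples:
        flag = any(lo <= s.t < hi for lo, hi in spans)
        out.append(replace(s, interacting=flag) if flag != s.interacting else s)
    return out
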