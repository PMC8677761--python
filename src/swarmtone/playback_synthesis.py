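"""Artificial swarm-tone playback stimuli.

The standard 1-h stimulus is 15 min of silence followed by 45 min of
alternating 5 s tone periods: female stimuli alternate a 550 Hz baseline
swarm tone with a 600 Hz mating-interaction tone, male stimuli 850 with
900 Hz.  Each tone is a sine fundamental with stacked harmonic overtones
(F2-F5 / M2-M5 by default), rendered phase-continuously within a period
with short raised-cosine ramps at period boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .audio_core import AudioClip, Spectrogram, peak_in_band
from .tone_tracking import Band

__all__ = [
    "PlaybackSchedule",
    "HarmonicStack",
    "SamplingPlan",
    "DEFAULT_TONES",
    "make_schedule",
    "count_periods",
    "render",
    "sampling_plan",
    "period_midpoints",
    "period_truth",
    "classify_periods",
]

#: (baseline_hz, interaction_hz) per stimulus sex
DEFAULT_TONES: dict[Band, tuple[float, float]] = {
    Band.FEMALE: (550.0, 600.0),
    Band.MALE: (850.0, 900.0),
}

#: raised-cosine ramp at each tone-period boundary (anti-click)
RAMP_S = 0.010
#: output peak level, dB re full scale
PEAK_DBFS = -3.0


@dataclass(frozen=True)
class PlaybackSchedule:
    """Deterministic playback timeline: silence then alternating tone periods.

    Alternation starts with the baseline tone.  ``alternating_s`` must be
    an integer multiple of ``period_s``.
    """

    baseline_hz: float
    interaction_hz: float
    silence_s: float = 900.0
    alternating_s: float = 2700.0
    period_s: float = 5.0
    n_harmonics: int = 5

    def __post_init__(self) -> None:
        if self.baseline_hz <= 0 or self.interaction_hz <= 0:
            raise ValueError("tone frequencies must be positive")
        if self.silence_s < 0 or self.alternating_s < 0:
            raise ValueError("durations must be non-negative")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        ratio = self.alternating_s / self.period_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("alternating_s must be divisible by period_s")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")

    @property
    def n_periods(self) -> int:
        return int(round(self.alternating_s / self.period_s))

    @property
    def total_duration(self) -> float:
        return self.silence_s + self.alternating_s


def make_schedule(sex: Band, **overrides) -> PlaybackSchedule:
    """Canonical 1-h schedule for one stimulus sex, with optional overrides."""
    baseline, interaction = DEFAULT_TONES[sex]
    params = dict(baseline_hz=baseline, interaction_hz=interaction)
    params.update(overrides)
    return PlaybackSchedule(**params)


def count_periods(schedule: PlaybackSchedule) -> tuple[int, int]:
    """(n_baseline, n_interaction) tone periods; alternation starts baseline."""
    n = schedule.n_periods
    return (n + 1) // 2, n // 2


@dataclass(frozen=True)
class HarmonicStack:
    """Amplitude multipliers for overtones 1..n (weight 1 at the fundamental)."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.weights or abs(self.weights[0] - 1.0) > 1e-12:
            raise ValueError("fundamental weight must be 1")
        if any(not 0.0 <= w <= 1.0 for w in self.weights):
            raise ValueError("weights must lie in [0, 1]")

    @classmethod
    def rolloff(cls, n_harmonics: int) -> "HarmonicStack":
        """Default 1/k amplitude rolloff over k = 1..n_harmonics."""
        return cls(tuple(1.0 / k for k in range(1, n_harmonics + 1)))


def _tone_period(
    f: float, weights: tuple[float, ...], n_samples: int, sample_rate: int
) -> np.ndarray:
    t = np.arange(n_samples) / sample_rate
    sig = np.zeros(n_samples)
    for k, w in enumerate(weights, start=1):
        sig += w * np.sin(2.0 * np.pi * k * f * t)
    ramp_n = min(int(RAMP_S * sample_rate), n_samples // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        sig[:ramp_n] *= ramp
        sig[-ramp_n:] *= ramp[::-1]
    return sig


def render(
    schedule: PlaybackSchedule,
    stack: HarmonicStack | None = None,
    sample_rate: int = 44100,
) -> AudioClip:
    """Render a schedule to audio: exact silence, then alternating tone periods.

    Tone periods are phase-continuous internally (phase resets at period
    boundaries) and the output is peak-normalized to -3 dBFS.
    """
    if stack is None:
        stack = HarmonicStack.rolloff(schedule.n_harmonics)
    weights = stack.weights[: schedule.n_harmonics]
    top = len(weights) * max(schedule.baseline_hz, schedule.interaction_hz)
    if top >= sample_rate / 2.0:
        raise ValueError(
            f"highest overtone {top:.0f} Hz aliases at sample rate {sample_rate}"
        )
    n_silence = int(round(schedule.silence_s * sample_rate))
    n_period = int(round(schedule.period_s * sample_rate))
    n_periods = schedule.n_periods

    base = _tone_period(schedule.baseline_hz, weights, n_period, sample_rate)
    inter = _tone_period(schedule.interaction_hz, weights, n_period, sample_rate)
    alternation = np.empty((n_periods, n_period))
    alternation[0::2] = base
    alternation[1::2] = inter
    sig = np.concatenate([np.zeros(n_silence), alternation.ravel()])
    peak = np.max(np.abs(sig)) if sig.size else 0.0
    if peak > 0:
        sig *= 10.0 ** (PEAK_DBFS / 20.0) / peak
    return AudioClip(sig.astype(np.float32), sample_rate)


class SamplingPlan(NamedTuple):
    """Scheduled measurement counts for the playback protocol."""

    tone_samples_per_trial: int
    period_assays_per_trial: int
    tone_samples_total: int
    period_assays_total: int


def sampling_plan(schedule: PlaybackSchedule, n_trials: int = 3) -> SamplingPlan:
    """Measurement counts: one tone sample per minute of silence, two per
    minute of alternation (one per tone type), plus a presence/absence
    assay at every tone period."""
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    per_trial = int(schedule.silence_s // 60) + 2 * int(schedule.alternating_s // 60)
    assays = schedule.n_periods
    return SamplingPlan(
        tone_samples_per_trial=per_trial if n_trials else 0,
        period_assays_per_trial=assays if n_trials else 0,
        tone_samples_total=per_trial * n_trials,
        period_assays_total=assays * n_trials,
    )


# ---------------------------------------------------------------------------
# round-trip verification helpers
# ---------------------------------------------------------------------------


def period_midpoints(schedule: PlaybackSchedule) -> np.ndarray:
    """Midpoint time of each alternating tone period (seconds)."""
    idx = np.arange(schedule.n_periods)
    return schedule.silence_s + (idx + 0.5) * schedule.period_s


def period_truth(schedule: PlaybackSchedule) -> np.ndarray:
    """True fundamental of each tone period (baseline first)."""
    idx = np.arange(schedule.n_periods)
    return np.where(idx % 2 == 0, schedule.baseline_hz, schedule.interaction_hz)


def classify_periods(
    spec: Spectrogram,
    schedule: PlaybackSchedule,
    band: tuple[float, float] | None = None,
):
    """Measure the fundamental at each period midpoint and assign the nearest
    scheduled tone.

    Returns a DataFrame with measured ``f0``, the scheduled ``truth_hz``,
    the ``assigned_hz`` nearest tone, and per-period correctness.
    """
    import pandas as pd

    if band is None:
        lo = 0.8 * min(schedule.baseline_hz, schedule.interaction_hz)
        hi = 1.2 * max(schedule.baseline_hz, schedule.interaction_hz)
        band = (lo, hi)
    mids = period_midpoints(schedule)
    truth = period_truth(schedule)
    rows = []
    tones = np.array([schedule.baseline_hz, schedule.interaction_hz])
    for i, (t, ft) in enumerate(zip(mids, truth)):
        peak = peak_in_band(spec, t, band)
        f0 = peak[0] if peak is not None else np.nan
        assigned = tones[np.argmin(np.abs(tones - f0))] if np.isfinite(f0) else np.nan
        rows.append(
            dict(
                period_index=i,
                t_mid=t,
                truth_hz=ft,
                f0=f0,
                assigned_hz=assigned,
                correct=bool(np.isfinite(f0) and assigned == ft),
            )
        )
    return pd.DataFrame(rows)
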