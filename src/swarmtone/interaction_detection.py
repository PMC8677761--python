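"""Detection and phase segmentation of mating-interaction tones.

A male tone counts as a mating-interaction tone only when it meets all
three criteria simultaneously: (1) a >= 25 Hz frequency rise relative to
the background swarming-male frequency, (2) a >= 10 dB amplitude rise
relative to background male tones, and (3) rapid frequency modulation
(RFM), the turbulent wingbeat signature of mating-attempt flight.

Background is the running median of the male track over a +/- 10 s window
with candidate (excursion) frames excluded.  RFM is quantified as the
standard deviation of the tracked fundamental over a short sliding window
(>= 15 Hz over 0.5 s by default) -- the field describes the behavior
qualitatively, so the threshold is the pivotal free parameter here and is
fully configurable.

Criteria-passing runs are merged across sub-0.25 s dropouts (the FM
trough of a strongly modulated tone periodically dips below the frequency
criterion), runs shorter than 0.5 s are discarded, and nearby runs are
grouped into multi-segment interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .tone_tracking import ToneTrack

__all__ = [
    "InteractionEvent",
    "BackgroundStats",
    "Phase",
    "Mode",
    "background_stats",
    "is_rapid_fm",
    "detect_events",
    "segment_phases",
    "first_segment_near",
]


class Phase(Enum):
    EARLY = "early"
    LATE = "late"
    BEFORE = "before"
    DURING = "during"


class Mode(Enum):
    """Phase-segmentation convention: mixed-sex halves or playback before/during."""

    MIXED = "mixed"
    PLAYBACK = "playback"


@dataclass
class InteractionEvent:
    """One detected mating-interaction tone segment.

    ``times``/``f0``/``amp`` hold the tracked frames inside the segment.
    ``interaction_id`` groups segments belonging to one multi-segment
    interaction; ``segment_index`` is the ordinal within that group.
    ``phase_points`` is filled by :func:`segment_phases`.
    """

    onset: float
    offset: float
    interaction_id: int
    segment_index: int
    peak_f0: float
    peak_amp: float
    times: np.ndarray
    f0: np.ndarray
    amp: np.ndarray
    phase_points: dict[Phase, list[tuple[float, float, float]]] | None = None
    low_resolution: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class BackgroundStats:
    """Median background frequency/amplitude of the swarming-male chorus."""

    f_bg: float
    a_bg: float
    window: float


def _in_excluded(times: np.ndarray, exclude) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for lo, hi in exclude:
        mask |= (times >= lo) & (times < hi)
    return mask


def background_stats(
    track: ToneTrack,
    t: float,
    window: float = 20.0,
    exclude: list[tuple[float, float]] = (),
) -> BackgroundStats:
    """Median f0/amp of non-candidate frames within ``t +/- window/2``.

    ``exclude`` lists candidate (interaction) spans to leave out.  Raises
    if fewer than 5 background frames remain ("no background").
    """
    lo, hi = t - window / 2.0, t + window / 2.0
    sel = (track.times >= lo) & (track.times <= hi)
    sel &= ~_in_excluded(track.times, exclude)
    if np.count_nonzero(sel) < 5:
        raise ValueError("no background: fewer than 5 non-candidate frames in window")
    return BackgroundStats(
        f_bg=float(np.median(track.f0[sel])),
        a_bg=float(np.median(track.amp[sel])),
        window=window,
    )


def is_rapid_fm(
    track: ToneTrack,
    t: float,
    fm_window: float = 0.5,
    fm_sd_min: float = 15.0,
) -> bool:
    """True when the tracked f0 SD within ``t +/- fm_window/2`` is >= threshold.

    Fewer than 4 frames in the window yields False (not assayable).
    """
    sel = np.abs(track.times - t) <= fm_window / 2.0
    if np.count_nonzero(sel) < 4:
        return False
    return float(np.std(track.f0[sel])) >= fm_sd_min


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) inclusive index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def detect_events(
    track: ToneTrack,
    df_min: float = 25.0,
    da_min: float = 10.0,
    min_duration: float = 0.5,
    gap_merge_s: float = 0.25,
    bg_window_s: float = 20.0,
    fm_window_s: float = 0.5,
    fm_sd_min: float = 15.0,
    segment_gap_s: float = 1.0,
) -> list[InteractionEvent]:
    """Find maximal frame runs meeting all three interaction criteria.

    Two background passes are used: a first pass flags frequency/amplitude
    excursion candidates against the plain running median, then the
    background is re-estimated with candidates excluded so that long or
    frequent interactions do not inflate their own reference.  Runs are
    merged across gaps shorter than ``gap_merge_s``, dropped when shorter
    than ``min_duration``, and grouped into interactions when separated by
    at most ``segment_gap_s``.
    """
    if track.empty:
        return []
    dt = track.frame_dt
    n = track.n_frames
    idx = np.round((track.times - track.grid_t0) / dt).astype(np.int64)
    f_full = np.full(n, np.nan)
    a_full = np.full(n, np.nan)
    f_full[idx] = track.f0
    a_full[idx] = track.amp

    win_bg = max(5, int(round(bg_window_s / dt)) | 1)
    win_fm = max(4, int(round(fm_window_s / dt)))
    fs = pd.Series(f_full)
    as_ = pd.Series(a_full)

    # sustained excursion: a short median strips the FM oscillation so the
    # frequency criterion reads the tone's overall rise, not its FM crests
    f_exc = fs.rolling(win_fm, center=True, min_periods=2).median()
    a_exc = as_.rolling(win_fm, center=True, min_periods=2).median()

    med_f = fs.rolling(win_bg, center=True, min_periods=5).median()
    med_a = as_.rolling(win_bg, center=True, min_periods=5).median()
    cand = ((f_exc - med_f >= df_min) & (a_exc - med_a >= da_min)).to_numpy()

    f_bg = fs.mask(cand).rolling(win_bg, center=True, min_periods=5).median()
    a_bg = as_.mask(cand).rolling(win_bg, center=True, min_periods=5).median()
    fm_sd = fs.rolling(win_fm, center=True, min_periods=4).std(ddof=0)

    crit = (
        (f_exc - f_bg >= df_min) & (a_exc - a_bg >= da_min) & (fm_sd >= fm_sd_min)
    ).to_numpy()
    crit &= np.isfinite(f_full)

    runs = _runs(crit)
    if not runs:
        return []

    # merge runs across short gaps
    gap_frames = int(round(gap_merge_s / dt))
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 < gap_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # duration filter, then group into interactions
    kept = [(s, e) for s, e in merged if (e - s + 1) * dt >= min_duration - 1e-9]
    events: list[InteractionEvent] = []
    interaction_id = -1
    prev_offset = None
    seg_index = 0
    for s, e in kept:
        onset = track.grid_t0 + s * dt
        offset = track.grid_t0 + (e + 1) * dt
        if prev_offset is None or onset - prev_offset > segment_gap_s:
            interaction_id += 1
            seg_index = 0
        else:
            seg_index += 1
        prev_offset = offset
        sel = (idx >= s) & (idx <= e)
        t_run, f_run, a_run = track.times[sel], track.f0[sel], track.amp[sel]
        events.append(
            InteractionEvent(
                onset=onset,
                offset=offset,
                interaction_id=interaction_id,
                segment_index=seg_index,
                peak_f0=float(f_run.max()),
                peak_amp=float(a_run.max()),
                times=t_run,
                f0=f_run,
                amp=a_run,
            )
        )
    return events


def _phase_points(
    t_src: np.ndarray,
    f_src: np.ndarray,
    a_src: np.ndarray,
    span: tuple[float, float],
) -> tuple[list[tuple[float, float, float]], bool]:
    """Three (t, f0, amp) triplets at 10/50/90% of a phase span.

    Duplicates the nearest available frame when the phase is too short for
    three distinct frames; the second return flags that condition.
    """
    lo, hi = span
    targets = [lo + frac * (hi - lo) for frac in (0.1, 0.5, 0.9)]
    pts = []
    used = set()
    for target in targets:
        if t_src.size == 0:
            return [], True
        i = int(np.argmin(np.abs(t_src - target)))
        used.add(i)
        pts.append((float(t_src[i]), float(f_src[i]), float(a_src[i])))
    return pts, len(used) < 3


def segment_phases(
    event: InteractionEvent,
    mode: Mode,
    track: ToneTrack | None = None,
    drop_trim_max_s: float = 0.2,
    before_s: float = 1.5,
) -> InteractionEvent:
    """Attach three-point phase samples to an event (in place; returns it).

    MIXED mode splits the interaction into early/late halves after
    trimming ``min(0.2 s, 10% of duration)`` from the end (tones emitted
    as the couple drops out of flight are excluded).  PLAYBACK mode
    samples a 1.5 s background window immediately before onset (requires
    ``track`` for the pre-onset frames) and the full interaction span.
    """
    trim = min(drop_trim_max_s, 0.1 * event.duration)
    end = event.offset - trim
    low_res = False
    points: dict[Phase, list[tuple[float, float, float]]] = {}
    if mode is Mode.MIXED:
        mid = (event.onset + end) / 2.0
        spans = {Phase.EARLY: (event.onset, mid), Phase.LATE: (mid, end)}
        for phase, span in spans.items():
            sel = (event.times >= span[0] - 1e-9) & (event.times <= span[1] + 1e-9)
            pts, lr = _phase_points(
                event.times[sel], event.f0[sel], event.amp[sel], span
            )
            points[phase] = pts
            low_res |= lr
    elif mode is Mode.PLAYBACK:
        if track is None:
            raise ValueError("PLAYBACK mode requires the male track for BEFORE frames")
        before_span = (event.onset - before_s, event.onset)
        sel = (track.times >= before_span[0]) & (track.times < event.onset)
        pts, lr = _phase_points(
            track.times[sel], track.f0[sel], track.amp[sel], before_span
        )
        points[Phase.BEFORE] = pts
        low_res |= lr
        during_span = (event.onset, end)
        sel = (event.times >= event.onset) & (event.times <= end + 1e-9)
        pts, lr = _phase_points(
            event.times[sel], event.f0[sel], event.amp[sel], during_span
        )
        points[Phase.DURING] = pts
        low_res |= lr
    else:  # pragma: no cover
        raise ValueError(f"unknown mode {mode}")
    event.phase_points = points
    event.low_resolution = low_res
    return event


def first_segment_near(
    events: list[InteractionEvent],
    t: float,
    max_dist_s: float = 150.0,
) -> InteractionEvent | None:
    """First segment of the interaction temporally closest to ``t``.

    Distance is measured to the interaction's full span (zero when ``t``
    falls inside it); returns ``None`` when no interaction lies within
    ``max_dist_s``.
    """
    if not events:
        return None
    groups: dict[int, list[InteractionEvent]] = {}
    for ev in events:
        groups.setdefault(ev.interaction_id, []).append(ev)
    best_id, best_dist = None, np.inf
    for gid, segs in groups.items():
        lo = min(s.onset for s in segs)
        hi = max(s.offset for s in segs)
        dist = 0.0 if lo <= t <= hi else min(abs(t - lo), abs(t - hi))
        if dist < best_dist:
            best_id, best_dist = gid, dist
    if best_id is None or best_dist > max_dist_s:
        return None
    first = min(groups[best_id], key=lambda s: s.segment_index)
    return first
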