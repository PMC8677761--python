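"""Contingency statistics and run-report assembly.

Implements the tests used to summarize swarm-acoustics tabulations --
chi-square goodness of fit with equal expected probabilities, the
continuity-corrected 2x2 chi-square, the two-sided Fisher exact test
(minimum-likelihood rule), and Benjamini-Hochberg adjustment -- plus the
pipeline driver that turns a recording into tracks, events, cadence
samples, interaction scenarios, and report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .audio_core import AudioClip, build_noise_profile, compute_spectrogram, subtract_noise
from .harmonic_analysis import (
    DiffCategory,
    MixedScenario,
    phase_category,
    scenario_mixed,
)
from .interaction_detection import (
    InteractionEvent,
    Mode,
    Phase,
    detect_events,
    first_segment_near,
    segment_phases,
)
from .tone_tracking import (
    Band,
    SwarmPeriod,
    ToneSample,
    ToneTrack,
    bin_by_period,
    mark_interacting,
    sample_track,
    swarm_period_of,
    track_band,
)

__all__ = [
    "ContingencyTable",
    "GofInput",
    "chisq_gof",
    "chisq_2x2_corrected",
    "fisher_exact",
    "bh_adjust",
    "analyze_recording",
    "RunResult",
    "Report",
    "build_report",
    "period_frame_medians",
    "mixed_sampling_times",
]


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled 2x2 table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, 2):
            raise ValueError("ContingencyTable must be 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("at least one count must be positive")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class GofInput:
    """Observed counts and expected probabilities for a goodness-of-fit test."""

    observed: np.ndarray
    expected_probs: np.ndarray

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=np.int64)
        probs = np.asarray(self.expected_probs, dtype=np.float64)
        if obs.size < 2 or obs.size != probs.size:
            raise ValueError("need k >= 2 matching observed counts and probabilities")
        if np.any(obs < 0):
            raise ValueError("observed counts must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("expected probabilities must sum to 1")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "expected_probs", probs)

    @classmethod
    def equal_probs(cls, observed) -> "GofInput":
        observed = np.asarray(observed)
        k = observed.size
        return cls(observed, np.full(k, 1.0 / k))


def chisq_gof(inp: GofInput) -> tuple[float, int]:
    """Pearson goodness-of-fit statistic and df (no continuity correction)."""
    total = inp.observed.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    expected = total * inp.expected_probs
    if np.any(expected <= 0):
        raise ValueError("expected cell count of zero")
    res = _sps.chisquare(inp.observed, expected)
    return float(res.statistic), inp.observed.size - 1


def chisq_2x2_corrected(table: ContingencyTable) -> float:
    """Yates continuity-corrected chi-square on a 2x2 table."""
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = _sps.chi2_contingency(counts, correction=True)
    return float(res.statistic)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (sum of tables no more likely than observed)."""
    if table.counts.sum() > 10**6:
        raise ValueError("table too large for exact computation")
    return float(_sps.fisher_exact(table.counts).pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.asarray(_sps.false_discovery_control(p, method="bh"))


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def mixed_sampling_times() -> list[float]:
    """Interaction sampling grid: every 5 min from 15 to 60 min (10 points)."""
    return [900.0 + 300.0 * k for k in range(10)]


@dataclass
class RunResult:
    """Everything the analysis pipeline extracted from one recording."""

    male_track: ToneTrack
    female_track: ToneTrack
    events: list[InteractionEvent]
    male_samples: list[ToneSample]
    female_samples: list[ToneSample]
    interactions: pd.DataFrame | None
    duration: float


def analyze_recording(
    clip: AudioClip,
    denoise: bool = True,
    noise_profile_s: float = 10.0,
    window_s: float = 0.0929,
    overlap: float = 0.75,
    fmax: float = 1200.0,
    detect: bool = True,
    sample_interval: float = 60.0,
    mixed_sampling: bool = True,
) -> RunResult:
    """Run the full analysis chain on one swarm recording.

    Optionally denoises against a profile built from the silent lead-in,
    computes the shared spectrogram, tracks both sex bands, detects
    mating-interaction events in the male track, samples both tracks on
    the standard cadence, and (for recordings long enough) classifies
    interactions at the 5-min sampling grid into outcome scenarios.
    """
    work = clip
    if denoise and clip.duration > noise_profile_s + 1.0:
        lead = AudioClip(
            clip.samples[: int(noise_profile_s * clip.sample_rate)], clip.sample_rate
        )
        profile = build_noise_profile(lead, window_s=window_s, overlap=0.5)
        work = subtract_noise(clip, profile)

    spec = compute_spectrogram(work, window_s=window_s, overlap=overlap, fmax=fmax)
    male_track = track_band(spec, Band.MALE)
    female_track = track_band(spec, Band.FEMALE)
    del spec

    events = detect_events(male_track) if detect else []
    spans = [(e.onset, e.offset) for e in events]
    male_samples = mark_interacting(
        sample_track(male_track, interval=sample_interval), spans
    )
    female_samples = mark_interacting(
        sample_track(female_track, interval=sample_interval), spans
    )

    interactions = None
    if mixed_sampling and clip.duration >= 1200.0:
        interactions = _classify_interactions(male_track, female_track, events, clip.duration)

    return RunResult(
        male_track=male_track,
        female_track=female_track,
        events=events,
        male_samples=male_samples,
        female_samples=female_samples,
        interactions=interactions,
        duration=clip.duration,
    )


def _female_f0_at(track: ToneTrack, t: float, snap_s: float = 2.0) -> float | None:
    if track.empty:
        return None
    i = int(np.clip(np.searchsorted(track.times, t), 0, len(track) - 1))
    if i > 0 and abs(track.times[i - 1] - t) < abs(track.times[i] - t):
        i -= 1
    if abs(track.times[i] - t) > snap_s:
        return None
    return float(track.f0[i])


def _classify_interactions(
    male_track: ToneTrack,
    female_track: ToneTrack,
    events: list[InteractionEvent],
    duration: float,
) -> pd.DataFrame:
    """Scenario classification at each 5-min sampling point."""
    rows = []
    for t in mixed_sampling_times():
        if t > duration:
            continue
        period = swarm_period_of(min(t, 3599.999))
        ev = first_segment_near(events, t)
        if ev is None:
            rows.append(
                dict(
                    t=t,
                    period=period.value,
                    onset=np.nan,
                    early_cat=None,
                    late_cat=None,
                    ratio=None,
                    scenario=MixedScenario.NONE_GT50.name,
                    low_resolution=False,
                )
            )
            continue
        segment_phases(ev, Mode.MIXED)
        cats: dict[Phase, DiffCategory | None] = {}
        best_ratio = None
        best_diff = np.inf
        for phase in (Phase.EARLY, Phase.LATE):
            pts = ev.phase_points.get(phase, []) if ev.phase_points else []
            pairs = [(f0, _female_f0_at(female_track, t_pt)) for t_pt, f0, _ in pts]
            out = phase_category(pairs)
            cats[phase] = out.category if out is not None else None
            if out is not None and out.diff < best_diff:
                best_diff, best_ratio = out.diff, out.ratio
        scen = scenario_mixed(cats[Phase.EARLY], cats[Phase.LATE])
        rows.append(
            dict(
                t=t,
                period=period.value,
                onset=ev.onset,
                early_cat=cats[Phase.EARLY].name if cats[Phase.EARLY] else None,
                late_cat=cats[Phase.LATE].name if cats[Phase.LATE] else None,
                ratio=best_ratio.name if best_ratio is not None else None,
                scenario=scen.name,
                low_resolution=ev.low_resolution,
            )
        )
    return pd.DataFrame(rows)


def period_frame_medians(
    track: ToneTrack, events: list[InteractionEvent] = ()
) -> dict[SwarmPeriod, float]:
    """Per-period median tracked f0, excluding frames inside interactions.

    Frame-level medians are far more precise than the 60 s cadence for
    recovering the period trajectory, and excluding interaction frames
    keeps the baseline estimate free of excursion bias.
    """
    if track.empty:
        return {}
    mask = np.ones(track.times.size, dtype=bool)
    for ev in events:
        mask &= ~((track.times >= ev.onset) & (track.times < ev.offset))
    out: dict[SwarmPeriod, float] = {}
    for p in SwarmPeriod:
        lo, hi = {
            SwarmPeriod.PRE: (0.0, 900.0),
            SwarmPeriod.PEAK: (900.0, 1800.0),
            SwarmPeriod.WANING: (1800.0, 2700.0),
            SwarmPeriod.LATE: (2700.0, 3600.0),
        }[p]
        sel = mask & (track.times >= lo) & (track.times < hi)
        if np.count_nonzero(sel):
            out[p] = float(np.median(track.f0[sel]))
    return out


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class Report:
    """Tabular summary of one analyzed recording."""

    period_summary: pd.DataFrame
    event_counts: pd.DataFrame
    scenario_counts: pd.DataFrame | None
    statistics: dict[str, float]
    gaps: list[str] = field(default_factory=list)

    def text(self) -> str:
        lines = ["swarmtone run report", "=" * 40, "", "Per-period tone summary:"]
        lines.append(self.period_summary.to_string(index=False))
        lines += ["", "Interaction events per period:"]
        lines.append(self.event_counts.to_string(index=False))
        if self.scenario_counts is not None:
            lines += ["", "Harmonic outcome scenarios:"]
            lines.append(self.scenario_counts.to_string(index=False))
        if self.statistics:
            lines += ["", "Statistics:"]
            for k, v in self.statistics.items():
                lines.append(f"  {k} = {v:.4g}")
        for gap in self.gaps:
            lines.append(f"  [missing] {gap}")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.period_summary.to_csv(out / "period_summary.csv", index=False)
        self.event_counts.to_csv(out / "event_counts.csv", index=False)
        if self.scenario_counts is not None:
            self.scenario_counts.to_csv(out / "scenario_counts.csv", index=False)
        (out / "report.txt").write_text(self.text() + "\n")


def _summarize_samples(samples: list[ToneSample], band: Band) -> list[dict]:
    rows = []
    for period, group in bin_by_period(samples).items():
        f0s = [s.f0 for s in group if not s.absent]
        amps = [s.amp for s in group if not s.absent]
        rows.append(
            dict(
                band=band.value,
                period=period.value,
                n_samples=len(group),
                n_present=len(f0s),
                mean_f0=float(np.mean(f0s)) if f0s else np.nan,
                sd_f0=float(np.std(f0s, ddof=1)) if len(f0s) > 1 else np.nan,
                mean_amp=float(np.mean(amps)) if amps else np.nan,
            )
        )
    return rows


def build_report(result: RunResult, out_dir=None) -> Report:
    """Assemble per-period summaries, event counts, scenario tabulations and
    the statistics block from a pipeline run."""
    gaps: list[str] = []
    period_summary = pd.DataFrame(
        _summarize_samples(result.male_samples, Band.MALE)
        + _summarize_samples(result.female_samples, Band.FEMALE)
    )

    counts = {p.value: 0 for p in SwarmPeriod}
    for ev in result.events:
        if 0.0 <= ev.onset < 3600.0:
            counts[swarm_period_of(ev.onset).value] += 1
    event_counts = pd.DataFrame(
        [dict(period=k, n_events=v) for k, v in counts.items()]
    )

    statistics: dict[str, float] = {}
    scenario_counts = None
    if result.interactions is not None:
        order = [s.name for s in MixedScenario]
        tally = result.interactions["scenario"].value_counts()
        scenario_counts = pd.DataFrame(
            [dict(scenario=name, n=int(tally.get(name, 0))) for name in order]
        )
        observed = scenario_counts["n"].to_numpy()
        if observed.sum() > 0:
            stat, df = chisq_gof(GofInput.equal_probs(observed))
            statistics["scenario_gof_chisq"] = stat
            statistics["scenario_gof_df"] = df
        early_yes = int(
            (result.interactions["early_cat"].notna()
             & (result.interactions["early_cat"] != "GT50")).sum()
        )
        late_yes = int(
            (result.interactions["late_cat"].notna()
             & (result.interactions["late_cat"] != "GT50")).sum()
        )
        n_int = len(result.interactions)
        if n_int and (early_yes or late_yes) and (early_yes < n_int or late_yes < n_int):
            table = ContingencyTable(
                np.array([[early_yes, n_int - early_yes], [late_yes, n_int - late_yes]]),
                row_labels=("early", "late"),
                col_labels=("yes", "no"),
            )
            statistics["early_late_fisher_p"] = fisher_exact(table)
    else:
        gaps.append("interaction scenario table (recording too short or disabled)")

    report = Report(
        period_summary=period_summary,
        event_counts=event_counts,
        scenario_counts=scenario_counts,
        statistics=statistics,
        gaps=gaps,
    )
    if out_dir is not None:
        report.save(out_dir)
    return report
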