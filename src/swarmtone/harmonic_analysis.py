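"""Harmonic frequency differences, convergence categories, and outcome scenarios.

A male at fundamental ``m`` and a female at fundamental ``f`` are compared
at four harmonic ratios (M1:F2, M2:F3, M3:F4, M3:F5): the harmonic
difference at ratio (n, k) is ``|n*m - k*f|`` in Hz.  Differences are
classified into half-open bins [0,5), [5,10), [10,20), [20,50), [50,inf);
a difference below 5 Hz is harmonic convergence.  Mixed-sex interactions
are summarized by whether any sub-50 Hz difference was achieved in the
early and/or late interaction phase; playback interactions by a four-bit
achievement signature over {before, during} x {baseline tone, interaction
tone}.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple

__all__ = [
    "HarmonicRatio",
    "DiffCategory",
    "MixedScenario",
    "PlaybackOutcome",
    "RatioOutcome",
    "harmonic",
    "ratio_difference",
    "classify_difference",
    "best_outcome",
    "phase_category",
    "scenario_mixed",
    "scenario_playback",
    "rank_outcomes",
]


class HarmonicRatio(Enum):
    """Male:female overtone index pairs assayed for convergence."""

    M1F2 = (1, 2)
    M2F3 = (2, 3)
    M3F4 = (3, 4)
    M3F5 = (3, 5)

    @property
    def n_male(self) -> int:
        return self.value[0]

    @property
    def m_female(self) -> int:
        return self.value[1]


class DiffCategory(Enum):
    """Harmonic frequency-difference bins (Hz), half-open on the right.

    ``LT5`` is harmonic convergence; ``GT50`` means no sub-50 Hz
    difference was achieved.
    """

    LT5 = (0.0, 5.0)
    LT10 = (5.0, 10.0)
    LT20 = (10.0, 20.0)
    LT50 = (20.0, 50.0)
    GT50 = (50.0, float("inf"))

    @property
    def achieved(self) -> bool:
        """True for any sub-50 Hz difference category."""
        return self is not DiffCategory.GT50


class MixedScenario(Enum):
    """Phase-combination outcomes for mixed-sex mating interactions."""

    S1_BOTH = "both early and late"
    S2_EARLY_ONLY = "early only"
    S3_LATE_ONLY = "late only"
    NONE_GT50 = "> 50 Hz"


class RatioOutcome(NamedTuple):
    ratio: HarmonicRatio
    diff: float
    category: DiffCategory


def harmonic(f1: float, n: int) -> float:
    """The n-th harmonic of a fundamental: ``n * f1`` Hz."""
    if f1 <= 0:
        raise ValueError("fundamental must be positive")
    if n < 1:
        raise ValueError("harmonic index must be >= 1")
    return n * f1


def ratio_difference(male_f1: float, female_f1: float, ratio: HarmonicRatio) -> float:
    """Absolute harmonic frequency difference at one ratio (Hz)."""
    if male_f1 <= 0 or female_f1 <= 0:
        raise ValueError("fundamentals must be positive")
    return abs(ratio.n_male * male_f1 - ratio.m_female * female_f1)


def classify_difference(diff: float) -> DiffCategory:
    """Bin a non-negative harmonic difference; bins are half-open [lo, hi)."""
    if diff < 0:
        raise ValueError("difference must be non-negative")
    for cat in DiffCategory:
        lo, hi = cat.value
        if lo <= diff < hi:
            return cat
    return DiffCategory.GT50  # pragma: no cover - inf bin is exhaustive


def best_outcome(male_f1: float, female_f1: float) -> RatioOutcome:
    """Minimum-difference ratio for a fundamental pair (ties: enum order)."""
    best: RatioOutcome | None = None
    for ratio in HarmonicRatio:
        d = ratio_difference(male_f1, female_f1, ratio)
        if best is None or d < best.diff:
            best = RatioOutcome(ratio, d, classify_difference(d))
    assert best is not None
    return best


def phase_category(
    pairs: Iterable[tuple[float | None, float | None]],
) -> RatioOutcome | None:
    """Best outcome over a phase's sampled (male_f1, female_f1) pairs.

    Pairs with a missing fundamental are skipped; returns ``None`` when no
    valid pair exists (no tone to assay in this phase).
    """
    best: RatioOutcome | None = None
    for m, f in pairs:
        if m is None or f is None:
            continue
        out = best_outcome(m, f)
        if best is None or out.diff < best.diff:
            best = out
    return best


def scenario_mixed(
    early_cat: DiffCategory | None, late_cat: DiffCategory | None
) -> MixedScenario:
    """Combine early/late phase categories into a mixed-sex scenario.

    An absent phase (``None``, e.g. no interacting pair at the sampling
    point) counts as not achieved, so a fully absent interaction lands in
    the > 50 Hz scenario.
    """
    early = early_cat is not None and early_cat.achieved
    late = late_cat is not None and late_cat.achieved
    if early and late:
        return MixedScenario.S1_BOTH
    if early:
        return MixedScenario.S2_EARLY_ONLY
    if late:
        return MixedScenario.S3_LATE_ONLY
    return MixedScenario.NONE_GT50


@dataclass(frozen=True)
class PlaybackOutcome:
    """Achievement lattice cell for one playback mating interaction.

    Categories are recorded against the female baseline tone and the
    female interaction tone, both before and during the interaction; the
    four-bit ``signature`` (e.g. ``"1001"``) encodes which of the four
    comparisons achieved a sub-50 Hz difference.
    """

    before_vs_baseline: DiffCategory
    before_vs_interaction: DiffCategory
    during_vs_baseline: DiffCategory
    during_vs_interaction: DiffCategory

    @property
    def categories(self) -> tuple[DiffCategory, ...]:
        return (
            self.before_vs_baseline,
            self.before_vs_interaction,
            self.during_vs_baseline,
            self.during_vs_interaction,
        )

    @property
    def signature(self) -> str:
        return "".join("1" if c.achieved else "0" for c in self.categories)


def scenario_playback(
    before_vs_baseline: DiffCategory,
    before_vs_interaction: DiffCategory,
    during_vs_baseline: DiffCategory,
    during_vs_interaction: DiffCategory,
) -> PlaybackOutcome:
    """Place one playback interaction on the 16-cell achievement lattice."""
    return PlaybackOutcome(
        before_vs_baseline,
        before_vs_interaction,
        during_vs_baseline,
        during_vs_interaction,
    )


def rank_outcomes(outcomes: Iterable[PlaybackOutcome]) -> list[tuple[str, int]]:
    """Signature counts sorted from most to least common (ties: signature)."""
    counts = Counter(o.signature for o in outcomes)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
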