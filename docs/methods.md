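# Methods

This note documents the models, conventions and parameter choices behind
`swarmtone`, in the spirit of a statistics package's methods appendix:
what is computed, under what assumptions, and which knobs matter.

## Signal model and time-frequency analysis

A swarm recording is modelled as a sum of quasi-harmonic flight tones —
each flying mosquito contributes a fundamental (wingbeat frequency) with
integer overtones, males near 850 Hz with harmonics to M4, females near
550 Hz with harmonics to F5 — over broadband background noise.

All measurements are taken on a Hann-windowed magnitude spectrogram.
The default geometry is a window of `int(0.0929 s * sample_rate)`
samples (4096 at 44.1 kHz, 1024 at the simulator's 11.025 kHz), 75 %
overlap, and 4x zero-padding. Zero-padding refines bin spacing to
~2.7 Hz, and 3-point parabolic interpolation on the dB spectrum refines
peak frequencies well below a bin (measured error on clean tones:
< 0.01 Hz; the sub-5 Hz convergence category demands sub-5 Hz accuracy).
Frame count follows the no-padding convention `floor((N-W)/hop) + 1`, so
every frame covers real signal. Amplitudes are dB re digital full scale
(0 dBFS = amplitude 1.0); every downstream criterion is a *difference*
of levels, so the absolute calibration of microphone and amplifier
cancels and is not modelled.

**Peak gating.** A band peak counts as a tone only if it (a) rises at
least 12 dB above the band's median level, (b) exceeds an absolute floor
of −75 dBFS, and (c) does not sit on a band-edge bin. The relative gate
separates tones from broadband noise; empirically the peak-to-median
spread of pure noise across a few hundred (oversampled) Rayleigh bins is
8–9 dB, so a lower gate would hallucinate tones in empty bands. The
absolute floor rejects the window-leakage skirt of a strong out-of-band
tone, which in near-noiseless audio can pass the relative gate at
−90 dBFS; any real flyer near the microphone registers far above
−75 dBFS. All three gates are configurable.

**Noise reduction** is magnitude-domain spectral subtraction against a
profile (per-bin mean and SD of STFT magnitude) built from the 10 s
silent lead-in recorded before mosquitoes are added: each bin magnitude
is reduced by `over_subtraction * (mean + sd)` (default factor 1.0) and
floored at 2 % of the original magnitude; phase is untouched. This is a
standard textbook noise gate, not a bit-level reproduction of any
editor's effect. Measured on a −20 dBFS tone in white noise it improves
time-domain SNR by ~15 dB and removes ~98 % of pure-noise power.

## Tone tracking and swarm periods

Each sex band (male 700–1100 Hz, female 400–700 Hz, chosen around the
~850/~550 Hz baselines and configurable) yields one track: the per-frame
gated band peak. Jumps > 150 Hz between consecutive frames split the
track into segments (distinct flyers); the band separation itself is
what keeps male and female ridges from crossing. Tracks are sampled
every 60 s (nearest frame within ±2 s, else an "absent" marker) and
binned into the four swarm periods — pre-swarm 0–15 min (dusk), peak
15–30, waning 30–45, late 45–60 — with half-open boundaries, so
t = 900 s belongs to the peak period.

## Mating-interaction detection

A male tone is a mating-interaction tone when all three criteria hold
simultaneously:

1. frequency ≥ 25 Hz above the background male frequency,
2. amplitude ≥ 10 dB above the background male level,
3. rapid frequency modulation (RFM).

Background is the running median over a 20 s window, computed twice: a
first pass flags excursion candidates, a second pass re-estimates the
median with candidates excluded, so interactions do not inflate their
own reference. RFM — described in the field qualitatively as the
turbulent signature of mating-attempt flight — is quantified as the SD
of the tracked fundamental over a 0.5 s window, threshold 15 Hz. This
threshold is the pivotal free parameter of the detector: a ±40 Hz
sinusoidal FM gives an SD of ~28 Hz and passes comfortably, while OU
wingbeat drift over 0.5 s gives ~2 Hz. It is exposed as `fm_sd_min`.

Criteria 1–2 are evaluated on a 0.5 s rolling *median* of the track
(the sustained excursion): the superimposed FM swings the instantaneous
frequency ±40 Hz around the excursion, and reading the criterion on raw
frames would let a sub-threshold (+20 Hz) excursion pass on every FM
crest. Criterion 3 sees the raw frames.

Criteria-passing runs are merged across gaps < 0.25 s (FM troughs),
discarded below 0.5 s (free-flight interactions last ~1–2 s; shorter
blips are untrackable), and grouped into multi-segment interactions when
separated by ≤ 1 s. When interactions are sampled on the 5-min grid
(15–60 min, ten points), only the first segment of the temporally
closest interaction within ±150 s (half the sampling cadence) is
analyzed.

**Phases.** Mixed-sex interactions are split into early/late halves
after trimming `min(0.2 s, 10 % of duration)` from the end — the tones
emitted as the couple drops out of flight are excluded. Playback-mode
interactions get a BEFORE phase (the 1.5 s of background tones
immediately preceding onset) and a DURING phase (the interaction span).
Each phase is sampled at 10 %, 50 % and 90 % of its span, taking the
nearest tracked frame; if a phase holds fewer than three distinct
frames, the nearest frame is duplicated and the event is flagged
`low_resolution`.

## Harmonic analysis

Overtones are computed from fundamentals (`n * f1`), differences at the
four ratios M1:F2, M2:F3, M3:F4, M3:F5, and classified into half-open
bins [0,5), [5,10), [10,20), [20,50), [50,inf) Hz. The boundaries are
strict: exactly 5 Hz is not convergence, exactly 50 Hz is not an
achieved difference (the canonical 850/550 Hz baseline pair sits at
exactly 50 Hz at M2:F3 — a deliberate boundary case the tests pin down).
A phase's category is the category of the *minimum* difference across
its three sample points and all four ratios; either phase of an
interaction may achieve its difference at a different ratio. Mixed-sex
interactions collapse to four scenarios (both phases / early only / late
only / neither, with absent interactions counted as "neither"); playback
interactions occupy a 16-cell lattice keyed by the four-bit achievement
signature over {before, during} x {baseline tone, interaction tone},
ordered empirically by frequency. The twelve observed playback scenarios
of the motivating design are a subset of this lattice; the lattice makes
no claim about their labels.

## Playback synthesis

The artificial stimulus is 15 min of silence followed by 45 min of
alternating 5 s tone periods, baseline first (the alternation's starting
tone is unstated in the protocol; starting with baseline does not change
any count): female 550/600 Hz, male 850/900 Hz, five stacked overtones
with 1/k amplitude rolloff (the stack is fully configurable), phase
continuous within a period, 10 ms raised-cosine ramps at period
boundaries (anti-click; the protocol is silent on transitions), peak
normalized to −3 dBFS. Speaker calibration and frequency response are
out of scope. The canonical schedule yields 270 baseline + 270
interaction periods; the sampling plan is 15 silence samples + 90
alternation samples = 105 tone samples and 540 period assays per trial
(315 and 1620 over three trials).

## The simulator: what it emulates, and what it does not

`swarm_synth.simulate` renders per-individual harmonic tones. Each
individual's wingbeat is a mean-reverting Ornstein–Uhlenbeck trajectory
(stationary SD 15 Hz, reversion time 2 s — the simplest process giving
realistic, continuous spectrogram ridges) around a base frequency
(male 843 Hz, female 550 Hz) plus a static individual offset (SD 10 Hz)
and a per-period elevation (pre 0, peak +30, waning +10, late 0 Hz).
Individual levels are −35 dBFS (males) / −38 dBFS (females) with ±1.5 dB
static spread and a slow ±1.5 dB OU level modulation (5 s), so chorus
dominance rotates between individuals. Male participation follows the
observed swarm profile (14 / 58 / 43 / 31 % of individuals per period,
with at least one male kept airborne per period so the chorus is always
observable); females fly in intermittent 3–10 s offering-flight bouts at
a lower duty cycle. Background noise is Gaussian at −45 dBFS per sample,
and the first 10 s are mosquito-free for noise profiling.

Interaction events (frequency step + FM + amplitude step, raised-cosine
50 ms edges, 1.5–2.5 s duration) are synthesized *relative to the
measured chorus background*: the chorus is rendered first, its male-band
running median (frequency and level) is measured, and each event tone is
placed `df` Hz and `da` dB above that background at its onset. The
detection criteria are defined relatively, so injected margins of
+50 Hz / +15 dB then carry exactly the meaning the detector tests;
anchoring `da` to a single individual's level would make the realized
margin depend on chorus order statistics. Events are scheduled
non-overlapping (≥ 3.5 s onset spacing, allocated across periods in
proportion to per-period rates that peak during peak swarming), each
with a male and — in mixed swarms — a partner female whose flight bout
is forced to cover the event. Default event rates mirror the observed
mating-attempt time course; `n_events` overrides the total for
parameter-recovery experiments.

The simulator's default sample rate is 11.025 kHz: every simulated
component (M4 of the highest male excursion, F5 of females) stays well
below the 5.5 kHz Nyquist, at a quarter of the cost of CD-rate audio.
Playback rendering defaults to 44.1 kHz.

Not emulated: spatial acoustics, Doppler from flight paths, microphone
directivity, reverberation, couple drop-out amplitude dynamics, female
excursions during events, and non-Gaussian room noise. Passing
parameter-recovery tests on this simulator therefore demonstrates that
the pipeline's logic and thresholds are self-consistent at realistic
SNRs and chorus densities — not that the detector is robust to every
artifact of real cage recordings.

## Statistics

Goodness of fit uses the plain Pearson statistic with equal expected
probabilities (df = k−1, no continuity correction). The 2x2 chi-square
applies the Yates continuity correction (observed counts moved 0.5
toward expectation). Fisher's exact test is two-sided under the
minimum-likelihood rule: the p-value sums the probabilities of all
tables with the observed margins whose hypergeometric probability does
not exceed that of the observed table. The Benjamini–Hochberg adjustment
is the standard step-up procedure (monotone after sorting, capped at 1);
note that adjusted values are not fixed points of the procedure —
re-adjusting adjusted p-values inflates them further, which is why the
test suite checks dominance and rank-monotonicity rather than
idempotence. Repeated-measures ANOVA with post-hoc contrasts on real
recordings is deliberately left to general statistics packages.

## Problem sizes and numerical choices

Hour-long round trips run at full protocol scale: the playback check
classifies all 540 periods of the rendered 1-h stimulus, and the
parameter-recovery check simulates a full 1-h mixed swarm with 100
injected events at +50 Hz / +15 dB margins. Spectrograms are stored
band-cropped (default `fmax` 1200 Hz for tracking) in float32, computed
in 2048-frame chunks; dB conversion floors magnitudes at 1e-10
(−200 dB). Ties in `best_outcome` break by ratio enum order; degenerate
inputs (empty tracks, silent clips, zero-length schedules) return empty
results rather than raising wherever the operation is total.

## Known limitations

* The tracker follows one dominant ridge per band; simultaneous
  same-band tones (two interacting males) merge into whichever is
  louder.
* The RFM threshold (15 Hz SD over 0.5 s) is calibrated on the
  simulator's FM model; real recordings may need tuning.
* Difference categories are hard boundaries on measured frequencies;
  measurement error near a boundary (e.g. the exact-50 Hz baseline
  pair) flips categories, which is inherent to the taxonomy, not to
  this implementation.
* Absolute dB values are full-scale-relative; comparisons against
  sound-pressure-calibrated measurements require an external offset.
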