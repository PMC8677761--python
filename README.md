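# swarmtone

Flight-tone tracking and harmonic-convergence analysis for *Anopheles
gambiae* swarm audio.

Mating in *An. gambiae* happens in flight, in male-dominated swarms at
dusk. Males hold a collective flight tone near 850 Hz (fundamental M1,
harmonics to M4), females near 550 Hz (F1, harmonics to F5), and during a
mating attempt a male's tone jumps ~50 Hz up, ~10-20 dB louder, with
rapid frequency modulation (RFM). Courting pairs also *harmonize*: their
tones match at shared harmonics — at 900/600 Hz, the male second and
female third harmonics coincide at M2 = F3 = 1800 Hz. A harmonic
frequency difference below 5 Hz is called harmonic convergence; this
package also tracks the coarser <10, <20 and <50 Hz difference outcomes
used to characterize swarm-scale harmonization.

`swarmtone` is for bioacousticians and vector-biology groups who want to
run this analysis on their own cage recordings — or validate it end to
end without any recordings, using the built-in ground-truthed swarm
simulator.

## What it does

* **audio_core** — WAV I/O, spectral-subtraction noise reduction against
  a profile from a silent lead-in, Hann spectrograms with 4x zero-padded
  bins (~2.7 Hz), band-limited peak extraction with parabolic sub-bin
  refinement.
* **tone_tracking** — per-sex fundamental ridges (male 700–1100 Hz,
  female 400–700 Hz), 60 s cadence sampling, binning into the four
  15-min swarm periods (pre / peak / waning / late).
* **interaction_detection** — mating-interaction tones by the three
  criteria (≥25 Hz frequency rise and ≥10 dB amplitude rise vs. the
  running background median, plus RFM), early/late or before/during
  phase segmentation with three sample points per phase.
* **harmonic_analysis** — harmonic differences at the four ratios
  (M1:F2, M2:F3, M3:F4, M3:F5), half-open difference categories, and the
  mixed-sex (scenarios 1–3 / >50 Hz) and playback (16-cell achievement
  lattice) outcome taxonomies.
* **playback_synthesis** — the artificial stimulus: 15 min silence, then
  45 min of alternating 5 s periods of baseline vs. interaction tone
  (female 550/600 Hz, male 850/900 Hz) with stacked overtones; 270+270
  periods, 105 tone samples and 540 period assays per trial.
* **swarm_synth** — a seeded simulator producing swarm audio plus a
  ground-truth event log for parameter-recovery testing.
* **stats_report** — chi-square goodness of fit, Yates-corrected 2x2
  chi-square, two-sided Fisher's exact test, Benjamini–Hochberg
  adjustment, and report tables.

## Worked example

```python
import numpy as np
from swarmtone import (
    mixed_config, simulate, analyze_recording, build_report,
    harmonic, best_outcome,
)

# a 1-h mixed-sex swarm (30 males : 10 females) with 20 mating interactions
cfg = mixed_config(seed=7, n_events=20)
clip, truth = simulate(cfg)

result = analyze_recording(clip)
print(len(result.events), "interaction tones detected")
report = build_report(result)
print(report.period_summary[report.period_summary.band == "male"]
      [["period", "n_present", "mean_f0"]].to_string(index=False))
print(best_outcome(900.0, 600.0))
```

prints (seed 7):

```
15 interaction tones detected
period  n_present    mean_f0
   pre         15 852.616358
  peak         15 873.853513
waning         15 851.211397
  late         15 845.374728
RatioOutcome(ratio=<HarmonicRatio.M2F3: (2, 3)>, diff=0.0, category=<DiffCategory.LT5: (0.0, 5.0)>)
```

Reading the output: 15 of the 20 injected interactions are detected —
the default config draws amplitude excursions all the way down to the
+10 dB criterion threshold, and threshold-grazing events are (correctly)
not called; at a comfortable +15 dB margin detection is complete (see
the acceptance tests). The male chorus climaxes in the peak swarm period
(+21 Hz over pre-swarm in these 60 s cadence samples, from the +30 Hz
injected elevation) and decays through the waning and late periods. The
last line is the harmonic arithmetic: a 900 Hz male interaction tone
converges exactly (diff 0 < 5 Hz) with a 600 Hz female at the shared
M2 = F3 = 1800 Hz harmonic.

From the shell:

```sh
swarmtone simulate --preset mixed --seed 7 --out sim/
swarmtone playback --sex female --out playback.wav
swarmtone analyze sim/swarm.wav --report out/
```

## Documentation

See `docs/methods.md` for the underlying model, parameter choices, what
the simulator does and does not emulate, and known limitations.
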