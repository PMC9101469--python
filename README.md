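# fogcast

Freezing of gait (FOG) — the sudden, episodic inability to step despite the
intention to walk — is one of the most disabling motor symptoms of
Parkinson's disease. Because external cues (a rhythmic tone, a laser line)
can break or shorten a freeze, a wearable system that *predicts* an imminent
episode from a single plantar-pressure insole could trigger a cue before the
freeze takes hold. `fogcast` implements that analysis end to end as a tested
Python library: from per-foot ground-reaction-force (GRF) and
centre-of-pressure (COP) time series to episode-level cueing metrics, with a
synthetic gait generator standing in for clinical recordings, which cannot
be redistributed.

It is written for gait-analysis and digital-biomarker researchers who want a
reproducible reference implementation of this class of pipeline: every stage
is importable, unit-tested against independent oracles, and deterministic
under a master seed.

## The analysis

1. **Labeling and windowing.** Video-rate (30 Hz) FOG annotations are
   transferred to the 100 Hz pressure stream by nearest timestamp. The 2 s
   before each onset is labeled pre-FOG (gaps < 2 s between episodes merge
   into pre-FOG). Signals are cut into 1 s windows shifted by 0.2 s; a
   window is **target** iff it contains only pre-FOG and/or FOG samples —
   so a single binary model both predicts and detects freezes.
2. **Features (333).** Per foot and window, 166 features over 7 signals
   (GRF; COP position, velocity, acceleration in AP and ML): COP-path
   reversal and ML-deviation run statistics, coefficients of variation, an
   8-value FFT block per signal — total power, dominant frequency,
   amplitude extrema/mean, power in the locomotion band (0.5–3 Hz) and the
   freeze band (3–8 Hz), and the freeze index
   FI = P(3–8 Hz) / P(0.5–3 Hz) — and a 14-value single-level Haar wavelet
   block per signal. One bilateral feature (weight-shift count) completes
   166 + 166 + 1 = 333.
3. **Ranking and training.** Relief-F ranks features per cross-validation
   fold; RUSBoost — AdaBoost with per-iteration random undersampling of the
   majority class — combines 100 depth-limited trees (5 splits each).
   Models are trained on the top 5, 10, 15, 20, 25 and 30 features of the
   most-affected-side (MAS), least-affected-side (LAS) and bilateral
   datasets: an 18-cell grid under leave-one-freezer-out cross-validation
   (non-freezers always train, never test).
4. **Evaluation.** Window-level sensitivity/specificity, plus episode-level
   scoring: three consecutive target windows raise a *model trigger
   decision* (MTD) at the third window's end; a 2.5 s no-cue interval
   suppresses rapid-fire MTDs; each episode owns a target zone from 6 s
   before onset (truncated by prior freezes and by turn/stand ends + 1 s)
   through the episode end. Reported per participant: % episodes
   identified (EI), mean identification delay (ID; negative = before
   onset), and false positives per trial (FPR), with standing and
   gait-initiation false alarms ignored. The best model per dataset is the
   one with the smallest rank sum across the five metrics.

## Worked example

`examples/04_episode_scoring.py` scores a hand-made classification timeline
for one 30 s trial with a freeze at 19.5 s:

```
zone for episode at 19.5 s: (13.5, 23.0) | truncated by: none
  MTD at   3.8 s  -> false-positive
  MTD at  18.4 s  -> true-positive
  MTD at  18.6 s  -> suppressed
  ...
episodes identified: 100 %
identification delay: -1.1 s (negative = predicted before onset)
false positives/trial: 1.0
```

The spurious early run costs one false positive; the genuine pre-FOG run
fires 1.1 s before onset, identifying the episode in advance; every MTD
within 2.5 s of an accepted cue is suppressed by the no-cue filter. The
other examples cover trial simulation (`01`), the feature catalog (`02`),
Relief-F ranking (`03`) and the full reduced-scale experiment grid (`05`).

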