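# Methods

This note documents the models, conventions and design choices behind
`fogcast`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Signals and preprocessing

The pipeline consumes, per foot, total ground-reaction force (GRF) and
centre-of-pressure (COP) anterior–posterior (AP) and medial–lateral (ML)
coordinates at 100 Hz. Where raw pressure-cell grids are available,
`cop_from_pressure_grid` reduces them to the pressure-weighted centroid
(undefined, NaN, at zero total load).

* **Swing-phase zeroing.** A foot carrying strictly less than 5 % of the
  two-foot total GRF at a sample is set to zero — residual insole pressure
  during swing is noise, not load. The inequality is strict, so exactly 5 %
  is kept. The operation is idempotent.
* **COP of an unloaded foot** is held at its last valid value rather than
  zero-filled. Zero-filling would create a large artificial COP jump at
  every toe-off, which the reversal/deviation features would count as
  spurious path events. Last-valid-hold instead freezes the path; this is a
  modelling choice, and a known deviation risk if compared against systems
  that emit zeros.
* **Derivatives.** COP velocity and acceleration are central differences in
  the interior and one-sided differences at the ends (`numpy.gradient`).
  The differentiation scheme had to be fixed for oracle tests; central
  differences are exact for quadratics and introduce no phase shift.
* **Label transfer.** Annotations arrive at a video-like 30 Hz and are
  mapped to the 100 Hz clock by nearest frame timestamp; exact ties take
  the earlier frame (deterministic and order-independent). Pre-FOG labels
  cover the 2 s before each onset, clipped at the trial start; FOG labels
  are never overwritten, which automatically merges inter-episode gaps
  shorter than 2 s into pre-FOG.
* **Windows** are half-open sample intervals `[start, start + 1 s)` on a
  0.2 s grid, 0-based, so boundary samples are never double-counted. A
  window is *target* iff its label composition is {pre-FOG}, {pre-FOG, FOG}
  or {FOG}; any composition containing non-FOG is *non-target*.

## Feature catalog

166 features per foot plus one bilateral feature (333 total): per foot,
3 reversal features on AP COP, 3 deviation features on ML COP, 6
coefficients of variation, and an 8-value FFT block plus a 14-value Haar
wavelet block on each of the 7 signals; bilaterally, the weight-shift
count. Equivalent tallies: 25 time-domain + 112 FFT + 196 wavelet
features, from 13 time-domain and 22 frequency-domain feature types.

Conventions that required a decision:

* **Reversals** are maximal runs of first differences moving against the
  window's *net* AP direction (sign flips when net displacement is
  negative). The run count, mean run duration and mean summed |Δ| give the
  three features. This run-based operationalization is deterministic and
  matches the three named statistics; an absolute-posterior-motion variant
  would be equally defensible.
* **Deviations** read the "± 0.5 mm" threshold as a per-sample first
  difference magnitude on ML COP; the literal unit in the source
  description is ambiguous, and this reading makes the threshold
  rate-independent at fixed sampling rate.
* **FFT block.** Windows are mean-detrended; the one-sided amplitude
  spectrum covers bins 1…N/2 (DC excluded) with amplitude 2|X_k|/N at
  interior bins and √2·|X_{N/2}|/N at Nyquist. Under this scaling
  Parseval's identity is exact: Σx² = (N/2)·Σa². At the default 1 s / 100 Hz
  window the bin width is 1 Hz; the locomotion band sums bins in
  [0.5, 3) Hz and the freeze band bins in [3, 8] Hz — the shared 3 Hz edge
  belongs to the freeze band. The freeze index (freeze/locomotion power) is
  0 when both powers are 0 and capped at 10⁶ throughout: an uncapped ratio
  against a roundoff-level denominator produces values ~10³⁰ that destroy
  min–max scaling downstream.
* **Wavelet block.** Single-level orthonormal Haar transform
  (aC_k = (x_{2k}+x_{2k+1})/√2, dC_k = (x_{2k}−x_{2k+1})/√2, via
  PyWavelets); odd windows pad-repeat the last sample. Variance (sample,
  ddof = 1), max, min, mean, and max/min/mean energy (coefficient squared)
  of each coefficient vector. A single level matches the "detail and
  approximation coefficient vectors" (singular pair) framing.
* **Guards.** A coefficient of variation with |mean| < 10⁻⁹·σ returns 0 and
  is flagged; any non-finite feature value is zeroed and counted in a
  run-level quality report, so a single degenerate window cannot poison
  training.

## Relief-F

Kononenko's Relief-F in the binary case: features min–max scaled, k = 10
nearest hits and misses per sampled instance under normalized Manhattan
distance, weight update W_f += Σ_miss diff_f/(mk) − Σ_hit diff_f/(mk).
Constant features score exactly 0. Neighbour ties break by instance index
and weight ties by catalog order, so rankings are reproducible. By default
every instance is sampled; `n_sampling` draws a seeded subsample for large
window sets (the experiment-scale runs in this repository use
n_sampling = 400, which left rankings stable in practice). Ranking is done
**per cross-validation fold on training windows only** — ranking on the
full dataset would leak held-out information into feature selection.

## RUSBoost

Two-class AdaBoost with per-iteration random undersampling (Seiffert-style):
instance weights are maintained over the full training set; each iteration
draws all minority windows plus an equal number of majority windows
(1:1 post-sampling ratio, configurable), fits a tree on the sampled
weighted data, and computes the weighted error ε and the learner weight
α = ½·ln((1−ε)/ε) on the **full** set, so α reflects true performance.
ε = 0 caps α at ½·ln(10¹⁰); ε ≥ ½ discards the iteration and resamples (10
retries, then early stop — common late in boosting once weight mass sits on
irreducibly ambiguous boundary windows; the ensemble simply stays shorter).
Trees are axis-aligned, grown best-first by weighted Gini gain to at most
5 internal nodes ("5 splits"), leaves scoring the weighted target
probability. The ensemble score is Σ α(p_t − ½); ties (score 0) resolve to
non-target — for a cueing system the conservative error is the missed cue,
not the false one. A two-class AdaBoost core is used rather than
AdaBoost.M2: with two classes they are equivalent in effect and the
two-class loop is fully specified and simpler to verify.

## Episode-level evaluation

Three consecutive target windows raise a model trigger decision (MTD) at
the third window's end; every further window extending the run raises
another, and the 2.5 s no-cue interval (measured from the last accepted
MTD) is the sole rate limiter. Each episode's target zone runs from
onset − 6 s through the episode **end** — detections after onset count as
identifications with positive delay, matching how identification delay is
reported in this literature. A turn or stand segment ending inside the 6 s
span pushes the zone opening to its end + 1 s; a prior freeze pushes it to
its own end with no delay (the 1 s delay belongs to gait transitions, not
freezes). A zone pushed past the onset collapses to detection-only
[onset, end]. Unsuppressed MTDs are true positives inside a zone; outside,
they are ignored during standing or the first 1 s of walking after
standing, otherwise false positives (FPR = false positives / trials). The
identification delay of an episode uses the earliest in-zone MTD. Model
selection ranks the six feature counts per dataset on the five metrics
(sensitivity, specificity, EI higher-better; ID and FPR lower-better, ID by
signed value so earlier prediction ranks better), averages ranks on ties,
and picks the smallest rank sum, ties going to fewer features.

## Synthetic cohorts

The generator produces the statistical structure the analysis relies on,
not biomechanically faithful kinetics:

* walking as alternating stance loading at stride period 1.1 s (stance
  fraction 0.62), half-sine stance GRF with a 10 % double-bump modulation,
  linear heel→toe AP COP progression (±120 mm), ~3 mm sinusoidal ML sway
  (×2.5 during turns), and 3 % residual body-weight pressure during swing
  (exercising the 5 % zeroing rule);
* freezes as both feet loaded near half body weight, no AP progression, and
  COP "trembling" at a per-episode frequency drawn uniformly from 3–8 Hz
  (5 mm AP, 9 mm ML);
* a 2 s pre-FOG transition in which cadence rises by up to 35 % and the
  tremor amplitude ramps in linearly. Real pre-FOG gait is not
  quantitatively characterised; this deterministic ramp is an assumption
  chosen so that pre-FOG windows are statistically separable and
  end-to-end recovery tests are meaningful;
* most-affected-side asymmetry as a ×1.5 noise scale on the MAS foot, and
  per-freezer episode propensity drawn from a Gamma(2, ½) multiplier on
  the expected 2 episodes/trial, giving heavy between-participant
  dispersion; non-freezers never freeze.

Labels are generated at 30 Hz and transferred through the same label-
transfer path as real annotations. Episode placement is uniform within
walk/turn segments with constraints that keep the design meaningful: never
in the first 2 s, at least 3 s between episodes, and onset at least 3.5 s
after the segment start so the pre-FOG run-up lies inside the segment and
the target zone stays open ahead of onset (without this, zone truncation
makes pre-onset prediction impossible by construction). A practical side
effect: the 2.5 s synthetic turns are too short to host episodes, so
synthetic freezes occur during walking — turn-triggered freezing is not
represented. Per-participant and per-trial random streams derive from the
master seed and the identifiers alone, so cohorts are reproducible and
order-independent.

What passing the end-to-end tests shows: the pipeline recovers a planted,
spectrally clean freeze signature through windowing, ranking, boosting and
episode scoring, with no leakage and full determinism. What it does not
show: performance on real plantar-pressure data, whose pre-FOG signatures
are weaker, non-stationary and heterogeneous across patients — published
window sensitivities/specificities on clinical cohorts sit near 75–88 %,
well below the synthetic recovery figures here.

## Problem sizes and defaults

Default experiment scale (used by `scripts/acceptance.py` and the
end-to-end tests): 7 freezers + 4 non-freezers, two 40 s trials each
(≈ 4 300 windows), Relief-F with n_sampling = 400, RUSBoost with 100 trees
× 5 splits, the 3 × 6 grid under leave-one-freezer-out cross-validation —
a few minutes on one CPU. All tunables are dataclass-exposed
(`GaitSimConfig`, `WindowSpec`, `BandSpec`, `ReliefFConfig`,
`RUSBoostConfig`, `EvalConfig`) and mirrored in the YAML config of the CLI.

## Known limitations

* The generator omits turn-hosted freezes, medication state, dual-task
  load, cueing response, and realistic inter-stride variability.
* The reversal/deviation definitions and the swing-phase COP hold are
  reasonable but not unique operationalizations; alternatives would change
  those 12 features.
* Undersampling ratio, boosting variant and decision threshold are
  conventional defaults, not tuned values; all are config-exposed.
* Episode scoring assumes complete, non-overlapping annotations; partially
  observed episodes are not modelled.
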