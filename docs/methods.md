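# Methods

This note documents the models, conventions and design choices behind
`srsleep`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Recording geometry and time axis

Zeitgeber time (ZT, hours since lights-on) is the canonical time axis
everywhere; lights off at ZT12. A recording day is 23 h (ZT0–23), sampled
at 64 Hz and scored in non-overlapping 4-s epochs (256 samples), i.e.
20 700 epochs/day. Two recording days per animal are the default; per-animal
metrics average the two days with equal weight (transition counts are
summed and normed frequencies recomputed from the sums), because the
statistical unit downstream is the animal. Pooling instead of averaging is
a one-line change in `summarize_animal` and is deliberately not the
default.

The analysis intervals are L1 = [0, 6), L2 = [6, 12), D1 = [12, 18) and
D2 = [18, 23) h — D2 spans only five hours because recordings stop at ZT23.
Normed (fraction-of-interval, fraction-of-all-transitions) quantities keep
the unequal interval lengths comparable.

## Synthetic cohort generator

**What it emulates.** Three breeding lines × 8 animals × 2 days. Hypnograms
are first-order Markov chains on 4-s epochs, piecewise-homogeneous by light
phase: one 3×3 row-stochastic matrix for LIGHT (ZT0–12) and one for DARK
(ZT12–23) per line. The first day starts from the stationary distribution
of the LIGHT matrix; day 2 continues from day 1's final state. Animal seeds
derive from the master seed via `numpy.random.SeedSequence`, so one integer
reproduces a cohort exactly. Default master seed: 20110324.

The shipped presets were chosen once to give realistic mouse sleep
architecture (light phase ≈ 35–40% WAKE, 46–55% NREMS, 9–15% REMS; dark
phase ≈ 71% WAKE; NREMS bouts ≈ 1.5–2.5 min, REMS bouts ≈ 1 min) and to
encode the line contrasts of interest:

- P(NREMS→REMS) per epoch is 0.019/0.013/0.010 (LIGHT) and
  0.010/0.006/0.005 (DARK) for HR/IR/LR, with **identical REMS exit rows**
  across lines. HR therefore gains REMS time purely through more episodes
  of unchanged length — the event-history mechanism under study.
- The LR NREMS band profile carries depressed theta (0.11 vs 0.15) and
  alpha (0.07 vs 0.10) relative power, with delta absorbing the remainder
  so total in-band power is constant. (Because relative powers are
  compositional, LR consequently sits *above* the other lines in delta —
  an expected mirror image, visible in the full stability screen.)

**Signals.** Per epoch, the EEG is spectrally shaped noise built by inverse
DFT: each analysis band's bins share the state's target fraction equally,
the remainder (1 − Σ fractions) goes to the inter-band gap bins, phases are
uniform random, and the epoch is scaled so its RMS equals the state's EEG
amplitude exactly (Parseval makes the scaling exact, not approximate).
Epochs are spectrally independent; no continuity across epoch boundaries,
no 1/f background, no artifacts or transients are modelled. EMG is white
noise with per-state RMS 30/10/2 µV for WAKE/NREMS/REMS (atonia ordering
enforced at preset construction).

**What passing tests do not show.** The generator has sharply separated
state-conditional distributions and no scorer-adversarial content (no
movement artifacts, no state transitions inside an epoch, no drift), so the
≥ 90% scorer round-trip criterion demonstrates internal consistency of the
feature/scoring chain, not expected performance on real recordings.
Likewise the Markov model has no ultradian or homeostatic (Process-S)
structure; it reproduces phase-level aggregates, which is all the
downstream statistics consume.

## Spectral features

Per epoch: a 256-point periodogram on the 0.25 Hz grid, rectangular window
by default (the taper is configurable; tapered windows are
power-compensated by 1/mean(w²)). One-sided scaling is chosen so the non-DC
bins sum exactly to the biased epoch variance (Parseval, asserted to 1e-8
relative in tests). The DC bin and bins below 0.75 Hz are excluded from all
powers.

Band-edge convention: a bin belongs to a band when its centre frequency
lies in [low, high] **inclusive** — the printed band edges are exact grid
points, and inclusivity makes eta|beta contiguous at 22.75|23.0 Hz. The
inter-band gap bins (5.25–5.75, 9.25–9.75, 15.25–15.75 Hz) count toward
total power (0.75–31.75 Hz) but toward no band, so relative powers sum to
slightly less than 1. Whether the original analysis included gap bins in
its denominator is not documented; the inclusive-total convention is this
package's decision and is visible in `BandScheme`.

The analog front-end band-pass (0.5–29 Hz, 48 dB/octave) is emulated as an
order-4 Butterworth applied forward and backward (`sosfiltfilt`), giving
the matching 48 dB/octave magnitude roll-off with zero phase. EMG is never
filtered. Synthetic signals are already band-limited by construction, so
the pipeline applies the filter only when asked (`filter_signals=True`,
meant for real recordings).

Epochs with zero total power are flagged `power_defined = False` with NaN
relative powers rather than silently propagating NaN; the scorer routes
them to its fall-back rule.

## Vigilance scoring

The original semi-automatic scorer is proprietary and specified elsewhere;
this package implements a transparent threshold cascade over the same
feature space (band fractions, EMG RMS):

1. EMG RMS > wake cutoff → WAKE;
2. else if theta/delta > 1.5 and EMG RMS < sleep cutoff → REMS;
3. else if relative delta > 0.35 → NREMS;
4. else the previous epoch's label (first epoch: WAKE).

EMG cutoffs are calibrated per recording as the 0.60/0.40 quantiles of the
epoch EMG RMS distribution, standing in for per-animal manual tuning; the
quantiles sit near the sleep/wake occupancy boundary of a typical 23-h
mouse recording, so with clustered EMG levels the wake cutoff lands at the
lower margin of the wake cluster and rule 4 absorbs the stragglers.
Explicit absolute cutoffs bypass calibration; a constant EMG distribution
raises a calibration error advising them. No smoothing or minimum-bout
post-processing is applied by default. Manual rescoring is represented by
an override table (epoch index → state) with per-epoch provenance
(AUTO/OVERRIDE).

Raising the wake cutoff can never increase the number of WAKE epochs
(rules 2–3 are cutoff-independent and rule 4 only inherits), a monotonicity
property the tests check empirically.

## Event-history metrics

Conventions (fixed for reproducibility; the results are insensitive to
reasonable alternatives at 4-s resolution): epochs belong to the interval
containing their start time; a transition between differing consecutive
epochs belongs to the interval in which the later epoch starts (partition
without double counting); a REMS episode is a maximal run of REMS epochs,
belongs to the interval of its first epoch, and is never split across a
boundary. An interval with no transitions has *undefined* (not zero)
normed frequencies; an interval with no REMS episode has an *undefined*
mean episode length and is excluded listwise from the episode-length
ANOVA, with N reported per test.

## Group statistics

Wilks' Λ from between/within SSCP matrices with Rao's F approximation
(t = 1 when p²+q²−5 ≤ 0, which also makes the single-response MANOVA
collapse exactly to one-way ANOVA — asserted in tests). For 5 responses,
3 groups and N = 23 this yields the df pattern F(10, 32).

Compositional responses are rank-deficient: the three normed durations sum
to 1, so the duration MANOVA drops WAKE; the six normed transition
frequencies also sum to 1, so the transition MANOVA drops structurally
constant pairs and then the rarest pair. Both choices are rank-preserving
and the dropped response is recoverable from the others.

"Bonferroni-modified LSD" is interpreted as unprotected Fisher-LSD t tests
(pooled within-group MSE, its error df) judged at α divided by the number
of comparisons; the divisor is configurable because the original family
definition (per response family vs per interval) is ambiguous. Contrasts
are gatekept: they are computed only when the omnibus MANOVA is significant
at the nominal α, and univariate follow-ups are judged at α/m. Complete
cases are used within a MANOVA, listwise deletion within a univariate
response, and every result carries the N actually used.

## Stability analysis

The "part of each mean power above the common median" is read as the
*signed* excess (value − per-ZT median of the group means); the
positive-part reading max(0, ·) would discard information and break the
antisymmetry of the test under group exchange, but remains available via
the excess series themselves. Group means across animals (not individual
animals) are the paired observations at ZT 1..23; hour h summarises epochs
with ZT in [h−1, h). The Wilcoxon matched-pairs test drops zero
differences, midranks ties, and uses the exact null distribution for
n ≤ 25 (covering n = 23) and the tie-corrected normal approximation above.
At least 10 paired points are required.

"Stable and continuously above" is operationalised as: significant at
α = 0.05 **and** sign-constant in ≥ 90% of non-zero points. The screen
always emits the full quantity × pair table (no selective reporting) with
an informational Benjamini–Hochberg column; the headline `stable` flag
deliberately uses the uncorrected level, matching the nominal-p reporting
convention of this literature.

## Numerical and edge-case choices

- Exact quantities (durations, counts, episode lengths, AUC, median
  excesses) are tested for *equality* against brute-force oracles, not
  within tolerances.
- Band AUC: interior missing hours are linearly interpolated; missing
  endpoint hours are dropped with a warning; < 2 points → NaN.
- Degenerate stability input (all differences zero) returns p = 1,
  direction "none", never an exception.
- EDF export quantises to 16 bits over the declared physical range
  (error ≤ one step, asserted against an independent reader); NPZ
  round-trips are bit-exact; hypnogram CSVs are validated with row-numbered
  errors.

## Problem sizes used in tests and the acceptance script

Long-chain parameter recovery uses a single-phase, well-mixed 3-state
matrix over 999 000 epochs (1110 h), where every off-diagonal flow yields
≥ 10⁴ expected transition counts, making the 1%-absolute /
2%-relative recovery bounds comfortably testable; rarer flows (like the
presets' REMS→NREMS at ~2×10⁻⁴ per epoch) would need ~50× longer chains
for the same relative precision and are exercised via the χ² row test
instead. The scorer round trip uses the full 24-animal × 2-day cohort
(993 600 epochs). Directional reproduction uses 100 master seeds
(hypnogram-only cohorts), and the null screen 40 seeds. Type-I calibration
uses 5 000 (ANOVA) and 2 000 (Wilcoxon) replicates.

## Known limitations

- The scorer thresholds are tuned to the synthetic signal model; real
  recordings would need recalibration and likely artifact handling.
- No repeated-measures treatment of the two recording days (pre-averaged),
  no REMS-latency/bout-survival modelling, no Process-S dynamics.
- The stability test treats ZT points as exchangeable pairs; serial
  correlation of the hourly curves is ignored, exactly as in the original
  procedure.
- Only one EEG lead is modelled; lead-selection logic is out of scope.
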