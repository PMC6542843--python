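# Methods

This note records the model implemented by `usvkit`, the numerical choices,
and every place where the implementation had to interpret an underspecified
convention. It is the authoritative reference for "why is it done this way".

## 1. Synthetic call model

Each call is a `CallSpec`: one or more *components*, each a piecewise-linear
frequency trajectory (kHz over ms). Components are rendered independently by
phase-integration FM synthesis — the phase is the cumulative sum of the
instantaneous frequency, so a stepped trajectory produces a continuous
waveform with an instantaneous frequency jump — multiplied by a
raised-cosine onset/offset ramp over 10 % of the component duration
(limiting spectral splatter), summed, peak-normalised to 0.5, and embedded
in 15 ms of background on either side. White Gaussian noise is added over
the whole record at the requested SNR (measured against the call's active
samples); if the sum exceeds ±1 the record is renormalised.

Category constraints (kHz/ms; all frequencies within the admissible
30–125 kHz band):

| category       | construction |
|----------------|--------------|
| flat           | duration U(15, 60), centre U(50, 90), drift ≤ ±2 |
| short          | duration U(1.5, 5), drift ≤ ±1 |
| upward         | duration U(15, 60), start U(50, 75), rise U(14, min(25, 105−f₀)) |
| downward       | duration U(15, 60), start U(65, 90), fall U(14, min(25, f₀−38)) |
| chevron        | duration U(20, 60), arms U(8, 16) each, apex at 40–60 % of the call |
| complex        | duration U(30, 60), three monotone runs with excursions U(8, 15) |
| frequency step | duration U(20, 60), 1–2 instantaneous jumps U(8, 20), plateau drift ≤ ±1 |
| two-components | main 20–45 ms flat-or-downward call, silent gap U(3, 15), second 5–12 ms component offset ±U(10, 20) |
| composite      | two simultaneous flat components at U(45, 60) and U(78, 95) |

The directional-change quantum is 6.25 kHz, the monotone-excursion threshold
12.5 kHz, the short-call bound 5 ms and the flat-call excursion bound 3 kHz.
Chevron and complex excursions are drawn above 8 kHz (not the bare 6.25
minimum) and their durations start at 20/30 ms so that the steepest sweep
stays within the whistle tracker's 3-bins-per-frame continuity bound; the
published category definitions only give minimums, so these draws remain
inside them.

A **rule oracle** (`rule_oracle_label`) classifies peak-frequency tracks by
the printed rules in a fixed precedence: composite (overlapping tracks) →
frequency step (intra-track jump ≥ 6.25 kHz) → two-components (sequential
tracks) → short (≤ 5 ms) → complex (≥ 2 directional changes) → chevron (one
up-then-down change) → upward/downward (net ±12.5 kHz) → flat (residual).
Structural rules must pre-empt shape rules, and flat is the only sensible
fallback. Tracks are median-3 smoothed and directional changes are counted
between *significant extremes* (turning points whose adjacent monotone runs
both reach 6.25 kHz), so sub-threshold jitter never creates spurious
changes. Generator and oracle agree on 100 % of draws (closure), and
re-extracting tracks from the synthesized audio recovers the category for
≥ 95 % of draws per category at high SNR (round trip).

## 2. Spectrograms

30 kHz zero-phase high-pass: 8th-order Butterworth applied
forward-backward (`sosfiltfilt`). Forward-backward filtering squares the
magnitude response, giving ≥ 40 dB attenuation one octave below cutoff and
< 1 dB droop above 1.2× cutoff with no group delay (call onsets stay put);
a 4th-order design misses the 1 dB passband requirement (−1.8 dB at 36 kHz),
which is why order 8 is used.

STFT: 512-point FFT, Hamming window, 75 % overlap, analysis frame equal to
the FFT length ("frame size 100 %" = no zero padding). At 250 kHz sampling:
hop 128 samples = 0.512 ms, bin spacing 488.28 Hz; the −3 dB main-lobe width
of the Hamming taper is 1.30 bins = 634.8 Hz, reproduced as a config echo.
The final partial frame is discarded, so
`frames = floor((len − 512)/128) + 1`. Magnitudes are linear (feature math
operates on spectral energy); frame times are frame centres, bins are bin
centres, all indices 0-based.

## 3. Detection

Frame level = the frame's peak passband bin magnitude in dB relative to the
file's peak. This is a deliberate choice over summed frame energy: with
additive white noise at the default 20 dB SNR the summed-energy statistic
sits exactly on the −20 dB start threshold, whereas the peak-bin statistic
gains the STFT's ~20 dB processing margin over broadband noise and keeps the
default hysteresis pair robust down to ~10 dB SNR.

Modes:

- **whistle tracking** — an element opens when the level rises above the
  start threshold (−20 dB) and continues while it stays above the stop
  threshold (−30 dB) *and* the spectral-peak ridge moves by at most
  3 × bin spacing per frame (≈ 2.9 kHz/ms at the default hop);
- **two thresholds** — plain start/stop amplitude hysteresis;
- **three thresholds** — as above plus an intermediate −25 dB re-arm level
  for follow-on elements (the vendor algorithm this mirrors is proprietary;
  this is an interpretation, flagged as such).

Elements separated by a silent gap shorter than the hold time are merged;
gap frames are kept in the span but masked out of frame-wise statistics.
Per-category settings (hold 20 ms for two-components, 25 ms for frequency
steps, minimum duration 1 ms for short calls) ship as
`src/usvkit/data/detection_table.yaml`. For unlabeled input the default is
whistle tracking with a 25 ms hold.

**Measured span vs nominal duration.** A 50 ms flat whistle at 20 dB SNR
detects as a stable 95-frame element (48.6 ms): the −20 dB threshold
crossing sits ~2 ms inside each 10 % raised-cosine ramp (amplitude 0.1 ≈
−20 dB), partially offset by the +1.5 ms temporal smearing of the 512-sample
analysis window. The offset is deterministic; the track-extraction path used
for oracle labeling subtracts the window smear
(`(fft_len − hop)/fs = 1.536 ms`) so the 5 ms short-call boundary survives
the round trip, while the feature-level `duration` is reported as the raw
detected span (`frames × hop`), uncorrected, as an instrument would.

## 4. The 102-feature grid

Ten frame-wise measures — peak frequency, peak amplitude, −20 dB minimum and
maximum frequency, bandwidth, 25/50/75 % spectral-energy quartile
frequencies, Wiener entropy (geometric/arithmetic mean of the magnitude
spectrum), fundamental (lowest local spectral peak within 20 dB of the frame
peak) — each aggregated ten ways: at the start/centre/end signal frame of
the principal (longest) element, mean/min/max over the principal element's
signal frames, and mean/min/max/standard deviation over all signal frames of
all elements ("entire" variants). Plus `duration` and `peaktopeak`
(waveform max − min over the detected span): 102 values.

Interpretive decisions, in decreasing order of consequence:

- **The grid itself is a reconstruction** (the authoritative feature list
  is not public). It is constrained to total exactly 102 and to contain
  every feature name that appears in the published selection tables.
- "Entire" aggregations span all elements of the call, not the whole file —
  otherwise multi-element classes lose their second component. Consequence:
  for the seven single-element classes `mean` ≡ `meanentire` (and min/max
  counterparts) are duplicate columns; see § Known limits.
- −20 dB relative floor for min/max frequency and the fundamental. Energy
  quartiles are computed within the `[min freq, max freq]` band so the
  ordering chain `min ≤ q25 ≤ q50 ≤ q75 ≤ max` holds on every frame; a
  full-passband definition violates it on noise-heavy frames (broadband
  energy below the floor can push `quart 75` past the floored maximum).
  The closed forms are unaffected: a uniform band lies entirely above the
  floor (median at the band midpoint), and a pure tone's energy is
  concentrated at the peak. Entropy uses the full passband spectrum
  (uniform band → 1).
- centre frame = `floor((start+end)/2)`, snapped to the nearest signal frame;
  one-frame elements have start = centre = end.
- Amplitudes are linear magnitudes in arbitrary units; every frequency
  measure is gain-invariant, `peak ampl` and `peaktopeak` scale linearly.

All measures are computed only on bins at or above the high-pass cutoff.
Silent (all-zero) frames are undefined and rejected; detection masks keep
them out.

## 5. Feature selection

- **GSO** — greedy forward ranking: standardized features, one-hot class
  indicator target; at each step the candidate with the largest sum of
  squared cosines against the (residualized) indicator columns is selected
  and its direction is deflated from remaining candidates and target. The
  cited derivations treat scalar targets; the one-hot/sum-of-cosines
  extension is this package's documented choice. Equivalent to naive
  per-step least-squares re-scoring (tested against a brute-force oracle).
- **mRMR** — features discretized to 3 levels at mean ± sd (standard
  practice for continuous features; no discretization is published), mutual
  information in bits from empirical joint frequencies, difference criterion
  `I(f;y) − mean_s I(f;s)`. Also oracle-tested.
- **SIMBA** — stochastic hypothesis-margin ascent: weights initialised to 1;
  for each sample the nearest hit and nearest miss under the w²-weighted
  Euclidean metric drive the update
  `dw_i = ½((x_i−M_i)²/‖x−M‖_w − (x_i−H_i)²/‖x−H‖_w)·w_i`; T = 5 passes;
  weights renormalised to max |w| = 1 per pass; merit = w²/max(w²).
  **Weights are kept signed, not clipped at zero**: the metric depends on w
  only through w², so the sign is irrelevant to the objective, while a clip
  combined with the multiplicative update permanently freezes any feature
  whose first overshooting step drives it non-positive (empirically this
  kills `duration` outright on the default corpus).
- **RFaccuracy** — Breiman-style permutation importance: per tree, the drop
  in accuracy on that tree's out-of-bag samples when each feature column is
  permuted, averaged over 500 trees. (Generic permutation importance on a
  held-out set is not a drop-in: the out-of-bag variant needs per-tree
  bootstrap bookkeeping, so it is implemented directly.)
- **Stability protocol** — each method is run 100 times on stratified 90 %
  subsamples (stratified so every run retains all classes) and the per-run
  orders are aggregated by Borda voting (sum of 0-based positions; ties by
  mean position, then feature index).

## 6. Classification and validation

- **RF**: 500 trees, Gini splits, bootstrap resampling, minimum node size 1,
  `mtry` = 10 or 20 on the full 102-feature matrix (default √M), raw
  features (trees are scale-invariant).
- **SVM**: RBF kernel, one-against-one (36 binary problems for 9 classes),
  C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (step 2 ⇒ 11 × 10 = 110 pairs), tuned by
  an inner 10-fold CV on the training partition; features z-scored with
  training-fold statistics only.
- **Validation**: stratified 10-fold CV (stratified because 25-per-class
  data can otherwise lose a class from a training fold), repeated (default
  10 repetitions; 100 reproduces the full published protocol);
  per-repetition accuracy pools correct predictions over the 10 folds
  (225 samples → fold sizes 22/23, i.e. 203/202 training samples);
  confusion matrices pool all repetitions. Selection, standardization and
  tuning happen strictly inside training partitions.
- **t-SNE**: perplexity 30, PCA initialisation, 1000 iterations, fixed
  seed — none of these are published; they are scikit-learn-conventional.

All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawning, so every corpus, ranking, CV run and report is bit-reproducible.

## 7. Known limits of the synthetic surrogate

- **Headline surrogate accuracy.** On the default corpus (25 calls/class,
  corpus seed 42, SNR 20 dB) the SIMBA-consensus top-8 features give a mean
  RF accuracy of ~72 %, against ~85 % reported for the corresponding
  experiment on real mouse calls. This is a property of the corpus geometry,
  not a defect of the selectors: all 102 features reach 89.6 %, an informed
  8-feature subset reaches 90.5 %, and the SIMBA top-15 reaches 87.9 %. The
  generator draws durations and centre frequencies from identical
  distributions across classes (only the category *rules* differ), so the
  duration and positional-frequency features that dominate selections on
  real data are only weakly informative marginally; margin-based weighting
  then concentrates on frequency-modulation spread measures, and the Borda
  vote promotes a mutually redundant cluster of them (including exact
  `mean`/`meanentire` duplicates for single-element classes) into the top-8,
  leaving only ~4–5 effective dimensions. Noise is not the cause (the same
  protocol at infinite SNR reaches only ~79 %), and the spec-faithful
  clipped-weight SIMBA variant selects essentially the same cluster.
- **Duration proxies.** On synthetic audio, per-frame amplitude statistics
  act as proxies for call duration (the envelope ramp occupies a fixed
  fraction of the call, and very short calls never reach full window
  overlap), so selectors may rank `peak ampl` aggregates above `duration`
  itself even when duration is the separating variable.
- **`short` vs `flat` spread.** Short calls span so few frames that their
  track-jitter spread (`peak freq (stddeventire)`) is *smaller* than flat
  calls'; flat has the least spread only among the longer single-component
  classes.
- The generator does not model laryngeal production mechanics, harmonics of
  sonic calls, or recording-chain coloration; amplitudes are normalised, so
  absolute-intensity cues present in real recordings are absent by design.
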