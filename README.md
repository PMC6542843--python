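# usvkit

Objective classification of mouse ultrasonic vocalizations (USVs): synthetic
call generation, spectrogram analysis, element detection, a 102-measure
acoustic feature set, four feature-selection algorithms under a
perturbation-voting stability protocol, supervised call-type classification
with random forests and SVMs under repeated cross-validation, and t-SNE
visualization.

## What it does

Mouse pups and adults emit ultrasonic calls (roughly 30–120 kHz) that
behavioural phenotyping pipelines sort into nine expert-defined categories:
**complex, two-components, upward, downward, chevron, short, composite,
frequency step, flat**. `usvkit` implements an end-to-end, fully reproducible
version of that workflow:

1. **Synthesis** (`usvkit.synth`) — a parametric generator draws labeled
   calls for each category (piecewise-linear frequency trajectories rendered
   by phase-integration FM synthesis at 250 kHz, raised-cosine onset/offset,
   additive white noise at a controlled SNR), so the whole pipeline is
   testable without animal recordings. A rule oracle labels peak-frequency
   tracks independently of the generator's bookkeeping.
2. **Spectrograms** (`usvkit.spectral`) — zero-phase 30 kHz high-pass, then
   an STFT with 512-point FFT, Hamming window, 75 % overlap: 0.512 ms hop and
   488 Hz bin spacing at 250 kHz sampling.
3. **Detection** (`usvkit.detection`) — whistle tracking or two/three
   amplitude-threshold hysteresis per call type, hold-time merging of
   multi-part calls, minimum-duration filtering.
4. **Features** (`usvkit.features`) — 10 frame-wise spectral measures (peak
   frequency/amplitude, −20 dB min/max frequency, bandwidth, 25/50/75 %
   energy quartiles, Wiener entropy, fundamental) × 10 aggregations
   (start/centre/end, mean/min/max over the principal element,
   mean/min/max/sd over all elements) + duration + peak-to-peak = **102
   features per call**.
5. **Feature selection** (`usvkit.selection`) — Gram-Schmidt
   orthogonalization (GSO), minimum-redundancy maximum-relevance (mRMR),
   SIMBA margin-based weighting, and random-forest out-of-bag permutation
   importance; each run 100 times on stratified 90 % subsamples and
   aggregated by Borda voting.
6. **Classification** (`usvkit.classify`) — random forests (500 Gini trees)
   and one-against-one RBF SVMs (grid-searched by inner 10-fold CV),
   validated by repeated stratified 10-fold cross-validation with pooled
   confusion matrices and accuracy-vs-k curves.
7. **Visualization** (`usvkit.embedding`) — t-SNE scatter plots of the full
   and selected feature spaces.

See `docs/methods.md` for the model, parameter choices, and the reasoning
behind every interpretive decision.

## Quick start (library)

```python
import usvkit as uk

corpus = uk.generate_corpus(n_per_class=25, master_seed=42, snr_db=20.0)
dm = uk.build_design_matrix(corpus)          # 225 x 102, no missing values
print(dm.shape)                              # (225, 102)

ranking = uk.stability_protocol(dm.X, dm.y, "simba", runs=100, rng=1)
print([dm.feature_names[i] for i in ranking.top(3)])
# ['quart 50 (stddeventire)', 'quart 25 (stddeventire)', 'peak ampl (stddeventire)']

result = uk.cross_validate(
    dm.X[:, ranking.top(8)], dm.y,
    uk.RFParams(n_trees=500, n_candidate_features=10),
    folds=10, repetitions=10, seed=1,
)
print(f"{result.mean:.3f} +/- {result.sd:.3f}")   # 0.719 +/- 0.016
```

## Quick start (CLI)

```bash
usvkit generate --n-per-class 25 --seed 42 --snr-db 20 --out corpus/
usvkit extract  --in corpus/ --out features.csv
usvkit select   --features features.csv --method simba --runs 100 --seed 1 --out ranking.json
usvkit classify --features features.csv --ranking ranking.json --top 8 \
                --model rf --folds 10 --reps 10 --seed 1 --out results.json
usvkit project  --features features.csv --out coords.csv --plot tsne.png
usvkit experiment --out run1/      # the whole study in one command
```

## Layout

```
src/usvkit/        library (synth, spectral, detection, features,
                   selection, classify, embedding, experiment, cli)
src/usvkit/data/   per-category detection parameter table (YAML)
scripts/           acceptance measurement
tests/             pytest suite (unit, property, and acceptance tests)
docs/methods.md    model description and design decisions
```
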